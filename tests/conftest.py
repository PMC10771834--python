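import math

import numpy as np
import pytest

from aneumorph.synthetic import SacSpec, make_sac
from aneumorph.types import AneurysmGeometry, Centerline, NeckAnnotation, TriSurface


@pytest.fixture(scope="session")
def hemisphere_geom():
    """Unit-hemisphere sac on a thin straight vessel, refinement 5."""
    return make_sac(SacSpec(shape="hemisphere", radius=1.0, refinement=5, vessel_radius=0.5))


@pytest.fixture(scope="session")
def tilted_geom():
    """A tilted half-ellipsoid with exact target ground truths."""
    spec = SacSpec.from_targets(
        hmax=6.5, dneck=5.6, dvessel=3.5, theta_a_deg=110.0, theta_f_deg=130.0, refinement=5
    )
    return make_sac(spec)


def cone_geometry(apex, ring_radius=1.0, n=64, centerline_z=-1.0):
    """Hand-built cone sac: circular neck contour at z = 0, single apex
    vertex, straight +x centerline below the plane. The apex is the farthest
    vertex whenever |apex| > ring_radius, making the sac axis exact."""
    theta = 2 * math.pi * np.arange(n) / n
    ring = np.column_stack([ring_radius * np.cos(theta), ring_radius * np.sin(theta), np.zeros(n)])
    vertices = np.vstack([ring, np.asarray(apex, dtype=float)[None, :]])
    faces = np.column_stack([np.arange(n), np.roll(np.arange(n), -1), np.full(n, n)])
    sac = TriSurface(vertices, faces)
    neck = NeckAnnotation(
        plane_point=np.zeros(3), plane_normal=np.array([0.0, 0.0, 1.0]), contour=ring
    )
    s = np.linspace(-10.0, 10.0, 41)
    parent = Centerline(
        points=np.column_stack([s, np.zeros_like(s), np.full_like(s, centerline_z)]),
        radii=np.full_like(s, 0.5),
    )
    return AneurysmGeometry(sac=sac, neck=neck, parent=parent)


def flat_patch(n=10, extent=2.0):
    """Regular triangulated square patch in the z = 0 plane."""
    xs = np.linspace(0.0, extent, n)
    xx, yy = np.meshgrid(xs, xs, indexing="xy")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for j in range(n - 1):
        for i in range(n - 1):
            v00 = j * n + i
            faces.append([v00, v00 + 1, v00 + n + 1])
            faces.append([v00, v00 + n + 1, v00 + n])
    return TriSurface(vertices, np.asarray(faces))


def random_rotation(rng):
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
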