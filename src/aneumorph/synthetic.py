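"""Synthetic aneurysm geometries and pulsatile WSS fields with known ground
truth, plus brute-force Monte-Carlo volume oracles.

The sac generator builds a lat-long triangulation of a hemisphere or
half-ellipsoid open at the neck plane (z = 0 in construction coordinates),
optionally adds radial cosine undulation and a Gaussian daughter-sac bleb
(both pinned to zero at the neck so the contour stays planar), and tilts the
main axis with a volume-preserving horizontal shear, so the perpendicular
height H stays equal to the semi-axis c. A straight parent centerline is
placed tangent to the neck plane so the aneurysm-vessel angle thetaF takes a
requested value.

Ground truth for smooth (bump-free) sacs is analytic. The sac is the image
of the upper unit hemisphere under N = Shear * diag(a, b, c), so the maximum
height Hmax (farthest point from the neck centroid) is the largest singular
value of N, and the sac main axis is the corresponding left singular
direction; the inclination angle thetaA follows from that direction. The
:meth:`SacSpec.from_targets` constructor inverts this relation in closed
form so that requested (Hmax, thetaA, thetaF, Dneck, Dvessel) are the exact
truth values. Further identities: H = c, Dneck = 2 max(a, b),
Dvessel = 2 r_vessel, V = (2/3) pi a b c (shear is volume-preserving).

The WSS generator assigns each vertex a fixed tangent direction d and
magnitude m + A sin(2 pi t / T + phase), which has closed-form cycle
averages: for m >= A the direction never reverses, so TAWSS = m and OSI = 0;
for 0 <= m < A, with alpha = arcsin(m / A),

    TAWSS = (2/pi) (A cos(alpha) + m alpha),   OSI = (1 - m / TAWSS) / 2.

Defaults emulate the measured study conditions: sacs a few millimetres tall
on 3-4 mm parent vessels, cycle period 1 s (60 bpm) sampled at 200 points,
mean WSS of order 1 Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull

from .types import (
    AneurysmGeometry,
    Centerline,
    NeckAnnotation,
    TriSurface,
    ValidationError,
    WSSField,
)

__all__ = [
    "SacSpec",
    "FlowSpec",
    "make_sac",
    "make_wss_series",
    "mc_volume_oracle",
    "mc_hull_volume_oracle",
    "sample_sac_specs",
    "transform_geometry",
]


def _axis_analysis(a: float, b: float, c: float, shear: float):
    """Farthest-point analysis of the sheared half-ellipsoid.

    The sac surface is {N u : |u| = 1, u_z >= 0} with
    N = [[a, 0, c*shear], [0, b, 0], [0, 0, c]]. Returns
    (hmax, axis, dominant): the largest singular value of N, the unit
    direction of the farthest point, and whether that direction is strictly
    dominant (unique up to sign, with a 2 percent margin) so that height and
    angle ground truths are well defined.
    """
    q = c * shear
    # eigenvalues of the x-z block of N N^T: [[a^2+q^2, q c], [q c, c^2]]
    tr = a * a + q * q + c * c
    det = (a * c) ** 2
    disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    hmax = math.sqrt(max(lam1, b * b))
    # eigenvector of the x-z block for lam1 (pick the numerically stable row)
    if abs(q * c) > 1e-15:
        v = np.array([q * c, lam1 - (a * a + q * q)])
        if np.linalg.norm(v) < 1e-12 * math.sqrt(lam1):
            v = np.array([lam1 - c * c, q * c])
    else:
        v = np.array([1.0, 0.0]) if a * a > c * c else np.array([0.0, 1.0])
    v = v / np.linalg.norm(v)
    if v[1] < 0:
        v = -v
    axis = np.array([v[0], 0.0, v[1]])
    dominant = lam1 > (1.02**2) * max(lam2, b * b)
    return hmax, axis, dominant


@dataclass
class SacSpec:
    """Parameters of one synthetic sac-on-vessel geometry (lengths in mm).

    ``shape`` is ``"hemisphere"`` (semi-axes all equal ``radius``) or
    ``"half_ellipsoid"`` with semi-axes ``a``, ``b`` (in-plane) and ``c``
    (height). ``theta_a_deg`` is the nominal apex tilt used to derive the
    shear (the exact inclination ground truth is computed analytically;
    use :meth:`from_targets` to hit requested values exactly), and
    ``theta_f_deg`` is the aneurysm-vessel angle realised by the centerline
    dip. Undulation is a radial cosine ripple; ``daughter`` adds a Gaussian
    bleb — both leave the neck contour untouched but void the height/angle
    ground truths.
    """

    shape: str = "half_ellipsoid"
    radius: float = 3.0
    a: float = 2.8
    b: float = 2.8
    c: float = 4.5
    theta_a_deg: float = 90.0
    theta_f_deg: float = 90.0
    undulation_amplitude: float = 0.0  # mm
    undulation_frequency: int = 6  # azimuthal bump count
    daughter: Optional[dict] = None  # {azimuth_deg, elevation_deg, radius_mm, width_rad?}
    vessel_radius: float = 1.75
    refinement: int = 5
    seed: int = 0

    def semi_axes(self) -> tuple[float, float, float]:
        if self.shape == "hemisphere":
            return self.radius, self.radius, self.radius
        if self.shape == "half_ellipsoid":
            return self.a, self.b, self.c
        raise ValidationError(f"unknown sac shape {self.shape!r}")

    def shear(self) -> float:
        if abs(self.theta_a_deg - 90.0) < 1e-12:
            return 0.0
        return -1.0 / math.tan(math.radians(self.theta_a_deg))

    def validate(self) -> "SacSpec":
        a, b, c = self.semi_axes()
        if min(a, b, c) <= 0 or self.vessel_radius <= 0:
            raise ValidationError("all dimensions must be positive")
        if self.undulation_amplitude < 0 or self.undulation_amplitude >= min(a, b, c) / 2:
            raise ValidationError(
                "undulation amplitude must be in [0, min_semi_axis / 2) to avoid self-intersection"
            )
        if not (0.0 < self.theta_a_deg < 180.0):
            raise ValidationError("theta_a_deg must lie in (0, 180)")
        if self.refinement < 1:
            raise ValidationError("refinement must be >= 1")
        return self

    @classmethod
    def from_targets(
        cls,
        hmax: float,
        dneck: float,
        dvessel: float,
        theta_a_deg: float = 90.0,
        theta_f_deg: float = 90.0,
        b_ratio: float = 1.0,
        refinement: int = 5,
        seed: int = 0,
    ) -> "SacSpec":
        """Solve the shear construction so the ground-truth Hmax, Dneck,
        Dvessel, thetaA and thetaF equal the requested values exactly.

        Closed form: with phi = 180 deg - thetaA the in-plane angle of the
        sac axis and T = tan(phi), requiring the farthest-point direction of
        N to lie along phi at distance Hmax fixes

            c^2 = T^2 Hmax^4 / (Hmax^2 (1 + T^2) - a^2),
            q   = (Hmax^2 - c^2) T / c,        shear = q / c.

        Raises when the request is infeasible (axis not dominant, or the
        vessel dip |180 - thetaF - thetaA| >= 90).
        """
        a = dneck / 2.0
        b = a * b_ratio
        if hmax <= 1.02 * max(a, b):
            raise ValidationError("Hmax must exceed the in-plane semi-axes by a clear margin")
        if abs(theta_a_deg - 90.0) < 1e-12:
            c, q = hmax, 0.0
        else:
            phi = math.radians(180.0 - theta_a_deg)
            T = math.tan(phi)
            denom = hmax**2 * (1.0 + T * T) - a * a
            if denom <= 0:
                raise ValidationError("requested thetaA too shallow for this Hmax/Dneck")
            c = math.sqrt(T * T * hmax**4 / denom)
            q = (hmax**2 - c * c) * T / c
        if a * c >= 0.98 * hmax**2:
            raise ValidationError("requested shape has no dominant axis (a*c close to Hmax^2)")
        gamma = theta_f_deg - theta_a_deg
        if abs(gamma) >= 89.0:
            raise ValidationError(
                f"theta_f={theta_f_deg}, theta_a={theta_a_deg} infeasible: "
                "|thetaF - thetaA| must be < 89"
            )
        theta_a_nominal = 180.0 - math.degrees(math.atan2(c, q))
        spec = cls(
            shape="half_ellipsoid",
            a=a,
            b=b,
            c=c,
            theta_a_deg=theta_a_nominal,
            theta_f_deg=theta_f_deg,
            vessel_radius=dvessel / 2.0,
            refinement=refinement,
            seed=seed,
        )
        hm, axis, dominant = _axis_analysis(a, b, c, spec.shear())
        if not dominant:
            raise ValidationError("requested shape has no dominant sac axis")
        assert abs(hm - hmax) < 1e-6 * hmax
        return spec


@dataclass
class FlowSpec:
    """Parameters of one synthetic pulsatile WSS field.

    ``mean_pa`` and ``osc_pa`` may be scalars or per-vertex arrays; direction
    reversal (nonzero OSI) occurs exactly when osc_pa > mean_pa.
    """

    period: float = 1.0  # s, 60 bpm cycle
    samples_per_cycle: int = 200
    mean_pa: float | np.ndarray = 1.5
    osc_pa: float | np.ndarray = 0.0
    n_cycles: int = 1
    random_phase: bool = False  # per-vertex phase offsets (cycle averages unchanged)
    seed: int = 0

    def validate(self) -> "FlowSpec":
        if self.period <= 0:
            raise ValidationError("period must be positive")
        if self.samples_per_cycle < 8:
            raise ValidationError("need at least 8 samples per cycle")
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        if np.any(np.asarray(self.mean_pa) < 0) or np.any(np.asarray(self.osc_pa) < 0):
            raise ValidationError("mean_pa and osc_pa must be non-negative")
        return self


# ---------------------------------------------------------------------------
# sac geometry
# ---------------------------------------------------------------------------

def _hemisphere_grid(refinement: int):
    """(theta, phi, unit_points, faces) lat-long grid on the unit upper
    hemisphere; ring 0 is the equator, the apex is a single final vertex."""
    n_theta = 4 * 2**refinement
    n_phi = 2**refinement
    theta = 2.0 * math.pi * np.arange(n_theta) / n_theta
    phi_rings = (math.pi / 2.0) * np.arange(n_phi) / n_phi
    tt, pp = np.meshgrid(theta, phi_rings, indexing="xy")
    theta_flat = np.concatenate([tt.ravel(), [0.0]])
    phi_flat = np.concatenate([pp.ravel(), [math.pi / 2.0]])

    faces = []
    idx = lambda j, i: j * n_theta + (i % n_theta)  # noqa: E731
    for j in range(n_phi - 1):
        for i in range(n_theta):
            v00, v01 = idx(j, i), idx(j, i + 1)
            v10, v11 = idx(j + 1, i), idx(j + 1, i + 1)
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
    apex = n_phi * n_theta
    for i in range(n_theta):
        faces.append([idx(n_phi - 1, i), idx(n_phi - 1, i + 1), apex])
    unit = np.column_stack(
        [
            np.cos(phi_flat) * np.cos(theta_flat),
            np.cos(phi_flat) * np.sin(theta_flat),
            np.sin(phi_flat),
        ]
    )
    return theta_flat, phi_flat, unit, np.asarray(faces, dtype=np.int64)


def make_sac(spec: SacSpec) -> AneurysmGeometry:
    """Build a synthetic aneurysm geometry with ground truth in
    ``metadata["truth"]``.

    The geometry lives in construction coordinates: neck plane z = 0 with
    normal +z, neck centroid at the origin, parent flow running toward +x in
    projection. Apply :func:`transform_geometry` for rigid placements.
    """
    spec.validate()
    a, b, c = spec.semi_axes()
    theta, phi, unit, faces = _hemisphere_grid(spec.refinement)
    n_theta = 4 * 2**spec.refinement

    pts = unit * np.array([a, b, c])

    # radial bumps, pinned to zero at both the neck ring and the apex
    smooth = spec.undulation_amplitude == 0.0 and spec.daughter is None
    offset = np.zeros(len(pts))
    if spec.undulation_amplitude > 0:
        offset += spec.undulation_amplitude * np.sin(2.0 * phi) * np.cos(
            spec.undulation_frequency * theta
        )
    if spec.daughter is not None:
        d = spec.daughter
        az = math.radians(d["azimuth_deg"])
        el = math.radians(d["elevation_deg"])
        center = np.array([math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)])
        width = d.get("width_rad", 0.35)
        psi = np.arccos(np.clip(unit @ center, -1.0, 1.0))
        offset += d["radius_mm"] * np.exp(-((psi / width) ** 2)) * np.sin(phi)
    if np.any(offset != 0.0):
        radial = np.linalg.norm(pts, axis=1)
        pts = pts * (1.0 + offset / radial)[:, None]

    # tilt the main axis with a z-preserving, volume-preserving shear
    shear = spec.shear()
    pts[:, 0] += shear * pts[:, 2]

    hmax_true, axis, dominant = _axis_analysis(a, b, c, shear)
    theta_a_true = math.degrees(math.acos(float(np.clip(-axis[0], -1.0, 1.0))))

    sac = TriSurface(pts, faces)
    # fix winding so the consistently cap-closed surface is outward-oriented
    loop = sac.boundary_loops()[0]
    cap = np.column_stack([np.full(len(loop), len(pts), dtype=np.int64), np.roll(loop, -1), loop])
    closed_test = TriSurface(
        np.vstack([pts, pts[loop].mean(axis=0)[None, :]]), np.vstack([faces, cap])
    )
    if closed_test.signed_volume() < 0:
        sac = TriSurface(pts, faces[:, ::-1])
    loop_ring = np.arange(n_theta, dtype=np.int64)

    neck = NeckAnnotation(
        plane_point=np.zeros(3),
        plane_normal=np.array([0.0, 0.0, 1.0]),
        contour=pts[loop_ring].copy(),
    )

    # straight centerline whose dip angle gamma realises thetaF against the
    # true (analytic) sac axis; without a dominant axis (e.g. hemisphere) the
    # nominal tilt is used and no angle truth is claimed
    theta_a_ref = theta_a_true if dominant else spec.theta_a_deg
    gamma_deg = spec.theta_f_deg - theta_a_ref
    if abs(gamma_deg) >= 89.0:
        raise ValidationError(
            f"theta_f={spec.theta_f_deg} infeasible for true thetaA={theta_a_true:.2f}: "
            "|thetaF - thetaA| must be < 89"
        )
    gamma = math.radians(gamma_deg)
    tangent = np.array([math.cos(gamma), 0.0, math.sin(gamma)])
    r_v = spec.vessel_radius
    anchor = np.array([0.0, 0.0, -r_v / math.cos(gamma)])
    half_len = max(10.0, 4.0 * r_v)
    s = np.linspace(-half_len, half_len, 81)
    parent = Centerline(
        points=anchor + s[:, None] * tangent,
        radii=np.full(len(s), r_v),
        flow_direction="forward",
    )

    truth: dict = {
        "H": c,
        "Dneck": 2.0 * max(a, b),
        "Dvessel": 2.0 * r_v,
    }
    if smooth:
        truth["V"] = 2.0 / 3.0 * math.pi * a * b * c
        if dominant:
            truth["Hmax"] = hmax_true
            truth["thetaA"] = theta_a_true
            truth["thetaF"] = spec.theta_f_deg
    return AneurysmGeometry(sac=sac, neck=neck, parent=parent, metadata={"truth": truth, "spec": spec})


def transform_geometry(
    geom: AneurysmGeometry, rotation: np.ndarray, translation: np.ndarray
) -> AneurysmGeometry:
    """Rigidly move a geometry (rotation must be a proper rotation matrix)."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
        raise ValidationError("rotation must be a proper orthogonal matrix")
    sac = TriSurface(geom.sac.vertices @ R.T + t, geom.sac.faces.copy())
    neck = NeckAnnotation(
        plane_point=R @ geom.neck.plane_point + t,
        plane_normal=R @ geom.neck.plane_normal,
        contour=geom.neck.contour @ R.T + t,
    )
    parent = None
    if geom.parent is not None:
        parent = Centerline(
            geom.parent.points @ R.T + t, geom.parent.radii.copy(), geom.parent.flow_direction
        )
    return AneurysmGeometry(sac=sac, neck=neck, parent=parent, metadata=dict(geom.metadata))


def sample_sac_specs(n: int, seed: int, refinement: int = 5) -> list[SacSpec]:
    """Seeded smooth sac specs spanning the measured parameter ranges
    (Hmax 3-8 mm, Dneck 5-7.5 mm, Dvessel 3-4.3 mm, varied angles), built
    with :meth:`SacSpec.from_targets` so truth values match the draws."""
    rng = np.random.default_rng(seed)
    specs: list[SacSpec] = []
    while len(specs) < n:
        dneck = rng.uniform(5.0, 7.5)
        theta_a = rng.uniform(70.0, 125.0)
        hmax = rng.uniform(max(3.0, 1.3 * dneck / 2.0), 8.0)
        theta_f = rng.uniform(max(theta_a - 85.0, 60.0), min(theta_a + 85.0, 160.0))
        try:
            spec = SacSpec.from_targets(
                hmax=hmax,
                dneck=dneck,
                dvessel=rng.uniform(3.0, 4.3),
                theta_a_deg=theta_a,
                theta_f_deg=theta_f,
                b_ratio=rng.uniform(0.85, 1.0),
                refinement=refinement,
                seed=int(rng.integers(2**31)),
            )
        except ValidationError:
            continue
        specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# WSS fields
# ---------------------------------------------------------------------------

def _vertex_tangents(surface: TriSurface, seed: int) -> np.ndarray:
    """A deterministic unit tangent per vertex (perpendicular to the vertex
    normal)."""
    mesh = surface.as_trimesh()
    normals = np.asarray(mesh.vertex_normals, dtype=float)
    rng = np.random.default_rng(seed)
    helper = rng.standard_normal(3)
    helper /= np.linalg.norm(helper)
    tang = np.cross(normals, helper)
    norms = np.linalg.norm(tang, axis=1)
    bad = norms < 1e-8
    if bad.any():  # helper parallel to some normal: fall back to a second axis
        helper2 = np.array([helper[1], helper[2], helper[0]])
        tang[bad] = np.cross(normals[bad], helper2)
        norms = np.linalg.norm(tang, axis=1)
        if np.any(norms < 1e-8):
            raise ValidationError("degenerate vertex normal; cannot build tangent directions")
    return tang / norms[:, None]


def closed_form_tawss_osi(mean_pa, osc_pa) -> tuple[np.ndarray, np.ndarray]:
    """Exact cycle averages of |m + A sin(2 pi t / T)|.

    TAWSS = m and OSI = 0 when m >= A; otherwise, with alpha = arcsin(m/A),
    TAWSS = (2/pi)(A cos alpha + m alpha) and OSI = (1 - m/TAWSS)/2.
    """
    m = np.atleast_1d(np.asarray(mean_pa, dtype=float))
    A = np.broadcast_to(np.atleast_1d(np.asarray(osc_pa, dtype=float)), m.shape).astype(float)
    tawss = m.copy()
    osc = A > m
    if osc.any():
        alpha = np.arcsin(m[osc] / A[osc])
        tawss[osc] = (2.0 / math.pi) * (A[osc] * np.cos(alpha) + m[osc] * alpha)
    osi = np.zeros_like(m)
    pos = tawss > 0
    osi[pos & osc] = 0.5 * (1.0 - m[pos & osc] / tawss[pos & osc])
    return tawss, osi


def make_wss_series(surface: TriSurface, spec: FlowSpec) -> WSSField:
    """Analytic pulsatile WSS series with closed-form TAWSS/OSI in
    ``field.metadata``.

    The field spans ``n_cycles`` periods (endpoint inclusive) with per-vertex
    vectors (m + A sin(2 pi t/T + phase)) d along fixed tangent directions d.
    """
    spec.validate()
    nv = len(surface.vertices)
    m = np.broadcast_to(np.atleast_1d(np.asarray(spec.mean_pa, dtype=float)), (nv,)).copy()
    A = np.broadcast_to(np.atleast_1d(np.asarray(spec.osc_pa, dtype=float)), (nv,)).copy()
    d = _vertex_tangents(surface, spec.seed)
    phase = np.zeros(nv)
    if spec.random_phase:
        phase = np.random.default_rng(spec.seed).uniform(0.0, 2.0 * math.pi, nv)

    n = spec.samples_per_cycle * spec.n_cycles
    times = np.linspace(0.0, spec.n_cycles * spec.period, n + 1)
    mag = m[None, :] + A[None, :] * np.sin(
        2.0 * math.pi * times[:, None] / spec.period + phase[None, :]
    )
    vectors = mag[:, :, None] * d[None, :, :]
    field = WSSField(surface=surface, times=times, vectors=vectors)
    tawss_cf, osi_cf = closed_form_tawss_osi(m, A)
    field.metadata = {"tawss": tawss_cf, "osi": osi_cf, "spec": spec}  # type: ignore[attr-defined]
    field.validate()
    return field


# ---------------------------------------------------------------------------
# Monte-Carlo volume oracles
# ---------------------------------------------------------------------------

def _assert_closed(surface: TriSurface) -> None:
    edges = np.sort(
        np.concatenate(
            [surface.faces[:, [0, 1]], surface.faces[:, [1, 2]], surface.faces[:, [2, 0]]]
        ),
        axis=1,
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts != 2):
        raise ValidationError("surface is not closed (boundary or non-manifold edges present)")


def _points_inside(surface: TriSurface, pts: np.ndarray, n_grid: int = 64) -> np.ndarray:
    """Vectorised z-ray parity inside test with a 2D triangle grid.

    Independent of the divergence-theorem volume path: casts a +z ray from
    each point and counts triangle crossings.
    """
    V, F = surface.vertices, surface.faces
    tri = V[F]
    xy_min = V[:, :2].min(axis=0)
    extent = np.maximum(V[:, :2].max(axis=0) - xy_min, 1e-12)
    cell = extent / n_grid

    t2 = tri[:, :, :2]
    lo = np.clip(np.floor((t2.min(axis=1) - xy_min) / cell).astype(int), 0, n_grid - 1)
    hi = np.clip(np.floor((t2.max(axis=1) - xy_min) / cell).astype(int), 0, n_grid - 1)
    buckets: dict[int, list[int]] = {}
    for k in range(len(tri)):
        for cx in range(lo[k, 0], hi[k, 0] + 1):
            for cy in range(lo[k, 1], hi[k, 1] + 1):
                buckets.setdefault(cx * n_grid + cy, []).append(k)

    pc = np.floor((pts[:, :2] - xy_min) / cell).astype(int)
    in_bbox = (pc >= 0).all(axis=1) & (pc < n_grid).all(axis=1)
    cid = np.where(in_bbox, pc[:, 0] * n_grid + pc[:, 1], -1)

    inside = np.zeros(len(pts), dtype=bool)
    order = np.argsort(cid, kind="stable")
    sorted_cid = cid[order]
    boundaries = np.flatnonzero(np.diff(sorted_cid)) + 1
    for grp in np.split(order, boundaries):
        c = int(cid[grp[0]])
        if c < 0 or c not in buckets:
            continue
        tidx = np.asarray(buckets[c])
        T = tri[tidx]  # (t, 3, 3)
        A2, B2, C2 = T[:, 0, :2], T[:, 1, :2], T[:, 2, :2]
        v0, v1 = B2 - A2, C2 - A2
        den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
        ok = np.abs(den) > 1e-14  # skip triangles vertical to the ray
        if not ok.any():
            continue
        T, v0, v1, den, A2 = T[ok], v0[ok], v1[ok], den[ok], A2[ok]
        P = pts[grp]
        vp = P[:, None, :2] - A2[None, :, :]  # (p, t, 2)
        u = (vp[:, :, 0] * v1[None, :, 1] - vp[:, :, 1] * v1[None, :, 0]) / den[None, :]
        v = (v0[None, :, 0] * vp[:, :, 1] - v0[None, :, 1] * vp[:, :, 0]) / den[None, :]
        hit2d = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        z_int = (1.0 - u - v) * T[None, :, 0, 2] + u * T[None, :, 1, 2] + v * T[None, :, 2, 2]
        crossings = (hit2d & (z_int > P[:, None, 2])).sum(axis=1)
        inside[grp] = crossings % 2 == 1
    return inside


def mc_volume_oracle(
    surface: TriSurface, n_samples: int = 1_000_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo volume of a closed surface by bounding-box rejection
    sampling with a z-ray parity inside test.

    Returns (estimate, standard error) in mm^3.
    """
    if n_samples < 10_000:
        raise ValidationError("use at least 1e4 samples for a meaningful estimate")
    _assert_closed(surface)
    rng = np.random.default_rng(seed)
    lo = surface.vertices.min(axis=0)
    hi = surface.vertices.max(axis=0)
    box_vol = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    hits = int(_points_inside(surface, pts).sum())
    p = hits / n_samples
    return box_vol * p, box_vol * math.sqrt(max(p * (1.0 - p), 0.0) / n_samples)


def mc_hull_volume_oracle(
    points: np.ndarray, n_samples: int = 1_000_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo convex-hull volume by rejection sampling against the
    hull's half-space inequalities. Returns (estimate, standard error)."""
    if n_samples < 10_000:
        raise ValidationError("use at least 1e4 samples for a meaningful estimate")
    hull = ConvexHull(np.asarray(points, dtype=float))
    eq = hull.equations  # (f, 4): n . x + d <= 0 inside
    rng = np.random.default_rng(seed)
    lo = hull.points.min(axis=0)
    hi = hull.points.max(axis=0)
    box_vol = float(np.prod(hi - lo))
    hits = 0
    chunk, fblock = 20_000, 1_024  # bounded memory: chunk x fblock working set
    for start in range(0, n_samples, chunk):
        pts = rng.uniform(lo, hi, size=(min(chunk, n_samples - start), 3))
        alive = np.ones(len(pts), dtype=bool)
        for fs in range(0, len(eq), fblock):
            sub = eq[fs : fs + fblock]
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            val = pts[idx] @ sub[:, :3].T + sub[:, 3][None, :]
            alive[idx] = (val <= 1e-9).all(axis=1)
        hits += int(alive.sum())
    p = hits / n_samples
    return box_vol * p, box_vol * math.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
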