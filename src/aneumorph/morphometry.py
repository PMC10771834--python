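"""Morphological parameters of a saccular aneurysm.

Given a sac surface open along an annotated neck contour and a parent-vessel
centerline, this module measures the raw quantities

    Hmax   max distance from the neck-contour centroid to the sac (mm)
    H      perpendicular height above the neck plane (mm)
    Dmiddle  largest cross-section width parallel to the neck plane (mm)
    Dneck  neck-plane diameter (mm)
    Dvessel  local parent-artery diameter near the neck (mm)
    V, S   sac volume (closed by a neck cap) and sac surface area
    Vch, Sch  convex-hull volume and (cap-free) hull area

and the derived indices

    AR  = H / Dneck                 aspect ratio
    SR  = Hmax / Dvessel            size ratio
    UI  = 1 - V / Vch               undulation index
    EI  = 1 - (18*pi)^(1/3) Vch^(2/3) / Sch    ellipticity index
    NSI = 1 - (18*pi)^(1/3) V^(2/3)  / S       non-sphericity index

together with the aneurysm-vessel angle thetaF (sac main axis vs the
proximal vessel direction) and the inclination angle thetaA (sac main axis
vs the proximal in-plane direction within the neck plane). Both angles are
referenced proximally, so 90 deg means perpendicular and values above 90
mean a distal (downstream) lean.

The neck cap used to close the sac for V is a triangle fan from the contour
centroid; its area is excluded from S, and hull facets lying in the neck
plane are excluded from Sch. With that convention a hemispherical sac has
UI = EI = NSI = 0 up to mesh-refinement error.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .types import (
    AneurysmGeometry,
    Centerline,
    MorphometryResult,
    NeckAnnotation,
    TriSurface,
    ValidationError,
    plane_basis,
)

__all__ = [
    "height_max",
    "height_perp",
    "diameter_middle",
    "neck_diameter",
    "vessel_diameter",
    "sac_volume_area",
    "hull_volume_area",
    "undulation_index",
    "ellipticity_index",
    "nonsphericity_index",
    "vessel_angle",
    "inclination_angle",
    "aspect_ratio",
    "size_ratio",
    "close_with_cap",
    "compute_all",
]

_ISO = (18.0 * math.pi) ** (1.0 / 3.0)  # isoperimetric constant: zero for a hemisphere


# ---------------------------------------------------------------------------
# heights
# ---------------------------------------------------------------------------

def _farthest_vertex(geom: AneurysmGeometry) -> int:
    """Index of the sac vertex farthest from the neck-contour centroid.

    Ties are broken by lowest vertex index (np.argmax convention) so results
    are deterministic.
    """
    if len(geom.sac.vertices) == 0:
        raise ValidationError("empty sac surface")
    d = np.linalg.norm(geom.sac.vertices - geom.neck.centroid(), axis=1)
    return int(np.argmax(d))


def height_max(geom: AneurysmGeometry) -> float:
    """Maximum aneurysm height Hmax: farthest sac vertex from the neck centroid."""
    idx = _farthest_vertex(geom)
    return float(np.linalg.norm(geom.sac.vertices[idx] - geom.neck.centroid()))


def height_perp(geom: AneurysmGeometry) -> float:
    """Perpendicular height H: max signed distance from the neck plane."""
    if len(geom.sac.vertices) == 0:
        raise ValidationError("empty sac surface")
    return float(geom.neck.signed_distance(geom.sac.vertices).max())


# ---------------------------------------------------------------------------
# diameters
# ---------------------------------------------------------------------------

def _max_planar_width(points2d: np.ndarray) -> float:
    """Diameter of a 2D point set (max pairwise distance via its hull)."""
    if len(points2d) < 2:
        return 0.0
    pts = points2d
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear sets fall back to brute force
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def diameter_middle(geom: AneurysmGeometry, n_slices: int = 100) -> float:
    """Largest sac cross-section width on planes parallel to the neck plane.

    Slices with ``n_slices`` planes evenly spaced over (0, H) plus the neck
    contour itself; each slice contributes the maximum in-plane chord of its
    intersection curve.
    """
    if n_slices < 2:
        raise ValidationError("n_slices must be >= 2")
    H = height_perp(geom)
    normal = geom.neck.plane_normal
    u, v = plane_basis(normal)
    origin = np.asarray(geom.neck.plane_point, dtype=float)

    rel = geom.neck.contour - origin
    best = _max_planar_width(np.column_stack([rel @ u, rel @ v]))

    mesh = geom.sac.as_trimesh()
    heights = (np.arange(1, n_slices + 1) / (n_slices + 1)) * H
    found_any = False
    for h in heights:
        section = mesh.section(plane_origin=origin + h * normal, plane_normal=normal)
        if section is None or len(section.vertices) == 0:
            continue
        found_any = True
        rel = np.asarray(section.vertices) - origin
        w = _max_planar_width(np.column_stack([rel @ u, rel @ v]))
        best = max(best, w)
    if not found_any and best == 0.0:
        raise ValidationError("no slice plane intersects the sac")
    return best


def neck_diameter(neck: NeckAnnotation, mode: str = "max_width") -> float:
    """Neck diameter Dneck from the contour.

    ``max_width``: maximum pairwise distance between contour points (default).
    ``equivalent_area``: 2*sqrt(A/pi) of the in-plane contour polygon.
    """
    if len(neck.contour) < 3:
        raise ValidationError("neck contour needs at least 3 points")
    u, v = plane_basis(neck.plane_normal)
    rel = neck.contour - neck.plane_point
    pts2d = np.column_stack([rel @ u, rel @ v])
    if mode == "max_width":
        return _max_planar_width(pts2d)
    if mode == "equivalent_area":
        import shapely.geometry as sg

        area = sg.Polygon(pts2d).area
        if area <= 0:
            raise ValidationError("neck contour encloses no area")
        return 2.0 * math.sqrt(area / math.pi)
    raise ValidationError(f"unknown neck-diameter mode {mode!r}")


def _closest_point_on_polyline(line: Centerline, target: np.ndarray):
    """(arclength, point, tangent) of the closest approach to ``target``."""
    p = line.points
    a, b = p[:-1], p[1:]
    ab = b - a
    seg_len = np.linalg.norm(ab, axis=1)
    t = np.clip(np.einsum("ij,ij->i", target - a, ab) / seg_len**2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - target, axis=1)
    i = int(np.argmin(d))
    s0 = line.arclengths()[i] + t[i] * seg_len[i]
    tangent = ab[i] / seg_len[i]
    return s0, proj[i], tangent


def vessel_diameter(
    parent: Centerline,
    neck_centroid: np.ndarray,
    window_mm: Optional[float] = None,
) -> float:
    """Parent-artery diameter Dvessel near the neck.

    Twice the mean of centerline radii within ``window_mm`` (arclength) of the
    closest-approach point to the neck centroid. The default window is one
    local diameter (2x the radius at the closest point).
    """
    parent = parent.oriented().validate()
    s = parent.arclengths()
    s0, _, _ = _closest_point_on_polyline(parent, np.asarray(neck_centroid, dtype=float))
    # radius at closest approach, interpolated along arclength
    r0 = float(np.interp(s0, s, parent.radii))
    if window_mm is None:
        window_mm = 2.0 * r0
    if window_mm <= 0:
        raise ValidationError("vessel-diameter window must be positive")
    mask = np.abs(s - s0) <= window_mm
    if not mask.any():
        raise ValidationError("no centerline samples within the averaging window")
    return 2.0 * float(parent.radii[mask].mean())


# ---------------------------------------------------------------------------
# volumes and areas
# ---------------------------------------------------------------------------

def close_with_cap(geom: AneurysmGeometry) -> tuple[TriSurface, float]:
    """Close the open sac with a triangle fan from the contour centroid.

    Returns the closed, outward-oriented surface and the cap area. Raises if
    the sac boundary is not a single loop.
    """
    return geom.sac.fan_capped()


def sac_volume_area(geom: AneurysmGeometry) -> tuple[float, float]:
    """(V, S): divergence-theorem volume of the cap-closed sac and the sac
    surface area excluding the cap."""
    closed, _ = close_with_cap(geom)
    V = closed.signed_volume()
    if V <= 0:
        raise ValidationError("closed sac has non-positive volume")
    S = geom.sac.area()
    return V, S


def hull_volume_area(geom: AneurysmGeometry, plane_tol: float = 1e-6) -> tuple[float, float]:
    """(Vch, Sch): convex hull of sac + contour vertices.

    Sch excludes hull facets lying in the neck plane (all facet vertices
    within ``plane_tol`` mm of the plane), mirroring the cap exclusion in S.
    """
    points = np.vstack([geom.sac.vertices, geom.neck.contour])
    try:
        hull = ConvexHull(points)
    except Exception as exc:  # qhull rejects coplanar/degenerate input
        raise ValidationError(f"convex hull failed: {exc}") from exc
    Vch = float(hull.volume)
    d = np.abs((points - geom.neck.plane_point) @ geom.neck.plane_normal)
    on_plane = d < plane_tol
    tri = points[hull.simplices]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    facet_on_plane = on_plane[hull.simplices].all(axis=1)
    Sch = float(areas[~facet_on_plane].sum())
    return Vch, Sch


# ---------------------------------------------------------------------------
# shape indices
# ---------------------------------------------------------------------------

def undulation_index(V: float, Vch: float) -> float:
    """UI = 1 - V/Vch; zero for a convex sac."""
    if V <= 0 or Vch <= 0:
        raise ValidationError("V and Vch must be positive")
    if V > Vch * (1.0 + 1e-9):
        raise ValidationError(f"V = {V:.6g} exceeds hull volume Vch = {Vch:.6g}")
    return 1.0 - V / Vch


def ellipticity_index(Vch: float, Sch: float) -> float:
    """EI = 1 - (18*pi)^(1/3) Vch^(2/3) / Sch; zero for a hemispherical hull."""
    if Vch <= 0 or Sch <= 0:
        raise ValidationError("Vch and Sch must be positive")
    return 1.0 - _ISO * Vch ** (2.0 / 3.0) / Sch


def nonsphericity_index(V: float, S: float) -> float:
    """NSI = 1 - (18*pi)^(1/3) V^(2/3) / S; zero for a hemispherical sac."""
    if V <= 0 or S <= 0:
        raise ValidationError("V and S must be positive")
    return 1.0 - _ISO * V ** (2.0 / 3.0) / S


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def _sac_axis(geom: AneurysmGeometry) -> np.ndarray:
    """Unit sac main axis: neck-contour centroid -> farthest sac vertex."""
    apex = geom.sac.vertices[_farthest_vertex(geom)]
    axis = apex - geom.neck.centroid()
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValidationError("degenerate sac main axis (apex at neck centroid)")
    return axis / n


def _flow_tangent(geom: AneurysmGeometry) -> np.ndarray:
    if geom.parent is None:
        raise ValidationError("parent centerline required for vessel angles")
    parent = geom.parent.oriented().validate()
    _, _, tangent = _closest_point_on_polyline(parent, geom.neck.centroid())
    return tangent


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    c = float(np.clip(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0))
    return math.degrees(math.acos(c))


def vessel_angle(geom: AneurysmGeometry) -> float:
    """thetaF in [0, 180]: angle between the sac main axis and the proximal
    (upstream) vessel direction at the closest-approach point.

    Referenced proximally, like thetaA: a sac perpendicular to the vessel
    gives 90 deg and a downstream lean gives values above 90, matching the
    reported >90 values of downstream-pointing aneurysms.
    """
    return _angle_deg(-_flow_tangent(geom), _sac_axis(geom))


def inclination_angle(geom: AneurysmGeometry) -> float:
    """thetaA in [0, 180]: angle between the sac main axis and the proximal
    in-plane direction (the negated projection of the flow tangent onto the
    neck plane). 90 deg = axis along the plane normal; >90 leans distally."""
    tangent = _flow_tangent(geom)
    n = geom.neck.plane_normal
    in_plane = tangent - (tangent @ n) * n
    if np.linalg.norm(in_plane) < 1e-12:
        raise ValidationError("flow tangent is normal to the neck plane; thetaA undefined")
    proximal = -in_plane / np.linalg.norm(in_plane)
    return _angle_deg(proximal, _sac_axis(geom))


# ---------------------------------------------------------------------------
# ratios and the full panel
# ---------------------------------------------------------------------------

def aspect_ratio(H: float, Dneck: float) -> float:
    """AR = H / Dneck."""
    if Dneck <= 0:
        raise ValidationError("Dneck must be positive")
    return H / Dneck


def size_ratio(Hmax: float, Dvessel: float) -> float:
    """SR = Hmax / Dvessel."""
    if Dvessel <= 0:
        raise ValidationError("Dvessel must be positive")
    return Hmax / Dvessel


def compute_all(
    geom: AneurysmGeometry,
    n_slices: int = 100,
    neck_mode: str = "max_width",
    vessel_window_mm: Optional[float] = None,
) -> MorphometryResult:
    """Compute the full morphometric panel.

    Vessel-relative entries (Dvessel, SR, thetaF, thetaA) are None when the
    geometry carries no parent centerline.
    """
    geom.validate()
    Hmax = height_max(geom)
    H = height_perp(geom)
    Dmiddle = diameter_middle(geom, n_slices=n_slices)
    Dneck = neck_diameter(geom.neck, mode=neck_mode)
    V, S = sac_volume_area(geom)
    Vch, Sch = hull_volume_area(geom)
    result = MorphometryResult(
        Hmax=Hmax,
        H=H,
        Dmiddle=Dmiddle,
        Dneck=Dneck,
        V=V,
        S=S,
        Vch=Vch,
        Sch=Sch,
        UI=undulation_index(V, Vch),
        EI=ellipticity_index(Vch, Sch),
        NSI=nonsphericity_index(V, S),
        AR=aspect_ratio(H, Dneck),
    )
    if geom.parent is not None:
        result.Dvessel = vessel_diameter(geom.parent, geom.neck.centroid(), vessel_window_mm)
        result.SR = size_ratio(Hmax, result.Dvessel)
        result.thetaF = vessel_angle(geom)
        result.thetaA = inclination_angle(geom)
    return result
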