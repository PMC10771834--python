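"""Core domain containers for saccular-aneurysm morphometry and wall-shear
postprocessing.

All geometry is expressed in millimetres in a right-handed Cartesian frame;
wall shear stress (WSS) vectors are in pascal. Containers are thin dataclasses
around numpy arrays with explicit ``validate`` methods so that file readers and
generators can enforce the same invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

__all__ = [
    "ValidationError",
    "ConfigError",
    "TriSurface",
    "NeckAnnotation",
    "Centerline",
    "AneurysmGeometry",
    "WSSField",
    "MorphometryResult",
    "HemodynamicsResult",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented geometric/physical invariant."""


class ConfigError(ValueError):
    """Raised for unknown parameter names or malformed configuration."""


def _as_points(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError(f"{name} must be an (n, 3) array, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite coordinates")
    return arr


@dataclass
class TriSurface:
    """Triangulated surface: ``vertices`` (n, 3) in mm, ``faces`` (m, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices, "vertices")
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValidationError(f"faces must be (m, 3), got shape {self.faces.shape}")
        self.faces = self.faces.reshape(-1, 3)

    def validate(self) -> "TriSurface":
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise ValidationError("empty surface (no vertices or no faces)")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValidationError("face index out of range")
        if np.any(self.face_areas() <= 0.0):
            raise ValidationError("surface contains degenerate (zero-area) faces")
        return self

    # -- derived quantities -------------------------------------------------
    def triangle_corners(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangle_corners()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Divergence-theorem signed volume; positive for outward orientation."""
        tri = self.triangle_corners()
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex weights: one third of incident triangle areas."""
        w = np.zeros(len(self.vertices))
        np.add.at(w, self.faces.ravel(), np.repeat(self.face_areas() / 3.0, 3))
        return w

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(), process=False)

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex-index loops of boundary (single-face) edges.

        Each loop follows the direction the boundary edges carry in the face
        winding, so a cap wound opposite to a loop closes the surface with
        consistent orientation.
        """
        directed = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        undirected = np.sort(directed, axis=1)
        _, inverse, counts = np.unique(
            undirected, axis=0, return_inverse=True, return_counts=True
        )
        boundary = directed[counts[inverse] == 1]
        if len(boundary) == 0:
            return []
        nxt = {int(u): int(v) for u, v in boundary}
        if len(nxt) != len(boundary):
            raise ValidationError("non-manifold boundary (vertex with multiple outgoing edges)")
        loops: list[np.ndarray] = []
        seen: set[int] = set()
        for start in sorted(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                seen.add(cur)
                cur = nxt[cur]
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    def fan_capped(self) -> tuple["TriSurface", float]:
        """Close the single boundary loop with a triangle fan from its
        centroid, wound consistently with the existing faces; globally
        re-orient outward. Returns (closed surface, cap area)."""
        loops = self.boundary_loops()
        if len(loops) != 1:
            raise ValidationError(f"expected one boundary loop, found {len(loops)}")
        loop = loops[0]
        ring = self.vertices[loop]
        centroid = ring.mean(axis=0)
        nv = len(self.vertices)
        vertices = np.vstack([self.vertices, centroid[None, :]])
        # boundary runs with the sac winding; the cap traverses it backwards
        cap = np.column_stack(
            [np.full(len(loop), nv, dtype=np.int64), np.roll(loop, -1), loop]
        )
        closed = TriSurface(vertices, np.vstack([self.faces, cap]))
        if closed.signed_volume() < 0:
            closed = TriSurface(vertices, closed.faces[:, ::-1])
        cap_area = TriSurface(vertices, cap).area()
        return closed, cap_area

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.faces.copy())


@dataclass
class NeckAnnotation:
    """Neck plane (point + unit normal oriented toward the dome) and its
    ordered closed contour, all in mm."""

    plane_point: np.ndarray
    plane_normal: np.ndarray
    contour: np.ndarray

    PLANE_TOL = 1e-6  # mm, contour-on-plane tolerance

    def __post_init__(self) -> None:
        self.plane_point = np.asarray(self.plane_point, dtype=float).reshape(3)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float).reshape(3)
        self.contour = _as_points(self.contour, "contour")

    def validate(self) -> "NeckAnnotation":
        n = np.linalg.norm(self.plane_normal)
        if abs(n - 1.0) > 1e-9:
            raise ValidationError(f"plane_normal must be unit length (|n| = {n:.3e})")
        if len(self.contour) < 3:
            raise ValidationError("neck contour needs at least 3 points")
        d = (self.contour - self.plane_point) @ self.plane_normal
        if np.abs(d).max() > self.PLANE_TOL:
            raise ValidationError(
                f"contour departs from neck plane by {np.abs(d).max():.2e} mm"
            )
        if not self._is_simple():
            raise ValidationError("neck contour self-intersects in-plane")
        return self

    def _is_simple(self) -> bool:
        import shapely.geometry as sg

        u, v = plane_basis(self.plane_normal)
        rel = self.contour - self.plane_point
        ring = sg.LinearRing(np.column_stack([rel @ u, rel @ v]))
        return ring.is_simple and ring.is_valid

    def centroid(self) -> np.ndarray:
        return self.contour.mean(axis=0)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the plane, positive on the dome side."""
        return (np.atleast_2d(points) - self.plane_point) @ self.plane_normal


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (u, v) with u x v = normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


@dataclass
class Centerline:
    """Ordered parent-vessel centerline with local radii.

    ``points`` run proximal -> distal when ``flow_direction`` is ``"forward"``
    (set ``"reversed"`` when the stored order is distal -> proximal).
    """

    points: np.ndarray
    radii: np.ndarray
    flow_direction: str = "forward"

    def __post_init__(self) -> None:
        self.points = _as_points(self.points, "centerline points")
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)

    def validate(self) -> "Centerline":
        if len(self.points) < 2:
            raise ValidationError("centerline needs at least 2 points")
        if len(self.radii) != len(self.points):
            raise ValidationError("centerline radii length must match points")
        if np.any(self.radii <= 0):
            raise ValidationError("centerline radii must be positive")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValidationError("consecutive centerline points must be distinct")
        if self.flow_direction not in ("forward", "reversed"):
            raise ValidationError("flow_direction must be 'forward' or 'reversed'")
        return self

    def oriented(self) -> "Centerline":
        """Return a copy ordered proximal -> distal."""
        if self.flow_direction == "forward":
            return Centerline(self.points.copy(), self.radii.copy(), "forward")
        return Centerline(self.points[::-1].copy(), self.radii[::-1].copy(), "forward")

    def arclengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class AneurysmGeometry:
    """Sac surface (open along the neck) + neck annotation + parent centerline.

    ``parent`` may be None (morphometry then reports the vessel-relative
    quantities Dvessel, SR, thetaF, thetaA as missing). ``metadata`` carries
    generator ground truth for synthetic fixtures.
    """

    sac: TriSurface
    neck: NeckAnnotation
    parent: Optional[Centerline] = None
    metadata: dict = field(default_factory=dict)

    BOUNDARY_TOL = 1e-6  # mm

    def validate(self) -> "AneurysmGeometry":
        self.sac.validate()
        self.neck.validate()
        if self.parent is not None:
            self.parent.validate()
        d = self.neck.signed_distance(self.sac.vertices)
        if d.min() < -self.BOUNDARY_TOL:
            raise ValidationError(
                f"sac vertices cross the neck plane by {-d.min():.2e} mm"
            )
        loops = self.sac.boundary_loops()
        if len(loops) != 1:
            raise ValidationError(f"sac must have exactly one boundary loop, found {len(loops)}")
        ring = self.sac.vertices[loops[0]]
        # every boundary vertex must sit on the annotated contour
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(self.neck.contour).query(ring)
        if dist.max() > self.BOUNDARY_TOL:
            raise ValidationError(
                f"sac boundary departs from neck contour by {dist.max():.2e} mm"
            )
        return self

    def boundary_loop(self) -> np.ndarray:
        loops = self.sac.boundary_loops()
        if len(loops) != 1:
            raise ValidationError(f"expected one boundary loop, found {len(loops)}")
        return loops[0]


@dataclass
class WSSField:
    """Per-vertex WSS vector time series over (up to) one cardiac cycle.

    ``times`` in seconds, strictly increasing; ``vectors`` has shape
    (n_times, n_vertices, 3) in Pa.
    """

    surface: TriSurface
    times: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.vectors = np.asarray(self.vectors, dtype=float)

    def validate(self, period: Optional[float] = None) -> "WSSField":
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValidationError(f"vectors must be (n_times, n_vertices, 3), got {self.vectors.shape}")
        if self.vectors.shape[0] != len(self.times):
            raise ValidationError("vectors first axis must match number of times")
        if self.vectors.shape[1] != len(self.surface.vertices):
            raise ValidationError("vectors second axis must match surface vertex count")
        if len(self.times) and self.times[0] < 0:
            raise ValidationError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.isfinite(self.vectors).all():
            raise ValidationError("WSS vectors contain non-finite values")
        if period is not None and self.times[-1] - self.times[0] > period + 1e-9:
            raise ValidationError("time span exceeds one cycle period")
        return self

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_vertices(self) -> int:
        return len(self.surface.vertices)


# field name -> unit, in the order the report prints them
MORPHOMETRY_UNITS = {
    "Hmax": "mm",
    "H": "mm",
    "Dmiddle": "mm",
    "Dneck": "mm",
    "Dvessel": "mm",
    "V": "mm^3",
    "S": "mm^2",
    "Vch": "mm^3",
    "Sch": "mm^2",
    "thetaF": "deg",
    "thetaA": "deg",
    "AR": "",
    "SR": "",
    "UI": "",
    "EI": "",
    "NSI": "",
}


@dataclass
class MorphometryResult:
    """The printed geometric panel: raw measurements plus derived indices.

    Vessel-relative entries (Dvessel, SR, thetaF, thetaA) are None when the
    parent centerline is absent.
    """

    Hmax: float
    H: float
    Dmiddle: float
    Dneck: float
    V: float
    S: float
    Vch: float
    Sch: float
    UI: float
    EI: float
    NSI: float
    AR: float
    Dvessel: Optional[float] = None
    SR: Optional[float] = None
    thetaF: Optional[float] = None
    thetaA: Optional[float] = None

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in MORPHOMETRY_UNITS}


@dataclass
class HemodynamicsResult:
    """Per-vertex TAWSS/OSI/RRT maps plus the sac-averaged summaries."""

    tawss_map: np.ndarray  # Pa
    osi_map: np.ndarray  # dimensionless, [0, 0.5]
    rrt_map: np.ndarray  # 1/Pa
    OSI: float
    RRT: float
    NWSS: Optional[float] = None  # sac mean TAWSS / parent mean TAWSS

    def to_dict(self) -> dict:
        return {"NWSS": self.NWSS, "OSI": self.OSI, "RRT": self.RRT}
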