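"""Wall-shear-stress postprocessing: TAWSS, OSI, RRT and sac summaries.

With tau_w(t) the per-vertex WSS vector over one cardiac cycle sampled on a
(possibly non-uniform) time grid, trapezoidal quadrature over the sampled
span T gives

    TAWSS = (1/T) integral |tau_w| dt
    OSI   = 1/2 (1 - |integral tau_w dt| / integral |tau_w| dt)
    RRT   = 1 / ((1 - 2 OSI) TAWSS)  ==  1 / |(1/T) integral tau_w dt|

The RRT identity (it equals the reciprocal magnitude of the time-mean WSS
vector) is exact and is used as an internal cross-check. OSI lies in
[0, 0.5]; a vertex whose WSS vanishes for the whole cycle gets OSI = 0 with a
warning, and RRT is capped (default 1e6 1/Pa) where the time-mean vector
vanishes. Sac averages are area-weighted by default (vertex weight = one
third of incident triangle areas, exact for linear fields); an unweighted
vertex mean is available for comparison with tools that report it.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .types import HemodynamicsResult, TriSurface, ValidationError, WSSField

__all__ = [
    "select_cycle",
    "tawss",
    "osi",
    "rrt",
    "sac_average",
    "nwss",
    "compute_summary",
    "RRT_CAP",
]

RRT_CAP = 1e6  # 1/Pa, guard for fully oscillatory vertices (OSI -> 0.5)


def select_cycle(series: WSSField, period: float, cycle_index: int) -> WSSField:
    """Extract one cardiac cycle from a multi-cycle series.

    Returns samples with times in [(k-1) T, k T] for k = ``cycle_index``
    (1-based), re-zeroed to start at 0. Typical use selects the last simulated
    cycle, after start-up transients have decayed.
    """
    if period <= 0:
        raise ValidationError("period must be positive")
    if cycle_index < 1:
        raise ValidationError("cycle_index is 1-based and must be >= 1")
    series.validate()
    t0, t1 = (cycle_index - 1) * period, cycle_index * period
    if series.times[-1] < t1 - 1e-9:
        raise ValidationError(
            f"series spans {series.times[-1]:.6g} s, cycle {cycle_index} "
            f"requires coverage up to {t1:.6g} s"
        )
    mask = (series.times >= t0 - 1e-9) & (series.times <= t1 + 1e-9)
    return WSSField(
        surface=series.surface,
        times=series.times[mask] - t0,
        vectors=series.vectors[mask],
    )


def _integrals(field: WSSField) -> tuple[np.ndarray, np.ndarray, float]:
    """(integral |tau| dt, integral tau dt, span) per vertex."""
    field.validate()
    if field.n_times < 2:
        raise ValidationError("need at least 2 time samples")
    t = field.times
    span = float(t[-1] - t[0])
    mag = np.linalg.norm(field.vectors, axis=2)  # (nt, nv)
    int_mag = np.trapezoid(mag, t, axis=0)
    int_vec = np.trapezoid(field.vectors, t, axis=0)  # (nv, 3)
    return int_mag, int_vec, span


def tawss(field: WSSField) -> np.ndarray:
    """Time-averaged WSS magnitude per vertex (Pa)."""
    int_mag, _, span = _integrals(field)
    return int_mag / span


def osi(field: WSSField) -> np.ndarray:
    """Oscillatory shear index per vertex, in [0, 0.5].

    Vertices with identically zero WSS over the cycle are degenerate; they
    get OSI = 0 with a warning.
    """
    int_mag, int_vec, _ = _integrals(field)
    mean_mag = np.linalg.norm(int_vec, axis=1)
    out = np.zeros_like(int_mag)
    ok = int_mag > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} vertices have zero WSS over the cycle; OSI set to 0",
            stacklevel=2,
        )
    out[ok] = 0.5 * (1.0 - mean_mag[ok] / int_mag[ok])
    return np.clip(out, 0.0, 0.5)


def rrt(field: WSSField, cap: float = RRT_CAP) -> np.ndarray:
    """Relative residence time per vertex (1/Pa), capped at ``cap``.

    Equals 1 / |time-mean WSS vector|; the cap handles fully oscillatory
    vertices where the mean vector vanishes (OSI = 0.5).
    """
    tw = tawss(field)
    oi = osi(field)
    denom = (1.0 - 2.0 * oi) * tw
    out = np.full_like(tw, cap)
    ok = denom > 1.0 / cap
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} fully-oscillatory vertices; RRT capped at {cap:g} 1/Pa",
            stacklevel=2,
        )
    out[ok] = 1.0 / denom[ok]
    return out


def sac_average(values: np.ndarray, surface: TriSurface, weighted: bool = True) -> float:
    """Surface average of a per-vertex scalar map.

    ``weighted`` (default) uses barycentric area weights — one third of each
    vertex's incident triangle areas — which integrates linear fields exactly;
    otherwise a plain vertex mean.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    if len(values) != len(surface.vertices):
        raise ValidationError(
            f"map length {len(values)} != vertex count {len(surface.vertices)}"
        )
    if not weighted:
        return float(values.mean())
    w = surface.vertex_areas()
    total = w.sum()
    if total <= 0:
        raise ValidationError("surface has zero area")
    return float((w * values).sum() / total)


def nwss(sac_field: WSSField, parent_field: WSSField, weighted: bool = True) -> float:
    """Normalized WSS: sac-averaged TAWSS over parent-artery-averaged TAWSS."""
    sac_mean = sac_average(tawss(sac_field), sac_field.surface, weighted)
    parent_mean = sac_average(tawss(parent_field), parent_field.surface, weighted)
    if parent_mean <= 0:
        raise ValidationError("parent-artery mean TAWSS is zero; NWSS undefined")
    return sac_mean / parent_mean


def compute_summary(
    sac_field: WSSField,
    parent_field: Optional[WSSField] = None,
    weighted: bool = True,
    cap: float = RRT_CAP,
) -> HemodynamicsResult:
    """Full hemodynamic panel: per-vertex maps plus sac-averaged OSI, RRT and
    (when a parent field is given) NWSS."""
    tw = tawss(sac_field)
    oi = osi(sac_field)
    rt = rrt(sac_field, cap=cap)
    result = HemodynamicsResult(
        tawss_map=tw,
        osi_map=oi,
        rrt_map=rt,
        OSI=sac_average(oi, sac_field.surface, weighted),
        RRT=sac_average(rt, sac_field.surface, weighted),
    )
    if parent_field is not None:
        result.NWSS = nwss(sac_field, parent_field, weighted)
    return result
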