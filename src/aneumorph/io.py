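"""Readers and writers: surface meshes, neck/centerline annotations, WSS
series, and the parameter report.

Surfaces go through trimesh for STL (ASCII and binary), OBJ and PLY; VTK XML
polydata (.vtp, ASCII) is read and written by a small built-in codec since
the format is a thin XML wrapper around points / connectivity / point-data
arrays. Loaded surfaces are cleaned: duplicate vertices merged within 1e-9
mm, degenerate faces dropped, and closed surfaces re-oriented outward
(positive signed volume).

Annotations (neck plane, contour, centerline) travel in a JSON sidecar with
keys ``plane_point``, ``plane_normal``, ``contour``, ``centerline_points``,
``centerline_radii``; units are millimetres throughout and no rescaling is
performed. WSS series are either a plain-text manifest (``time,file`` per
line) of .vtp snapshots carrying a 3-component ``wss`` point array in Pa, or
one tabular CSV with columns time, vertex_id, wx, wy, wz.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import os
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh

from .types import (
    AneurysmGeometry,
    Centerline,
    NeckAnnotation,
    TriSurface,
    ValidationError,
    WSSField,
)

__all__ = [
    "read_surface",
    "write_surface",
    "read_annotation",
    "write_annotation",
    "load_geometry",
    "read_wss_series",
    "write_wss_series",
    "read_wss_table",
    "write_maps_vtp",
    "write_report",
    "REPORT_ROWS",
]

log = logging.getLogger("aneumorph")

_TRIMESH_FORMATS = {"stl": "stl", "stl_ascii": "stl_ascii", "obj": "obj", "ply": "ply"}
MERGE_TOL = 1e-9  # mm, duplicate-vertex merge radius
DEGENERATE_AREA = 1e-14  # mm^2


def _infer_format(path: str | Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("stl", "obj", "ply", "vtp"):
        return suffix
    raise ValidationError(f"cannot infer mesh format from {path!r}; pass format=")


def _clean(vertices: np.ndarray, faces: np.ndarray, origin: str) -> TriSurface:
    """Merge near-duplicate vertices, drop degenerate faces, orient outward."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise ValidationError(f"empty mesh in {origin}")
    key = np.round(vertices / MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged = len(vertices) - len(first)
    vertices = vertices[np.sort(first)]
    remap = np.empty(len(first), dtype=np.int64)
    remap[np.argsort(first)] = np.arange(len(first))
    faces = remap[inverse][faces]

    surf = TriSurface(vertices, faces)
    distinct = (
        (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    )
    good = distinct & (surf.face_areas() > DEGENERATE_AREA)
    dropped = int((~good).sum())
    surf = TriSurface(vertices, faces[good])
    # drop vertices no longer referenced (e.g. only by degenerate faces)
    used = np.zeros(len(vertices), dtype=bool)
    used[surf.faces.ravel()] = True
    if not used.all():
        remap = np.cumsum(used) - 1
        surf = TriSurface(vertices[used], remap[surf.faces])

    if not surf.boundary_loops() and surf.signed_volume() < 0:
        surf = TriSurface(surf.vertices, surf.faces[:, ::-1])
    log.info(
        "loaded %s: %d vertices, %d faces (%d merged, %d degenerate dropped)",
        origin,
        len(surf.vertices),
        len(surf.faces),
        merged,
        dropped,
    )
    return surf.validate()


def read_surface(path: str | Path, format: Optional[str] = None) -> TriSurface:
    """Read and clean a triangulated surface (stl, obj, ply or vtp)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"surface file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "vtp":
        vertices, faces, _ = _read_vtp(path)
    elif fmt in _TRIMESH_FORMATS:
        try:
            mesh = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
        except Exception as exc:
            raise OSError(f"failed to parse {path} as {fmt}: {exc}") from exc
        vertices, faces = np.asarray(mesh.vertices), np.asarray(mesh.faces)
    else:
        raise ValidationError(f"unsupported surface format {fmt!r}")
    return _clean(vertices, faces, str(path))


def write_surface(surface: TriSurface, path: str | Path, format: Optional[str] = None) -> None:
    """Write a surface as stl (binary), stl_ascii, obj, ply or vtp."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "vtp":
        _write_vtp(path, surface.vertices, surface.faces, {})
        return
    if fmt not in _TRIMESH_FORMATS:
        raise ValidationError(f"unsupported surface format {fmt!r}")
    export_type = _TRIMESH_FORMATS[fmt]
    data = trimesh.exchange.export.export_mesh(surface.as_trimesh(), None, file_type=export_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# minimal ASCII .vtp codec
# ---------------------------------------------------------------------------

def _read_vtp(path: Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise OSError(f"failed to parse {path} as vtp XML: {exc}") from exc
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise OSError(f"{path}: no PolyData Piece element")

    def _array(el: ET.Element) -> np.ndarray:
        if el.get("format", "ascii") != "ascii":
            raise ValidationError(f"{path}: only ascii-format vtp arrays are supported")
        tokens = (el.text or "").split()
        return np.asarray(tokens, dtype=float) if tokens else np.zeros(0)

    pts_el = piece.find("./Points/DataArray")
    if pts_el is None:
        raise OSError(f"{path}: missing Points array")
    vertices = _array(pts_el).reshape(-1, 3)

    faces = np.zeros((0, 3), dtype=np.int64)
    polys = piece.find("Polys")
    if polys is not None:
        conn = offs = None
        for el in polys.findall("DataArray"):
            if el.get("Name") == "connectivity":
                conn = _array(el).astype(np.int64)
            elif el.get("Name") == "offsets":
                offs = _array(el).astype(np.int64)
        if conn is not None and offs is not None and len(offs):
            tris = []
            start = 0
            for end in offs:
                poly = conn[start:end]
                for k in range(1, len(poly) - 1):  # fan-triangulate n-gons
                    tris.append([poly[0], poly[k], poly[k + 1]])
                start = end
            faces = np.asarray(tris, dtype=np.int64)

    point_data: dict[str, np.ndarray] = {}
    pd = piece.find("PointData")
    if pd is not None:
        for el in pd.findall("DataArray"):
            name = el.get("Name", "unnamed")
            ncomp = int(el.get("NumberOfComponents", "1"))
            arr = _array(el)
            point_data[name] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
    return vertices, faces, point_data


def _write_vtp(
    path: Path, vertices: np.ndarray, faces: np.ndarray, point_data: dict[str, np.ndarray]
) -> None:
    def fmt(arr: np.ndarray) -> str:
        flat = np.asarray(arr).ravel()
        if np.issubdtype(flat.dtype, np.integer):
            return " ".join(str(int(x)) for x in flat)
        return " ".join(format(float(x), ".17g") for x in flat)

    pd_blocks = []
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        ncomp = arr.shape[1] if arr.ndim > 1 else 1
        pd_blocks.append(
            f'    <DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{fmt(arr)}</DataArray>'
        )
    pd_xml = "\n".join(pd_blocks)
    n_pts, n_polys = len(vertices), len(faces)
    conn = fmt(np.asarray(faces, dtype=np.int64))
    offs = fmt(3 * (np.arange(n_polys, dtype=np.int64) + 1))
    content = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="1.0" byte_order="LittleEndian">
 <PolyData>
  <Piece NumberOfPoints="{n_pts}" NumberOfVerts="0" NumberOfLines="0" NumberOfStrips="0" NumberOfPolys="{n_polys}">
   <Points>
    <DataArray type="Float64" NumberOfComponents="3" format="ascii">{fmt(vertices)}</DataArray>
   </Points>
   <PointData>
{pd_xml}
   </PointData>
   <Polys>
    <DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>
    <DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>
   </Polys>
  </Piece>
 </PolyData>
</VTKFile>
"""
    Path(path).write_text(content)


def write_maps_vtp(surface: TriSurface, maps: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-vertex scalar maps (e.g. tawss/osi/rrt) as .vtp point data."""
    for name, arr in maps.items():
        if len(np.atleast_1d(arr)) != len(surface.vertices):
            raise ValidationError(f"map {name!r} length does not match vertex count")
    _write_vtp(Path(path), surface.vertices, surface.faces, maps)


# ---------------------------------------------------------------------------
# annotation sidecar
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> tuple[NeckAnnotation, Optional[Centerline]]:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"annotation file not found: {path}")
    data = json.loads(path.read_text())
    neck = NeckAnnotation(
        plane_point=np.asarray(data["plane_point"], dtype=float),
        plane_normal=np.asarray(data["plane_normal"], dtype=float),
        contour=np.asarray(data["contour"], dtype=float),
    ).validate()
    parent = None
    if data.get("centerline_points"):
        parent = Centerline(
            points=np.asarray(data["centerline_points"], dtype=float),
            radii=np.asarray(data["centerline_radii"], dtype=float),
            flow_direction=data.get("flow_direction", "forward"),
        ).validate()
    return neck, parent


def write_annotation(
    path: str | Path, neck: NeckAnnotation, parent: Optional[Centerline] = None
) -> None:
    data: dict = {
        "plane_point": neck.plane_point.tolist(),
        "plane_normal": neck.plane_normal.tolist(),
        "contour": neck.contour.tolist(),
    }
    if parent is not None:
        data["centerline_points"] = parent.points.tolist()
        data["centerline_radii"] = parent.radii.tolist()
        data["flow_direction"] = parent.flow_direction
    Path(path).write_text(json.dumps(data))


def load_geometry(surface_path: str | Path, annotation_path: str | Path) -> AneurysmGeometry:
    """Assemble a validated AneurysmGeometry from a surface + sidecar pair."""
    sac = read_surface(surface_path)
    neck, parent = read_annotation(annotation_path)
    return AneurysmGeometry(sac=sac, neck=neck, parent=parent).validate()


# ---------------------------------------------------------------------------
# WSS series
# ---------------------------------------------------------------------------

def read_wss_series(
    manifest: str | Path | Sequence[tuple[float, str | Path]],
    surface: Optional[TriSurface] = None,
) -> WSSField:
    """Read a WSS time series from a manifest of .vtp snapshots.

    ``manifest`` is either a text file with one ``time,file`` entry per line
    (paths relative to the manifest) or an ordered sequence of
    (time_s, path). All snapshots must share one vertex set; each must carry
    a 3-component ``wss`` point array. When ``surface`` is given its vertex
    count is enforced and its connectivity used; otherwise the first
    snapshot supplies the surface.
    """
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        if not mpath.is_file():
            raise FileNotFoundError(f"manifest not found: {mpath}")
        entries = []
        for line in mpath.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t_str, fname = line.split(",", 1)
            entries.append((float(t_str), mpath.parent / fname.strip()))
    else:
        entries = [(float(t), Path(p)) for t, p in manifest]
    if len(entries) < 1:
        raise ValidationError("WSS manifest contains no snapshots")
    times = np.asarray([t for t, _ in entries])
    if np.any(np.diff(times) <= 0):
        raise ValidationError("manifest times must be strictly increasing")

    vectors = []
    ref_surface = surface
    for t, fpath in entries:
        vertices, faces, point_data = _read_vtp(Path(fpath))
        if "wss" not in point_data:
            raise ValidationError(f"{fpath}: no 'wss' point-data array")
        wss = np.atleast_2d(point_data["wss"])
        if wss.shape[1] != 3:
            raise ValidationError(f"{fpath}: 'wss' array must have 3 components")
        if ref_surface is None:
            ref_surface = _clean(vertices, faces, str(fpath))
            if len(ref_surface.vertices) != len(vertices):
                raise ValidationError(
                    f"{fpath}: snapshot mesh has duplicate/degenerate elements; "
                    "clean it before attaching point data"
                )
        if len(wss) != len(ref_surface.vertices) or len(vertices) != len(ref_surface.vertices):
            raise ValidationError(
                f"{fpath}: vertex count {len(vertices)} does not match the "
                f"shared surface ({len(ref_surface.vertices)})"
            )
        vectors.append(wss)
    field = WSSField(surface=ref_surface, times=times, vectors=np.stack(vectors))
    return field.validate()


def write_wss_series(
    field: WSSField, directory: str | Path, prefix: str = "wss"
) -> Path:
    """Write a WSS series as .vtp snapshots plus a ``time,file`` manifest.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, t in enumerate(field.times):
        fname = f"{prefix}_{i:04d}.vtp"
        _write_vtp(
            directory / fname,
            field.surface.vertices,
            field.surface.faces,
            {"wss": field.vectors[i]},
        )
        lines.append(f"{format(float(t), '.17g')},{fname}")
    manifest = directory / f"{prefix}_manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_wss_table(path: str | Path, surface: TriSurface) -> WSSField:
    """Read a WSS series from one CSV with columns
    time, vertex_id, wx, wy, wz."""
    import pandas as pd

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"WSS table not found: {path}")
    df = pd.read_csv(path)
    required = {"time", "vertex_id", "wx", "wy", "wz"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: WSS table needs columns {sorted(required)}")
    times = np.sort(df["time"].unique())
    nv = len(surface.vertices)
    vectors = np.full((len(times), nv, 3), np.nan)
    t_index = {t: i for i, t in enumerate(times)}
    rows_t = df["time"].map(t_index).to_numpy()
    vid = df["vertex_id"].to_numpy(dtype=np.int64)
    if vid.min() < 0 or vid.max() >= nv:
        raise ValidationError(f"{path}: vertex_id out of range for the surface")
    vectors[rows_t, vid] = df[["wx", "wy", "wz"]].to_numpy()
    if np.isnan(vectors).any():
        raise ValidationError(f"{path}: missing (time, vertex) entries in WSS table")
    return WSSField(surface=surface, times=times, vectors=vectors).validate()


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

# (row name, unit, decimals); RRS rows are percentages
REPORT_ROWS: list[tuple[str, str, int]] = [
    ("Hmax", "mm", 3),
    ("H", "mm", 3),
    ("Dmiddle", "mm", 3),
    ("Dneck", "mm", 3),
    ("Dvessel", "mm", 3),
    ("V", "mm^3", 3),
    ("S", "mm^2", 3),
    ("thetaF", "deg", 3),
    ("thetaA", "deg", 3),
    ("AR", "", 3),
    ("SR", "", 3),
    ("UI", "", 3),
    ("EI", "", 3),
    ("NSI", "", 3),
    ("NWSS", "", 3),
    ("OSI", "", 4),
    ("RRT", "1/Pa", 3),
    ("RRS_M", "%", 2),
    ("RRS_H", "%", 2),
    ("RRS_C", "%", 2),
]


def panel_rows(panel) -> list[dict]:
    """Flatten a RiskPanel into the report's row dictionaries."""
    values: dict[str, Optional[float]] = {name: None for name, _, _ in REPORT_ROWS}
    if panel.morphometry is not None:
        md = (
            panel.morphometry
            if isinstance(panel.morphometry, dict)
            else panel.morphometry.to_dict()
        )
        for k, v in md.items():
            if k in values:
                values[k] = v
    if panel.hemodynamics is not None:
        hd = (
            panel.hemodynamics
            if isinstance(panel.hemodynamics, dict)
            else panel.hemodynamics.to_dict()
        )
        for k, v in hd.items():
            if k in values:
                values[k] = v
    for model, p in (panel.rrs or {}).items():
        values[f"RRS_{model}"] = p

    thresholds = getattr(panel, "thresholds", None)
    flags = panel.flags or {}
    rows = []
    for name, unit, nd in REPORT_ROWS:
        raw = values[name]
        display = raw
        if raw is not None and unit == "%":
            display = raw * 100.0
        value = None if display is None else round(float(display), nd) + 0.0  # +0.0 kills -0.0
        rule = thresholds.rules.get(name) if thresholds is not None else None
        if rule is None:
            thr = "/"
        else:
            cut = rule[1] * 100.0 if unit == "%" else rule[1]
            thr = (">" if rule[0] == "greater" else "<") + format(cut, "g")
        flag = flags.get(name)
        rows.append(
            {
                "parameter": name,
                "value": value,
                "unit": unit,
                "threshold": thr,
                "flag": "not computed" if raw is None else ("yes" if flag else "no" if flag is not None else "/"),
            }
        )
    return rows


def write_report(panel, path: str | Path, format: str = "csv") -> None:
    """Write the full parameter report (every printed panel row with value,
    unit, threshold and flag) as CSV or JSON.

    Missing quantities (e.g. hemodynamics never computed) appear with null
    values and the flag "not computed"; both formats carry identical values.
    """
    rows = panel_rows(panel)
    path = Path(path)
    fmt = format.lower()
    try:
        if fmt == "json":
            path.write_text(json.dumps(rows, indent=1))
        elif fmt == "csv":
            with open(path, "w", newline="") as fh:
                writer = csv.DictWriter(
                    fh, fieldnames=["parameter", "value", "unit", "threshold", "flag"]
                )
                writer.writeheader()
                for row in rows:
                    out = dict(row)
                    if out["value"] is None:
                        out["value"] = ""
                    writer.writerow(out)
        else:
            raise ValidationError(f"unknown report format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
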