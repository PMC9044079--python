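"""Point-cloud, mesh and table I/O in plain interchange formats.

Supported cloud formats: PLY (ascii and binary_little_endian), OBJ
(``v``/``f`` records) and whitespace XYZ text.  All coordinates are
millimetres; no unit metadata is read from files.  Unknown PLY vertex
properties (colour, normals) are parsed and skipped, except an integer
``label`` property which round-trips per-point segment ids.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PointCloud",
    "TriangleMesh",
    "read_point_cloud",
    "write_point_cloud",
    "read_design_table",
    "write_trait_table",
    "read_trait_table",
]


class CloudIOError(ValueError):
    """Malformed or unsupported point-cloud file."""


@dataclass
class PointCloud:
    """An unordered set of 3D surface coordinates in millimetres.

    Parameters
    ----------
    points : (N, 3) float array
        Point coordinates in mm.
    labels : (N,) int array, optional
        Per-point segment id (written back by grain segmentation).
    source_path : str, optional
        Provenance of the cloud, if it was read from disk.
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
            if self.labels.shape[0] != self.points.shape[0]:
                raise ValueError(
                    f"labels ({self.labels.shape[0]}) must have one entry per "
                    f"point ({self.points.shape[0]})"
                )

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, indices: np.ndarray) -> "PointCloud":
        """Sub-cloud at the given point indices (labels carried along)."""
        idx = np.asarray(indices)
        labels = self.labels[idx] if self.labels is not None else None
        return PointCloud(self.points[idx], labels=labels, source_path=self.source_path)


@dataclass
class TriangleMesh:
    """Triangle surface mesh: ``vertices`` (V, 3) mm and ``faces`` (F, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            if (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ).any():
                raise ValueError("face repeats a vertex")

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_ply_header(fh):
    """Parse a PLY header; returns (format, elements, header_end_offset).

    ``elements`` is a list of (name, count, [(prop_name, dtype) ...]); list
    properties are recorded as ("list", count_dtype, item_dtype, name).
    """
    magic = fh.readline().strip()
    if magic != b"ply":
        raise CloudIOError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements = []
    while True:
        line = fh.readline()
        if not line:
            raise CloudIOError("unexpected end of PLY header")
        tokens = line.decode("ascii", errors="replace").split()
        if not tokens or tokens[0] == "comment" or tokens[0] == "obj_info":
            continue
        if tokens[0] == "format":
            if tokens[1] not in ("ascii", "binary_little_endian"):
                raise CloudIOError(f"unsupported PLY format {tokens[1]!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise CloudIOError("PLY property before any element")
            if tokens[1] == "list":
                elements[-1][2].append(("list", tokens[2], tokens[3], tokens[4]))
            else:
                if tokens[1] not in _PLY_DTYPES:
                    raise CloudIOError(f"unknown PLY property type {tokens[1]!r}")
                elements[-1][2].append((tokens[2], _PLY_DTYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
        else:
            raise CloudIOError(f"unrecognized PLY header line {line!r}")
    if fmt is None:
        raise CloudIOError("PLY header missing 'format' line")
    return fmt, elements


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        fmt, elements = _parse_ply_header(fh)
        vertex_elem = next((e for e in elements if e[0] == "vertex"), None)
        if vertex_elem is None:
            raise CloudIOError("PLY file has no vertex element")
        # only the leading vertex element is needed for a point cloud; refuse
        # layouts where another element precedes it (never emitted by scanners)
        if elements[0][0] != "vertex":
            raise CloudIOError("vertex element must come first")
        name, count, props = vertex_elem
        if any(p[0] == "list" for p in props):
            raise CloudIOError("list property on vertex element is unsupported")
        prop_names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in prop_names:
                raise CloudIOError(f"vertex element missing property {axis!r}")
        if fmt == "ascii":
            rows = []
            for i in range(count):
                line = fh.readline()
                if not line:
                    raise CloudIOError(f"expected {count} vertices, file ended at {i}")
                values = line.split()
                if len(values) != len(props):
                    raise CloudIOError(f"vertex record {i} has {len(values)} fields, expected {len(props)}")
                rows.append([float(v) for v in values])
            data = np.array(rows, dtype=np.float64).reshape(count, len(props))
            cols = {nm: data[:, j] for j, (nm, _) in enumerate(props)}
        else:
            dtype = np.dtype([(nm, "<" + dt) for nm, dt in props])
            raw = fh.read(dtype.itemsize * count)
            if len(raw) < dtype.itemsize * count:
                raise CloudIOError("binary PLY vertex data truncated")
            rec = np.frombuffer(raw, dtype=dtype, count=count)
            cols = {nm: rec[nm].astype(np.float64) for nm, _ in props}
        points = np.column_stack([cols["x"], cols["y"], cols["z"]]) if count else np.empty((0, 3))
        labels = None
        if "label" in cols and count:
            labels = cols["label"].astype(np.int64)
        elif "label" in prop_names:
            labels = np.empty(0, dtype=np.int64)
        return PointCloud(points, labels=labels, source_path=str(path))


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    n = len(cloud)
    props = ["property double x", "property double y", "property double z"]
    if cloud.labels is not None:
        props.append("property int label")
    header = "\n".join(
        [
            "ply",
            f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
            "comment produced by grain3d",
            f"element vertex {n}",
            *props,
            "end_header",
        ]
    ) + "\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            if cloud.labels is not None:
                dtype = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("label", "<i4")])
                rec = np.empty(n, dtype=dtype)
                rec["x"], rec["y"], rec["z"] = cloud.points.T
                rec["label"] = cloud.labels
            else:
                rec = cloud.points.astype("<f8")
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                x, y, z = cloud.points[i]
                line = f"{x:.10g} {y:.10g} {z:.10g}"
                if cloud.labels is not None:
                    line += f" {int(cloud.labels[i])}"
                fh.write((line + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# OBJ / XYZ
# ---------------------------------------------------------------------------

def _read_obj(path: Path) -> PointCloud:
    points = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0] in ("#", "f", "vn", "vt", "o", "g", "s", "usemtl", "mtllib"):
                continue
            if tokens[0] == "v":
                if len(tokens) < 4:
                    raise CloudIOError(f"{path}:{lineno}: vertex record needs 3 coordinates")
                points.append([float(t) for t in tokens[1:4]])
    return PointCloud(np.array(points, dtype=np.float64).reshape(-1, 3), source_path=str(path))


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 3:
                raise CloudIOError(f"{path}:{lineno}: expected at least 3 columns")
            rows.append([float(t) for t in tokens[:3]])
    return PointCloud(np.array(rows, dtype=np.float64).reshape(-1, 3), source_path=str(path))


def read_point_cloud(path, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from ``path``.

    ``format`` is one of ``{"ply", "obj", "xyz"}``; when omitted it is taken
    from the file extension.  An empty file (zero vertices) is a valid empty
    cloud, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "obj":
        return _read_obj(path)
    if fmt in ("xyz", "txt"):
        return _read_xyz(path)
    raise CloudIOError(f"unsupported point-cloud format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path, format: Optional[str] = None, *, binary: bool = False) -> None:
    """Write ``cloud`` to ``path``; ASCII PLY by default (diffable).

    ``binary=True`` selects binary_little_endian for PLY.  Labels are written
    as an integer scalar per vertex (PLY) or a fourth column (XYZ).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "obj":
        with open(path, "w") as fh:
            fh.write("# produced by grain3d\n")
            for x, y, z in cloud.points:
                fh.write(f"v {x:.10g} {y:.10g} {z:.10g}\n")
    elif fmt in ("xyz", "txt"):
        with open(path, "w") as fh:
            for i, (x, y, z) in enumerate(cloud.points):
                line = f"{x:.10g} {y:.10g} {z:.10g}"
                if cloud.labels is not None:
                    line += f" {int(cloud.labels[i])}"
                fh.write(line + "\n")
    else:
        raise CloudIOError(f"unsupported point-cloud format {fmt!r}")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_design_table(path) -> pd.DataFrame:
    """Read an L9 (3^k) orthogonal design table from CSV.

    Expects exactly 9 rows; all columns but the last are factor columns with
    levels coded 1-3, the last column is the numeric response.  Returns a
    DataFrame whose final column is named as in the file (the response).
    """
    df = pd.read_csv(path)
    if df.shape[0] != 9:
        raise ValueError(f"wrong row count: L9 design needs 9 rows, got {df.shape[0]}")
    if df.shape[1] < 2:
        raise ValueError("design table needs at least one factor column and a response")
    factors = df.iloc[:, :-1]
    response = pd.to_numeric(df.iloc[:, -1], errors="coerce")
    if response.isna().any() or not np.isfinite(response).all():
        raise ValueError("response column contains non-numeric or non-finite values")
    for col in factors.columns:
        levels = set(pd.to_numeric(factors[col], errors="coerce").dropna().astype(int))
        if not levels <= {1, 2, 3}:
            raise ValueError(f"factor {col!r} has levels outside 1-3: {sorted(levels)}")
    out = factors.astype(int)
    out[df.columns[-1]] = response.to_numpy()
    return out


def write_trait_table(df: pd.DataFrame, path) -> None:
    """Write a per-grain trait table (id + 32 traits [+ weight]) as CSV."""
    df.to_csv(path, index=False)


def read_trait_table(path) -> pd.DataFrame:
    """Read a per-grain trait table written by :func:`write_trait_table`."""
    from .traits import TRAIT_NAMES  # local import to avoid a cycle

    df = pd.read_csv(path)
    missing = [t for t in TRAIT_NAMES if t not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if df[TRAIT_NAMES].isna().any().any():
        raise ValueError("trait table contains missing values")
    return df
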