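"""Point-cloud and mesh file I/O.

Point clouds: PLY (ASCII and binary little-endian) and whitespace XYZ
(``x y z [nx ny nz]``). Binary big-endian PLY is rejected with a clear
error. Meshes (OBJ/STL/PLY) go through trimesh.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .core import PointCloud, TriangleMesh
from .errors import EmptyInputError, ParameterError, ParseError

__all__ = ["read_cloud", "write_cloud", "read_mesh", "write_mesh"]

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _parse_ply_header(fh):
    """Return (format, n_vertex, properties, header_end_offset)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise ParseError("line 1: not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertex = None
    properties: list[tuple[str, str]] = []
    in_vertex = False
    lineno = 1
    while True:
        raw = fh.readline()
        lineno += 1
        if not raw:
            raise ParseError(f"line {lineno}: unexpected EOF in PLY header")
        line = raw.decode("ascii", errors="replace").strip()
        if line.startswith("comment") or not line:
            continue
        tokens = line.split()
        if tokens[0] == "format":
            fmt = tokens[1]
            if fmt == "binary_big_endian":
                raise ParseError(
                    f"line {lineno}: binary big-endian PLY is not supported; "
                    "convert to ASCII or binary little-endian"
                )
            if fmt not in ("ascii", "binary_little_endian"):
                raise ParseError(f"line {lineno}: unknown PLY format '{fmt}'")
        elif tokens[0] == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                try:
                    n_vertex = int(tokens[2])
                except (IndexError, ValueError):
                    raise ParseError(f"line {lineno}: malformed vertex element")
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise ParseError(f"line {lineno}: list property on vertex element")
            if tokens[1] not in _PLY_TYPES:
                raise ParseError(f"line {lineno}: unknown PLY type '{tokens[1]}'")
            properties.append((tokens[2], _PLY_TYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if fmt is None or n_vertex is None:
        raise ParseError("PLY header missing format or vertex element")
    return fmt, n_vertex, properties, lineno


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        fmt, n, props, header_lines = _parse_ply_header(fh)
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ParseError(f"PLY vertex element lacks property '{axis}'")
        if fmt == "ascii":
            rows = []
            for i in range(n):
                raw = fh.readline()
                lineno = header_lines + 1 + i
                if not raw:
                    raise ParseError(f"line {lineno}: expected {n} vertices, file ended")
                tokens = raw.split()
                if len(tokens) < len(props):
                    raise ParseError(f"line {lineno}: expected {len(props)} values")
                try:
                    rows.append([float(t) for t in tokens[: len(props)]])
                except ValueError:
                    raise ParseError(f"line {lineno}: non-numeric token")
            data = {nm: np.array([r[j] for r in rows]) for j, nm in enumerate(names)}
        else:
            dtype = np.dtype([(nm, "<" + code) for nm, code in props])
            buf = fh.read(dtype.itemsize * n)
            if len(buf) < dtype.itemsize * n:
                raise ParseError(f"binary PLY truncated: expected {n} vertices")
            rec = np.frombuffer(buf, dtype=dtype, count=n)
            data = {nm: rec[nm].astype(np.float64) for nm in names}
    points = np.column_stack([data["x"], data["y"], data["z"]])
    normals = None
    if all(k in data for k in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]])
        norms = np.linalg.norm(normals, axis=1)
        nonzero = norms > 0
        normals[nonzero] /= norms[nonzero, None]
        normals[~nonzero] = np.nan
    labels = None
    if "label" in data:
        labels = data["label"].astype(np.int64)
    return PointCloud(points, normals, labels)


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    ncols = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            try:
                vals = [float(t) for t in tokens]
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric token in XYZ file")
            if len(vals) not in (3, 6):
                raise ParseError(
                    f"line {lineno}: expected 3 or 6 columns, got {len(vals)}"
                )
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ParseError(f"line {lineno}: inconsistent column count")
            rows.append(vals)
    if not rows:
        raise EmptyInputError(f"{path}: no points found")
    arr = np.asarray(rows, dtype=np.float64)
    normals = arr[:, 3:6] if arr.shape[1] == 6 else None
    if normals is not None:
        norms = np.linalg.norm(normals, axis=1)
        ok = norms > 0
        normals = normals.copy()
        normals[ok] /= norms[ok, None]
        normals[~ok] = np.nan
    return PointCloud(arr[:, :3], normals)


def read_cloud(path, format: str = "auto") -> PointCloud:
    """Read a point cloud from PLY or XYZ text.

    Parameters
    ----------
    path : path-like
    format : {"auto", "ply", "xyz"}
        ``auto`` picks by file extension, falling back to content sniffing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    if format == "auto":
        ext = path.suffix.lower()
        if ext == ".ply":
            format = "ply"
        elif ext in (".xyz", ".txt", ".pts", ".pcd"):
            format = "xyz"
        else:
            with open(path, "rb") as fh:
                format = "ply" if fh.read(3) == b"ply" else "xyz"
    if format == "ply":
        return _read_ply(path)
    if format == "xyz":
        return _read_xyz(path)
    raise ParameterError(f"unknown cloud format '{format}'")


def write_cloud(cloud: PointCloud, path, format: str | None = None,
                binary: bool = True) -> None:
    """Write a cloud to PLY (binary-LE by default) or XYZ text.

    Labels are carried as an ``int32 label`` vertex property (PLY only).
    """
    if len(cloud) == 0:
        raise EmptyInputError("refusing to write an empty cloud")
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix.lower() in (".xyz", ".txt") else "ply"
    if format == "xyz":
        cols = [cloud.points]
        if cloud.normals is not None:
            cols.append(cloud.normals)
        np.savetxt(path, np.column_stack(cols), fmt="%.8f")
        return
    if format != "ply":
        raise ParameterError(f"unknown cloud format '{format}'")

    props = [("x", "f8"), ("y", "f8"), ("z", "f8")]
    if cloud.normals is not None:
        props += [("nx", "f8"), ("ny", "f8"), ("nz", "f8")]
    if cloud.labels is not None:
        props += [("label", "i4")]
    ply_name = {"f8": "double", "i4": "int"}
    header = ["ply"]
    header.append("format " + ("binary_little_endian 1.0" if binary else "ascii 1.0"))
    header.append(f"element vertex {len(cloud)}")
    for nm, code in props:
        header.append(f"property {ply_name[code]} {nm}")
    header.append("end_header")

    rec = np.zeros(len(cloud), dtype=[(nm, "<" + code) for nm, code in props])
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    if cloud.normals is not None:
        rec["nx"], rec["ny"], rec["nz"] = cloud.normals.T
    if cloud.labels is not None:
        rec["label"] = cloud.labels
    try:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            if binary:
                fh.write(rec.tobytes())
            else:
                fmt = " ".join("%d" if c == "i4" else "%.8f" for _, c in props)
                for row in rec:
                    fh.write((fmt % tuple(row)).encode("ascii") + b"\n")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def read_mesh(path) -> TriangleMesh:
    """Read a triangle mesh (OBJ/STL/PLY) via trimesh."""
    import trimesh

    m = trimesh.load(str(path), force="mesh", process=False)
    if m.faces is None or len(m.faces) == 0:
        raise ParseError(f"{path}: no triangle faces found")
    return TriangleMesh(np.asarray(m.vertices, dtype=np.float64),
                        np.asarray(m.faces, dtype=np.int64))


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write a triangle mesh (format by extension) via trimesh."""
    import trimesh

    trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(str(path))


def _default_config_path() -> str | None:
    for candidate in ("phytopoint.cfg", os.path.expanduser("~/.phytopoint.cfg")):
        if os.path.exists(candidate):
            return candidate
    return None


def load_config(path=None) -> dict:
    """Read a plain ``key = value`` config file into a dict of floats/ints."""
    path = path or _default_config_path()
    out: dict[str, float] = {}
    if path is None:
        return out
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            try:
                out[key] = int(val) if val.isdigit() else float(val)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value '{val}'")
    return out
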