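"""Mesh export/import: legacy-VTK polydata and ASCII PLY with traction fields.

Hand-rolled writers/parsers are used deliberately: the files carry custom
per-vertex tensor-derived fields (t, t_n, ||t_t||) in the exact layout a
ParaView-style workflow expects, and the round-trip is part of the test
contract. Floats are printed with 17 significant digits so write->read is
lossless at double precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import EmptySurfaceError, InvalidParameterError

SUPPORTED_FORMATS = ("vtk", "ply")
_FMT = "%.17g"


def export_surface(surface, path: str | Path, format: str | None = None) -> Path:
    """Write mesh + per-vertex fields (t_n, ||t_t|| scalars; t vectors).

    ``format`` is "vtk" (legacy ASCII polydata) or "ply" (ASCII); inferred
    from the filename suffix when omitted.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise InvalidParameterError(
            f"unknown format {fmt!r}; supported formats: {', '.join(SUPPORTED_FORMATS)}"
        )
    if surface.is_empty():
        raise EmptySurfaceError("refusing to export an empty surface")
    if surface.traction is None:
        raise InvalidParameterError("sample_traction must run before export")
    writer = _write_vtk if fmt == "vtk" else _write_ply
    writer(surface, path)
    return path


def _write_vtk(surface, path: Path) -> None:
    v, f = surface.vertices, surface.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "mechanotrace traction surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines += [" ".join(_FMT % x for x in row) for row in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += ["3 %d %d %d" % tuple(row) for row in f]
    lines.append(f"POINT_DATA {len(v)}")
    lines.append("NORMALS normals double")
    lines += [" ".join(_FMT % x for x in row) for row in surface.normals]
    lines.append("VECTORS traction double")
    lines += [" ".join(_FMT % x for x in row) for row in surface.traction]
    lines.append("SCALARS t_n double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [_FMT % x for x in surface.t_normal]
    lines.append("SCALARS t_t_mag double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [_FMT % x for x in surface.t_tangential]
    path.write_text("\n".join(lines) + "\n")


def _write_ply(surface, path: Path) -> None:
    v, f = surface.vertices, surface.faces
    props = np.column_stack(
        [v, surface.normals, surface.traction, surface.t_normal, surface.t_tangential]
    )
    header = [
        "ply",
        "format ascii 1.0",
        "comment mechanotrace traction surface",
        f"element vertex {len(v)}",
    ]
    for name in ("x", "y", "z", "nx", "ny", "nz", "tx", "ty", "tz", "t_n", "t_t_mag"):
        header.append(f"property double {name}")
    header += [f"element face {len(f)}", "property list uchar int vertex_indices", "end_header"]
    lines = header + [" ".join(_FMT % x for x in row) for row in props]
    lines += ["3 %d %d %d" % tuple(row) for row in f]
    path.write_text("\n".join(lines) + "\n")


def read_surface(path: str | Path):
    """Re-read a surface written by :func:`export_surface` (either format)."""
    from .tractionmap import TractionSurface

    path = Path(path)
    text = path.read_text().splitlines()
    if text[0].startswith("# vtk"):
        return _read_vtk(text, TractionSurface)
    if text[0].strip() == "ply":
        return _read_ply(text, TractionSurface)
    raise InvalidParameterError(f"unrecognised mesh file {path}")


def _read_vtk(lines: list[str], cls):
    it = iter(range(len(lines)))
    i = 0
    data: dict[str, np.ndarray] = {}
    faces = None
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0]
        if key == "POINTS":
            n = int(tok[1])
            data["vertices"] = np.array([[float(x) for x in lines[i + 1 + k].split()] for k in range(n)])
            i += n + 1
        elif key == "POLYGONS":
            n = int(tok[1])
            faces = np.array([[int(x) for x in lines[i + 1 + k].split()[1:]] for k in range(n)])
            i += n + 1
        elif key == "NORMALS":
            n = len(data["vertices"])
            data["normals"] = np.array([[float(x) for x in lines[i + 1 + k].split()] for k in range(n)])
            i += n + 1
        elif key == "VECTORS":
            n = len(data["vertices"])
            data["traction"] = np.array([[float(x) for x in lines[i + 1 + k].split()] for k in range(n)])
            i += n + 1
        elif key == "SCALARS":
            name = tok[1]
            n = len(data["vertices"])
            data[name] = np.array([float(lines[i + 2 + k]) for k in range(n)])
            i += n + 2
        else:
            i += 1
    return cls(
        vertices=data["vertices"],
        faces=faces,
        normals=data["normals"],
        traction=data.get("traction"),
        t_normal=data.get("t_n"),
        t_tangential=data.get("t_t_mag"),
    )


def _read_ply(lines: list[str], cls):
    i = 0
    nv = nf = 0
    while lines[i].strip() != "end_header":
        tok = lines[i].split()
        if tok[:2] == ["element", "vertex"]:
            nv = int(tok[2])
        elif tok[:2] == ["element", "face"]:
            nf = int(tok[2])
        i += 1
    body = lines[i + 1 :]
    props = np.array([[float(x) for x in body[k].split()] for k in range(nv)])
    faces = np.array([[int(x) for x in body[nv + k].split()[1:]] for k in range(nf)])
    return cls(
        vertices=props[:, 0:3],
        faces=faces,
        normals=props[:, 3:6],
        traction=props[:, 6:9],
        t_normal=props[:, 9],
        t_tangential=props[:, 10],
    )
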