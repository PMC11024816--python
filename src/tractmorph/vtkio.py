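"""Plain-text serialization: legacy VTK unstructured grids and point clouds.

Meshes are stored as ASCII legacy VTK unstructured grids (``DATASET
UNSTRUCTURED_GRID`` with ``VTK_HEXAHEDRON`` cells) with per-element scalar
fields as ``CELL_DATA`` SCALARS arrays, readable by ParaView and friends.
Point clouds are stored as whitespace XYZ or ASCII PLY.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .errors import FormatError
from .mesh import HexMesh

__all__ = ["write_mesh", "read_mesh", "read_point_cloud", "write_point_cloud"]

_VTK_HEXAHEDRON = 12


def write_mesh(mesh: HexMesh, path: os.PathLike | str) -> None:
    """Write ``mesh`` (nodes, hex cells, all per-element fields) as ASCII VTK."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "tractmorph hexahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines.extend(" ".join(repr(float(v)) for v in row) for row in mesh.nodes)
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}")
    lines.extend("8 " + " ".join(str(int(v)) for v in row) for row in mesh.elements)
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend([str(_VTK_HEXAHEDRON)] * mesh.n_elements)
    if mesh.fields:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        for name, values in mesh.fields.items():
            if any(ch.isspace() for ch in name):
                raise FormatError(f"field name {name!r} must not contain whitespace")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(repr(float(v)) for v in values)
    path.write_text("\n".join(lines) + "\n")


class _TokenStream:
    """Whitespace token reader that remembers line numbers for errors."""

    def __init__(self, text: str, path: str):
        self.path = path
        self.tokens: list[tuple[str, int]] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            for tok in line.split():
                self.tokens.append((tok, lineno))
        self.pos = 0

    def fail(self, message: str) -> "FormatError":
        lineno = self.tokens[self.pos - 1][1] if self.pos else 0
        return FormatError(f"{self.path}:{lineno}: {message}")

    def next(self, what: str) -> str:
        if self.pos >= len(self.tokens):
            raise FormatError(f"{self.path}: unexpected end of file, expected {what}")
        tok, _ = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, literal: str) -> None:
        tok = self.next(literal)
        if tok.upper() != literal.upper():
            raise self.fail(f"expected {literal!r}, found {tok!r}")

    def next_int(self, what: str) -> int:
        tok = self.next(what)
        try:
            return int(tok)
        except ValueError:
            raise self.fail(f"expected integer {what}, found {tok!r}") from None

    def next_float(self, what: str) -> float:
        tok = self.next(what)
        try:
            return float(tok)
        except ValueError:
            raise self.fail(f"expected number for {what}, found {tok!r}") from None

    def peek(self) -> str | None:
        if self.pos >= len(self.tokens):
            return None
        return self.tokens[self.pos][0]


def read_mesh(path: os.PathLike | str) -> HexMesh:
    """Read an ASCII legacy VTK unstructured grid of hexahedra."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    first = text.splitlines()[0] if text.splitlines() else ""
    if not first.startswith("# vtk DataFile"):
        raise FormatError(f"{path}:1: not a legacy VTK file (missing header)")
    body = "\n".join(text.splitlines()[2:])  # skip header comment + title
    ts = _TokenStream(body, str(path))
    ts.expect("ASCII")
    ts.expect("DATASET")
    kind = ts.next("dataset kind")
    if kind.upper() != "UNSTRUCTURED_GRID":
        raise ts.fail(f"unsupported dataset {kind!r}, expected UNSTRUCTURED_GRID")

    ts.expect("POINTS")
    n_points = ts.next_int("point count")
    ts.next("point dtype")
    nodes = np.empty((n_points, 3))
    for i in range(n_points):
        for axis in range(3):
            nodes[i, axis] = ts.next_float(f"coordinate of point {i}")

    ts.expect("CELLS")
    n_cells = ts.next_int("cell count")
    ts.next_int("cell list size")
    elements = np.empty((n_cells, 8), dtype=np.int64)
    for e in range(n_cells):
        n_corner = ts.next_int(f"corner count of cell {e}")
        if n_corner != 8:
            raise ts.fail(f"cell {e} has {n_corner} corners, only hexahedra (8) supported")
        for c in range(8):
            elements[e, c] = ts.next_int(f"corner {c} of cell {e}")

    ts.expect("CELL_TYPES")
    n_types = ts.next_int("cell type count")
    if n_types != n_cells:
        raise ts.fail(f"CELL_TYPES count {n_types} != CELLS count {n_cells}")
    for e in range(n_cells):
        ctype = ts.next_int(f"type of cell {e}")
        if ctype != _VTK_HEXAHEDRON:
            raise ts.fail(
                f"cell {e} has VTK type {ctype}; only hexahedra (type 12) supported"
            )

    fields: dict[str, np.ndarray] = {}
    if ts.peek() is not None:
        ts.expect("CELL_DATA")
        n_data = ts.next_int("cell data count")
        if n_data != n_cells:
            raise ts.fail(f"CELL_DATA count {n_data} != cell count {n_cells}")
        while ts.peek() is not None:
            ts.expect("SCALARS")
            name = ts.next("field name")
            ts.next("field dtype")
            ncomp = 1
            nxt = ts.peek()
            if nxt is not None and nxt.isdigit():
                ncomp = ts.next_int("component count")
            if ncomp != 1:
                raise ts.fail(f"field {name!r} has {ncomp} components, expected 1")
            ts.expect("LOOKUP_TABLE")
            ts.next("lookup table name")
            values = np.empty(n_cells)
            for e in range(n_cells):
                values[e] = ts.next_float(f"value {e} of field {name!r}")
            fields[name] = values

    return HexMesh(nodes, elements, fields)


def write_point_cloud(points: np.ndarray, path: os.PathLike | str) -> None:
    """Write an (N, 3) point set as XYZ text or ASCII PLY, by extension."""
    path = Path(path)
    points = np.asarray(points, dtype=float)
    if path.suffix.lower() == ".ply":
        header = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(points)}",
            "property double x",
            "property double y",
            "property double z",
            "end_header",
        ]
        body = "\n".join(" ".join(repr(float(v)) for v in row) for row in points)
        path.write_text("\n".join(header) + "\n" + body + "\n")
    else:
        np.savetxt(path, points, fmt="%.17g")


def read_point_cloud(path: os.PathLike | str) -> np.ndarray:
    """Read an (N, 3) point set from whitespace XYZ or ASCII PLY."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if path.suffix.lower() == ".ply" or text.startswith("ply"):
        return _read_ply(text, str(path))
    try:
        points = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed XYZ file: {exc}") from exc
    if points.shape[1] < 3:
        raise FormatError(f"{path}: expected >= 3 columns, found {points.shape[1]}")
    return points[:, :3]


def _read_ply(text: str, path: str) -> np.ndarray:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path}:1: not a PLY file")
    n_vertex = None
    header_end = None
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if parts[:2] == ["format", "binary_little_endian"] or parts[:2] == [
            "format",
            "binary_big_endian",
        ]:
            raise FormatError(f"{path}:{lineno}: binary PLY is not supported")
        if parts[:2] == ["element", "vertex"]:
            n_vertex = int(parts[2])
        if parts[:1] == ["end_header"]:
            header_end = lineno
            break
    if n_vertex is None or header_end is None:
        raise FormatError(f"{path}: PLY header missing 'element vertex' or 'end_header'")
    rows = []
    for lineno, line in enumerate(lines[header_end:], start=header_end + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: vertex row has fewer than 3 columns")
        try:
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric vertex coordinate") from None
        if len(rows) == n_vertex:
            break
    if len(rows) != n_vertex:
        raise FormatError(f"{path}: expected {n_vertex} vertices, found {len(rows)}")
    return np.asarray(rows)
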