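"""Minimal mesh I/O: ASCII STL (via trimesh) and XML ASCII VTU.

The VTU writer emits a single-piece unstructured grid with optional
point/cell data arrays — enough to inspect models and stress fields in
ParaView.  Mixed tet (type 10) and hex (type 12) cells are supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_stl", "write_vtu"]

_VTK_TET = 10
_VTK_HEX = 12


def write_stl(path, vertices: np.ndarray, faces: np.ndarray) -> None:
    """Write a triangle surface as ASCII STL."""
    import trimesh

    m = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    Path(path).write_bytes(m.export(file_type="stl_ascii").encode())


def _fmt(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind in "iub":
        return " ".join(str(int(v)) for v in a.ravel())
    return " ".join(f"{v:.9g}" for v in a.ravel())


def write_vtu(
    path,
    nodes: np.ndarray,
    cells: list[tuple[str, np.ndarray]],
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write an unstructured grid.

    ``cells`` is a list of ("tetra"|"hexahedron", connectivity) blocks;
    ``cell_data`` arrays are concatenated over all blocks in order.
    """
    nodes = np.asarray(nodes, dtype=float)
    conn_parts, offsets, types = [], [], []
    off = 0
    for kind, conn in cells:
        conn = np.asarray(conn, dtype=np.int64)
        nper = {"tetra": 4, "hexahedron": 8}[kind]
        if conn.shape[1] != nper:
            raise ValueError(f"{kind} cells need {nper} nodes per cell")
        conn_parts.append(conn.ravel())
        off_block = off + nper * np.arange(1, len(conn) + 1)
        offsets.append(off_block)
        off = off_block[-1] if len(conn) else off
        types.append(
            np.full(len(conn), _VTK_TET if kind == "tetra" else _VTK_HEX)
        )
    ncells = sum(len(t) for t in types)

    out = []
    out.append('<?xml version="1.0"?>')
    out.append(
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">'
    )
    out.append("<UnstructuredGrid>")
    out.append(f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{ncells}">')
    out.append("<Points>")
    out.append(
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">'
    )
    out.append(_fmt(nodes))
    out.append("</DataArray>")
    out.append("</Points>")
    out.append("<Cells>")
    out.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    out.append(_fmt(np.concatenate(conn_parts)))
    out.append("</DataArray>")
    out.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    out.append(_fmt(np.concatenate(offsets)))
    out.append("</DataArray>")
    out.append('<DataArray type="UInt8" Name="types" format="ascii">')
    out.append(_fmt(np.concatenate(types)))
    out.append("</DataArray>")
    out.append("</Cells>")

    for tag, data in (("CellData", cell_data), ("PointData", point_data)):
        out.append(f"<{tag}>")
        for name, arr in (data or {}).items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            vtype = "Int64" if arr.dtype.kind in "iu" else "Float64"
            out.append(
                f'<DataArray type="{vtype}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            out.append(_fmt(arr))
            out.append("</DataArray>")
        out.append(f"</{tag}>")

    out.append("</Piece>")
    out.append("</UnstructuredGrid>")
    out.append("</VTKFile>")
    Path(path).write_text("\n".join(out))
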