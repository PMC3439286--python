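"""VTU (XML VTK UnstructuredGrid, ASCII) export of meshes and voxel fields.

Replaces a visualization pipeline: any standard viewer (ParaView, VisIt)
can load the written files.  Fields are per-voxel (= per-vertex) scalars.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

from .mesh import Mesh

__all__ = ["write_vtu", "read_vtu_point_data"]

_VTK_TET = 10
_VTK_TRI = 5
_VTK_LINE = 3


def write_vtu(path, mesh: Mesh, fields: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh plus named per-voxel fields as an ASCII .vtu file.

    Raises ``ValueError`` for fields of wrong length or containing
    non-finite values.
    """
    fields = fields or {}
    n = mesh.n_vertices
    for name, vals in fields.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != (n,):
            raise ValueError(f"field '{name}' has shape {vals.shape}, expected ({n},)")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"field '{name}' contains non-finite values")

    cells = []
    types = []
    for conn, t in ((mesh.tetrahedra, _VTK_TET), (mesh.triangles, _VTK_TRI), (mesh.lines, _VTK_LINE)):
        for el in conn:
            cells.append(el)
            types.append(t)
    offsets = np.cumsum([len(c) for c in cells])

    def fmt(arr, per_line=6):
        flat = np.asarray(arr).ravel()
        out = []
        for i in range(0, len(flat), per_line):
            out.append(" ".join(f"{v:.17g}" if isinstance(v, float) or flat.dtype.kind == "f" else str(v) for v in flat[i : i + per_line]))
        return "\n".join(out)

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write("<UnstructuredGrid>\n")
        fh.write(f'<Piece NumberOfPoints="{n}" NumberOfCells="{len(cells)}">\n')
        fh.write("<PointData>\n")
        for name, vals in fields.items():
            fh.write(f'<DataArray type="Float64" Name="{name}" format="ascii">\n')
            fh.write(fmt(np.asarray(vals, dtype=float)))
            fh.write("\n</DataArray>\n")
        fh.write("</PointData>\n")
        fh.write("<Points>\n")
        fh.write('<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        fh.write(fmt(mesh.vertices))
        fh.write("\n</DataArray>\n</Points>\n<Cells>\n")
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        fh.write(fmt(np.concatenate([np.asarray(c) for c in cells]) if cells else np.array([], dtype=int)))
        fh.write("\n</DataArray>\n")
        fh.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write(fmt(offsets))
        fh.write("\n</DataArray>\n")
        fh.write('<DataArray type="UInt8" Name="types" format="ascii">\n')
        fh.write(fmt(np.asarray(types)))
        fh.write("\n</DataArray>\n</Cells>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


def read_vtu_point_data(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Parse points and per-point scalar fields back from a .vtu file."""
    tree = ET.parse(path)
    piece = tree.getroot().find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError("not a VTU UnstructuredGrid file")
    pts_da = piece.find("./Points/DataArray")
    pts = np.array(pts_da.text.split(), dtype=float).reshape(-1, 3)
    fields = {}
    for da in piece.findall("./PointData/DataArray"):
        fields[da.get("Name")] = np.array(da.text.split(), dtype=float)
    return pts, fields
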