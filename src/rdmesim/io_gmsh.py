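"""Gmsh ``.msh`` ASCII I/O (format versions 2.2 and 4.1).

Physical-group integer tags map to subdomain labels; in v4.1 files the
``$Entities`` section is consulted to resolve the physical tag of each
entity block, falling back to the entity tag itself when no physical
group is defined.  Gmsh's 1-based node numbering is converted to 0-based
at this boundary, and nodes referenced by no element are dropped (with an
index remap).
"""

from __future__ import annotations

import numpy as np

from .mesh import Mesh

__all__ = ["read_gmsh", "write_gmsh", "GmshParseError", "UnsupportedFormatError"]

_ELEM_NODES = {1: 2, 2: 3, 4: 4}  # gmsh element type -> node count (line, tri, tet)


class GmshParseError(ValueError):
    pass


class UnsupportedFormatError(GmshParseError):
    pass


def read_gmsh(path) -> Mesh:
    """Read a Gmsh ASCII v2.2 or v4.1 file into a :class:`Mesh`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    sections = _split_sections(lines)
    if "MeshFormat" not in sections:
        raise GmshParseError("missing $MeshFormat section")
    fmt = sections["MeshFormat"][0].split()
    version, file_type = fmt[0], int(fmt[1])
    if file_type != 0:
        raise UnsupportedFormatError("binary .msh files are not supported")
    if version.startswith("2"):
        nodes, node_ids, elems = _parse_v2(sections)
    elif version.startswith("4"):
        nodes, node_ids, elems = _parse_v41(sections)
    else:
        raise UnsupportedFormatError(f"unsupported .msh version {version}")
    return _build_mesh(nodes, node_ids, elems)


def _split_sections(lines: list[str]) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    name = None
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("$End"):
            name = None
        elif s.startswith("$"):
            name = s[1:]
            sections[name] = []
        elif name is not None:
            sections[name].append(s)
    return sections


def _parse_v2(sections):
    try:
        node_lines = sections["Nodes"]
        elem_lines = sections["Elements"]
    except KeyError as e:
        raise GmshParseError(f"missing ${e.args[0]} section") from None
    n = int(node_lines[0])
    node_ids = np.empty(n, dtype=np.int64)
    nodes = np.empty((n, 3))
    for i, ln in enumerate(node_lines[1 : n + 1]):
        parts = ln.split()
        node_ids[i] = int(parts[0])
        nodes[i] = [float(v) for v in parts[1:4]]
    m = int(elem_lines[0])
    elems = []  # (etype, phys_tag, node_ids)
    for ln in elem_lines[1 : m + 1]:
        parts = [int(v) for v in ln.split()]
        eid, etype, ntags = parts[0], parts[1], parts[2]
        tags = parts[3 : 3 + ntags]
        conn = parts[3 + ntags :]
        if etype not in _ELEM_NODES:
            continue  # points / higher-order elements are ignored
        if len(conn) != _ELEM_NODES[etype]:
            raise GmshParseError(f"element {eid}: expected {_ELEM_NODES[etype]} nodes, got {len(conn)}")
        phys = tags[0] if tags else 0
        elems.append((etype, phys, conn))
    return nodes, node_ids, elems


def _parse_v41(sections):
    try:
        node_lines = sections["Nodes"]
        elem_lines = sections["Elements"]
    except KeyError as e:
        raise GmshParseError(f"missing ${e.args[0]} section") from None
    phys_of_entity = _entity_physical_tags(sections.get("Entities", []))

    header = node_lines[0].split()
    n_blocks, n_nodes = int(header[0]), int(header[1])
    node_ids, nodes = [], []
    pos = 1
    for _ in range(n_blocks):
        _dim, _tag, _param, nb = (int(v) for v in node_lines[pos].split())
        pos += 1
        ids = [int(node_lines[pos + i]) for i in range(nb)]
        pos += nb
        for i in range(nb):
            nodes.append([float(v) for v in node_lines[pos + i].split()[:3]])
        pos += nb
        node_ids.extend(ids)
    if len(node_ids) != n_nodes:
        raise GmshParseError("node count mismatch in $Nodes")

    header = elem_lines[0].split()
    n_blocks = int(header[0])
    elems = []
    pos = 1
    for _ in range(n_blocks):
        dim, tag, etype, nb = (int(v) for v in elem_lines[pos].split())
        pos += 1
        label = phys_of_entity.get((dim, tag), tag)
        for i in range(nb):
            parts = [int(v) for v in elem_lines[pos + i].split()]
            if etype in _ELEM_NODES:
                conn = parts[1:]
                if len(conn) != _ELEM_NODES[etype]:
                    raise GmshParseError(f"element {parts[0]}: bad node count in block {_}")
                elems.append((etype, label, conn))
        pos += nb
    return np.asarray(nodes), np.asarray(node_ids, dtype=np.int64), elems


def _entity_physical_tags(lines: list[str]) -> dict[tuple[int, int], int]:
    """Map (dim, entityTag) -> first physical tag from a v4.1 $Entities block."""
    out: dict[tuple[int, int], int] = {}
    if not lines:
        return out
    counts = [int(v) for v in lines[0].split()]  # nPoints nCurves nSurfaces nVolumes
    pos = 1
    for dim, cnt in enumerate(counts):
        for _ in range(cnt):
            parts = lines[pos].split()
            pos += 1
            tag = int(parts[0])
            # points: tag x y z nPhys ...; others: tag 6 bbox floats nPhys ...
            k = 4 if dim == 0 else 7
            nphys = int(parts[k])
            if nphys > 0:
                out[(dim, tag)] = int(parts[k + 1])
    return out


def _build_mesh(nodes, node_ids, elems) -> Mesh:
    id_map = {int(g): i for i, g in enumerate(node_ids)}
    tets, tris, segs = [], [], []
    tet_sd, tri_sd, seg_sd = [], [], []
    for etype, label, conn in elems:
        try:
            c = [id_map[v] for v in conn]
        except KeyError as e:
            raise GmshParseError(f"element references unknown node {e.args[0]}") from None
        if etype == 4:
            tets.append(c)
            tet_sd.append(label)
        elif etype == 2:
            tris.append(c)
            tri_sd.append(label)
        else:
            segs.append(c)
            seg_sd.append(label)
    used = sorted({v for group in (tets, tris, segs) for el in group for v in el})
    remap = {old: new for new, old in enumerate(used)}
    verts = nodes[used]

    def conv(conn, width):
        if not conn:
            return np.zeros((0, width), dtype=np.int64)
        return np.array([[remap[v] for v in el] for el in conn], dtype=np.int64)

    return Mesh(
        verts,
        tetrahedra=conv(tets, 4),
        triangles=conv(tris, 3),
        lines=conv(segs, 2),
        tet_subdomain=np.asarray(tet_sd, dtype=np.int64),
        tri_subdomain=np.asarray(tri_sd, dtype=np.int64),
        line_subdomain=np.asarray(seg_sd, dtype=np.int64),
    )


def write_gmsh(path, mesh: Mesh) -> None:
    """Write a :class:`Mesh` as Gmsh ASCII v2.2 (labels as physical tags)."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, (x, y, z) in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n")
        n_el = len(mesh.tetrahedra) + len(mesh.triangles) + len(mesh.lines)
        fh.write(f"$Elements\n{n_el}\n")
        eid = 1
        for conn, labels, etype in (
            (mesh.lines, mesh.line_subdomain, 1),
            (mesh.triangles, mesh.tri_subdomain, 2),
            (mesh.tetrahedra, mesh.tet_subdomain, 4),
        ):
            for el, lab in zip(conn, labels):
                nodes = " ".join(str(v + 1) for v in el)
                fh.write(f"{eid} {etype} 2 {lab} {lab} {nodes}\n")
                eid += 1
        fh.write("$EndElements\n")
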