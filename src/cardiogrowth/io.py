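"""Mesh and result serialization.

Meshes round-trip through ASCII VTK unstructured-grid (.vtu) files with
surface/node sets and any per-element vector fields (fiber triads,
transmural coordinate) stored as cell/point data arrays; an Abaqus-style
.inp export (nodes, C3D8 elements, surface definitions) is provided for
cross-checking in external solvers.  Writers emit plain text only.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

from .geometry import HexMesh

__all__ = ["write_vtu", "read_vtu", "write_inp", "write_energy_trace", "write_trace_csv"]

_VTK_HEX = 12


def _fmt(arr: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in np.atleast_2d(np.asarray(arr)))


def write_vtu(path, mesh: HexMesh, cell_data: dict = None, point_data: dict = None, coords: np.ndarray = None) -> None:
    """Write an ASCII .vtu file.

    ``coords`` overrides the node positions (deformed configurations);
    surface sets are encoded as point-data membership masks named
    ``set_<name>`` and cell/point data arrays are written verbatim.
    """
    nodes = mesh.nodes if coords is None else coords
    nn, ne = nodes.shape[0], mesh.elements.shape[0]
    point_data = dict(point_data or {})
    for name, ids in mesh.node_sets.items():
        m = np.zeros(nn)
        m[np.asarray(ids, dtype=np.int64)] = 1.0
        point_data[f"set_{name}"] = m

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian")
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(ug, "Piece", NumberOfPoints=str(nn), NumberOfCells=str(ne))

    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii")
    da.text = _fmt(nodes)

    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cells, "DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = _fmt(mesh.elements)
    offs = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = " ".join(str(8 * (i + 1)) for i in range(ne))
    typ = ET.SubElement(cells, "DataArray", type="UInt8", Name="types", format="ascii")
    typ.text = " ".join(str(_VTK_HEX) for _ in range(ne))

    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            nc = 1 if arr.ndim == 1 else arr.shape[1]
            d = ET.SubElement(pd, "DataArray", type="Float64", Name=name, NumberOfComponents=str(nc), format="ascii")
            d.text = _fmt(arr.reshape(nn, nc))
    if cell_data:
        cd = ET.SubElement(piece, "CellData")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            nc = 1 if arr.ndim == 1 else arr.shape[1]
            d = ET.SubElement(cd, "DataArray", type="Float64", Name=name, NumberOfComponents=str(nc), format="ascii")
            d.text = _fmt(arr.reshape(ne, nc))

    ET.ElementTree(root).write(str(path), xml_declaration=True)


def read_vtu(path):
    """Read an ASCII .vtu written by :func:`write_vtu`.

    Returns ``(mesh, cell_data, point_data)``; node sets are restored from
    the ``set_*`` membership masks (surface facet sets are not encoded in
    the VTK model and are left empty).
    """
    tree = ET.parse(str(path))
    piece = tree.getroot().find(".//Piece")
    nn = int(piece.get("NumberOfPoints"))
    ne = int(piece.get("NumberOfCells"))
    nodes = np.fromstring(piece.find("Points/DataArray").text, sep=" ").reshape(nn, 3)
    conn = None
    for da in piece.find("Cells"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text, sep=" ", dtype=np.int64).reshape(ne, 8)
    point_data, cell_data, node_sets = {}, {}, {}
    pd = piece.find("PointData")
    if pd is not None:
        for da in pd:
            nc = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ").reshape(nn, nc)
            arr = arr[:, 0] if nc == 1 else arr
            name = da.get("Name")
            if name.startswith("set_"):
                node_sets[name[4:]] = np.where(arr > 0.5)[0].astype(np.int64)
            else:
                point_data[name] = arr
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd:
            nc = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ").reshape(ne, nc)
            cell_data[da.get("Name")] = arr[:, 0] if nc == 1 else arr
    mesh = HexMesh(nodes=nodes, elements=conn, surface_sets={}, node_sets=node_sets, metadata={"source": str(path)})
    return mesh, cell_data, point_data


def write_inp(path, mesh: HexMesh, part_name: str = "LV") -> None:
    """Export nodes, C3D8 elements and surface node sets (Abaqus flavour)."""
    with open(path, "w") as fh:
        fh.write(f"*Heading\n** {part_name} export\n*Node\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
        fh.write("*Element, type=C3D8\n")
        for i, el in enumerate(mesh.elements, start=1):
            fh.write(f"{i}, " + ", ".join(str(int(n) + 1) for n in el) + "\n")
        for name, ids in mesh.node_sets.items():
            fh.write(f"*Nset, nset={name}\n")
            ids = [str(int(n) + 1) for n in np.asarray(ids)]
            for k in range(0, len(ids), 12):
                fh.write(", ".join(ids[k : k + 12]) + "\n")
        for name, quads in mesh.surface_sets.items():
            used = [str(int(n) + 1) for n in np.unique(quads)]
            fh.write(f"*Nset, nset=surf_{name}\n")
            for k in range(0, len(used), 12):
                fh.write(", ".join(used[k : k + 12]) + "\n")


def write_energy_trace(path, trace: np.ndarray) -> None:
    """CSV energy trace: pseudo-time, kinetic, internal, external work, ratio."""
    header = "t,kinetic,internal,external_work,ke_ratio"
    np.savetxt(str(path), trace, delimiter=",", header=header, comments="")


def write_trace_csv(path, trace) -> None:
    """CSV of the optimization trace (iteration, alpha_f, alpha_n, dice)."""
    with open(path, "w") as fh:
        fh.write("index,alpha_f,alpha_n,dice,provenance\n")
        for i, s in enumerate(trace):
            fh.write(f"{i},{s.params.alpha_f},{s.params.alpha_n},{s.score},{s.provenance}\n")
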