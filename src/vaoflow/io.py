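"""Export of meshes, fields and wall histories to standard formats.

VTU (VTK XML unstructured grid, ASCII) is written directly - the format is
a small XML schema and writing it in-package avoids an extra dependency.
STL export extrudes the planar lumen outline into a 3D surface for users
with external (3D) solvers.
"""

from __future__ import annotations

from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .geometry import LabeledMesh, Outline

__all__ = ["write_vtu", "write_wall_history_csv", "write_outline_csv",
           "export_extruded_stl"]


def write_vtu(mesh: LabeledMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """ASCII VTU file with optional per-vertex / per-triangle scalar fields."""
    nodes = np.column_stack([mesh.nodes, np.zeros(len(mesh.nodes))])
    tris = mesh.triangles
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{len(tris)}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "\n".join(" ".join(f"{v:.9g}" for v in row) for row in nodes),
        "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(map(str, t)) for t in tris),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(3 * (i + 1)) for i in range(len(tris))),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("5" for _ in range(len(tris))),
        "</DataArray>", "</Cells>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            lines.append(f'<DataArray type="Float64" Name="{escape(name)}" '
                         'format="ascii">')
            lines.append(" ".join(f"{v:.9g}" for v in np.asarray(arr)))
            lines.append("</DataArray>")
        lines.append("</PointData>")
    if cell_data:
        lines.append("<CellData>")
        for name, arr in cell_data.items():
            lines.append(f'<DataArray type="Float64" Name="{escape(name)}" '
                         'format="ascii">')
            lines.append(" ".join(f"{v:.9g}" for v in np.asarray(arr)))
            lines.append("</DataArray>")
        lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_wall_history_csv(history, path) -> None:
    """Long-format CSV: facet, tag, arclength, t, tau_x, tau_y."""
    import pandas as pd
    nt, nf, _ = history.tau.shape
    f_idx = np.repeat(np.arange(nf), nt)
    t_idx = np.tile(np.arange(nt), nf)
    df = pd.DataFrame({
        "facet": f_idx,
        "tag": history.tags[f_idx],
        "arclength_mm": history.arclength[f_idx],
        "t_s": history.times[t_idx],
        "tau_x_pa": history.tau[t_idx, f_idx, 0],
        "tau_y_pa": history.tau[t_idx, f_idx, 1],
    })
    df.to_csv(path, index=False)


def write_outline_csv(outline: Outline, path) -> None:
    import pandas as pd
    rows = []
    for tag, pts in outline.segments:
        for x, y in pts:
            rows.append({"tag": tag, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def export_extruded_stl(outline: Outline, path, depth_mm: float | None = None,
                        h: float = 1.0) -> int:
    """Extrude the planar lumen outline into a closed 3D surface STL.

    The extrusion depth defaults to the VA diameter, giving external 3D
    solvers a duct of the analysed planar cross-section.  Caps are built
    from the package's own planar triangulation at size ``h``; the side
    wall follows the boundary facets.  Returns the number of facets.
    """
    from .geometry import generate_mesh

    depth = depth_mm if depth_mm is not None else outline.spec.d_va
    mesh = generate_mesh(outline, h)
    v = mesh.nodes
    facets = []

    def tri3(p0, p1, p2):
        a = np.subtract(p1, p0)
        b = np.subtract(p2, p0)
        n = np.cross(a, b)
        norm = np.linalg.norm(n)
        n = n / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        facets.append((n, p0, p1, p2))

    for t in mesh.triangles:
        p = [(v[i][0], v[i][1], 0.0) for i in t]
        tri3(p[0], p[2], p[1])                      # bottom cap, outward -z
        q = [(v[i][0], v[i][1], depth) for i in t]
        tri3(q[0], q[1], q[2])                      # top cap, outward +z
    for (i, j) in mesh.boundary_edges:
        a0 = (v[i][0], v[i][1], 0.0)
        b0 = (v[j][0], v[j][1], 0.0)
        a1 = (v[i][0], v[i][1], depth)
        b1 = (v[j][0], v[j][1], depth)
        tri3(a0, b0, b1)
        tri3(a0, b1, a1)

    with open(path, "w") as fh:
        fh.write("solid vaoflow\n")
        for n, p0, p1, p2 in facets:
            fh.write(f"facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n")
            fh.write(" outer loop\n")
            for p in (p0, p1, p2):
                fh.write(f"  vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid vaoflow\n")
    return len(facets)
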