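"""Minimal legacy-ASCII VTK writers for surfaces and tet meshes."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _write_points(fh, pts: np.ndarray) -> None:
    fh.write(f"POINTS {len(pts)} double\n")
    for p in pts:
        fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def write_vtk_surface(path: str | Path, mesh) -> None:
    """Tagged triangle surface as legacy POLYDATA with face tags."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nivus2fe surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        _write_points(fh, mesh.vertices)
        f = mesh.faces
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_DATA {len(f)}\n")
        fh.write("SCALARS face_tag int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(t)) for t in mesh.tags) + "\n")


def write_vtk_volume(path: str | Path, mesh, point_data: dict | None = None,
                     cell_data: dict | None = None) -> None:
    """Tet mesh as legacy UNSTRUCTURED_GRID with material labels and any
    extra point/cell fields (scalars or 3-vectors)."""
    cell_data = dict(cell_data or {})
    if mesh.material is not None and "material" not in cell_data:
        cell_data["material"] = mesh.material
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nivus2fe volume mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        _write_points(fh, mesh.nodes)
        e = mesh.elements
        npe = e.shape[1]
        fh.write(f"CELLS {len(e)} {(npe + 1) * len(e)}\n")
        for el in e:
            fh.write(f"{npe} " + " ".join(str(int(x)) for x in el) + "\n")
        vtk_type = 24 if npe == 10 else 10  # quadratic / linear tetra
        fh.write(f"CELL_TYPES {len(e)}\n")
        fh.write("\n".join([str(vtk_type)] * len(e)) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {len(e)}\n")
            for name, arr in cell_data.items():
                _write_field(fh, name, np.asarray(arr))
        if point_data:
            fh.write(f"POINT_DATA {len(mesh.nodes)}\n")
            for name, arr in point_data.items():
                _write_field(fh, name, np.asarray(arr))


def _write_field(fh, name: str, arr: np.ndarray) -> None:
    if arr.ndim == 2 and arr.shape[1] == 3:
        fh.write(f"VECTORS {name} double\n")
        for v in arr:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    elif np.issubdtype(arr.dtype, np.integer):
        fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(x)) for x in arr) + "\n")
    else:
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{float(x):.9g}" for x in arr) + "\n")
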