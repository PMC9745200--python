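"""FEBio model export (spec 3.0 XML).

Writes the labeled tet4 mesh, per-material neo-Hookean cards (E converted
to MPa for the mm/N/MPa unit system FEBio expects with mm meshes), the
luminal pressure surface load with a linear one-second load curve, and the
fixed-displacement node set, so the identical problem can be solved in
FEBio. A small parser for the counts is included for round-trip checks.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fea import FEModel
from .labels import TISSUE_NAMES, Tissue

__all__ = ["export_feb", "read_feb_summary", "FebSummary"]


def export_feb(model: FEModel, path: str | Path) -> None:
    """Write the model as an FEBio spec-3.0 .feb document."""
    mesh = model.mesh
    if mesh.is_tet10:
        raise NotImplementedError(
            "tet10 export is not supported; export the tet4 parent mesh instead")

    root = ET.Element("febio_spec", version="3.0")
    ET.SubElement(root, "Module", type="solid")

    # materials, one per label present, grouped element domains
    labels = sorted(int(l) for l in np.unique(mesh.material))
    mat_el = ET.SubElement(root, "Material")
    mat_id = {}
    for k, lbl in enumerate(labels, start=1):
        mat = model.table[lbl]
        m = ET.SubElement(mat_el, "material", id=str(k),
                          name=mat.name, type="neo-Hookean")
        ET.SubElement(m, "density").text = "1e-9"
        ET.SubElement(m, "E").text = f"{mat.youngs_modulus_mpa:g}"
        ET.SubElement(m, "v").text = f"{mat.poisson_ratio:g}"
        mat_id[lbl] = k

    geo = ET.SubElement(root, "Mesh")
    nodes_el = ET.SubElement(geo, "Nodes", name="nodes")
    for i, p in enumerate(mesh.nodes, start=1):
        ET.SubElement(nodes_el, "node", id=str(i)).text = \
            f"{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}"

    for lbl in labels:
        sel = np.flatnonzero(mesh.material == lbl)
        part = ET.SubElement(geo, "Elements", type="tet4",
                             name=f"part_{TISSUE_NAMES[Tissue(lbl)]}")
        for eid in sel:
            el = mesh.elements[eid]
            ET.SubElement(part, "elem", id=str(eid + 1)).text = \
                ",".join(str(int(x) + 1) for x in el[:4])

    surf = ET.SubElement(geo, "Surface", name="pressure_surface")
    for k, tri in enumerate(model.pressure_faces, start=1):
        ET.SubElement(surf, "tri3", id=str(k)).text = \
            ",".join(str(int(x) + 1) for x in tri[:3])

    fixed_nodes = model.fixed_nodes
    ns = ET.SubElement(geo, "NodeSet", name="fixed_nodes")
    for n in fixed_nodes:
        ET.SubElement(ns, "n", id=str(int(n) + 1))

    domains = ET.SubElement(root, "MeshDomains")
    for lbl in labels:
        ET.SubElement(domains, "SolidDomain",
                      name=f"part_{TISSUE_NAMES[Tissue(lbl)]}",
                      mat=model.table[lbl].name)

    bnd = ET.SubElement(root, "Boundary")
    fix = ET.SubElement(bnd, "bc", type="fix", node_set="fixed_nodes")
    ET.SubElement(fix, "dofs").text = "x,y,z"

    loads = ET.SubElement(root, "Loads")
    pl = ET.SubElement(loads, "surface_load", type="pressure",
                       surface="pressure_surface")
    # kPa -> MPa for the mm/N/MPa system
    pr = ET.SubElement(pl, "pressure", lc="1")
    pr.text = f"{model.pressure_kpa * 1e-3:g}"
    ET.SubElement(pl, "linear").text = "0"
    ET.SubElement(pl, "symmetric_stiffness").text = "1"

    loaddata = ET.SubElement(root, "LoadData")
    lc = ET.SubElement(loaddata, "load_controller", id="1", type="loadcurve")
    ET.SubElement(lc, "interpolate").text = "LINEAR"
    pts = ET.SubElement(lc, "points")
    ET.SubElement(pts, "point").text = "0,0"
    ET.SubElement(pts, "point").text = "1,1"

    step = ET.SubElement(root, "Step")
    s1 = ET.SubElement(step, "step", id="1")
    ctrl = ET.SubElement(s1, "Control")
    ET.SubElement(ctrl, "analysis").text = "STATIC"
    ET.SubElement(ctrl, "time_steps").text = str(model.steps)
    ET.SubElement(ctrl, "step_size").text = f"{1.0 / model.steps:g}"

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="ISO-8859-1")


@dataclass
class FebSummary:
    n_nodes: int
    n_elements: int
    n_pressure_faces: int
    n_fixed_nodes: int
    materials: dict[str, tuple[float, float]]   # name -> (E MPa, nu)
    load_curve: list[tuple[float, float]]
    pressure_mpa: float


def read_feb_summary(path: str | Path) -> FebSummary:
    """Parse the counts and cards back out of a .feb file."""
    root = ET.parse(path).getroot()
    mesh = root.find("Mesh")
    n_nodes = len(mesh.find("Nodes"))
    n_elements = sum(len(part) for part in mesh.findall("Elements"))
    n_faces = len(mesh.find("Surface"))
    n_fixed = len(mesh.find("NodeSet"))
    mats = {}
    for m in root.find("Material"):
        mats[m.get("name")] = (float(m.find("E").text), float(m.find("v").text))
    curve = []
    for pt in root.find("LoadData").find("load_controller").find("points"):
        a, b = pt.text.split(",")
        curve.append((float(a), float(b)))
    pressure = float(root.find("Loads").find("surface_load").find("pressure").text)
    return FebSummary(n_nodes=n_nodes, n_elements=n_elements,
                      n_pressure_faces=n_faces, n_fixed_nodes=n_fixed,
                      materials=mats, load_curve=curve, pressure_mpa=pressure)
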