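"""Static pressurization of the labeled tetrahedral artery mesh.

Small-strain linear elasticity by default (the material table is linear
elastic); a compressible neo-Hookean law is selectable and agrees with the
linear law at small loads. Luminal pressure acts on the boundary faces
tagged as lumen (including the branch's luminal wall); nodes of the end
caps and branch caps are fixed in all axes. The load is ramped linearly
over a pseudo-time of 1 s in ``steps`` increments — for the linear law the
final state is independent of the number of increments (superposition), so
a single assembled solve at full load is performed.

Unit system: mm / kPa / mN. Young's moduli enter in kPa (converted from
the MPa material table), pressures in kPa, displacements in mm.

Post-processing: constant-strain Cauchy stress per tet4 element (centroid
stress for tet10), Von Mises effective stress, and volume-weighted nodal
smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .labels import TISSUE_NAMES, Tissue
from .materials import MaterialTable
from .surface_mesh import FaceTag
from .volume_mesh import TetMesh, _TET10_EDGES

__all__ = [
    "FEModel",
    "FEResult",
    "build_fe_model",
    "solve_static",
    "element_stress",
    "von_mises",
    "nodal_smooth",
    "stress_report",
    "equilibrium_residual",
]

#: boundary tags whose faces carry the luminal pressure
PRESSURE_TAGS = (FaceTag.LUMEN,)
#: boundary tags whose nodes are fixed in all axes
FIXED_TAGS = (FaceTag.CAP_PROXIMAL, FaceTag.CAP_DISTAL, FaceTag.BRANCH_CAP)


@dataclass
class FEModel:
    mesh: TetMesh
    table: MaterialTable
    pressure_kpa: float = 17.0
    steps: int = 10
    law: str = "linear"                    # "linear" | "neo-hookean"
    fixed_dofs: np.ndarray = None          # flat dof indices (3*node + axis)
    pressure_faces: np.ndarray = None      # (B, 3) or (B, 6) node triangles
    pressure_owner: np.ndarray = None      # (B,) owning elements

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.law not in ("linear", "neo-hookean"):
            raise ValueError(f"unknown material law {self.law!r}")
        if self.fixed_dofs is None or len(self.fixed_dofs) == 0:
            raise ValueError("fixed node set must be nonempty")

    @property
    def n_dofs(self) -> int:
        return 3 * len(self.mesh.nodes)

    @property
    def fixed_nodes(self) -> np.ndarray:
        return np.unique(np.asarray(self.fixed_dofs) // 3)


@dataclass
class FEResult:
    displacement: np.ndarray          # (N, 3) mm
    cauchy: np.ndarray                # (E, 6) Voigt xx yy zz xy yz zx, kPa
    von_mises_element: np.ndarray     # (E,) kPa
    von_mises_nodal: np.ndarray       # (N,) kPa
    solver_info: dict = field(default_factory=dict)

    def cauchy_tensor(self) -> np.ndarray:
        """(E, 3, 3) symmetric stress tensors."""
        s = self.cauchy
        t = np.zeros((len(s), 3, 3))
        t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
        t[:, 0, 1] = t[:, 1, 0] = s[:, 3]
        t[:, 1, 2] = t[:, 2, 1] = s[:, 4]
        t[:, 2, 0] = t[:, 0, 2] = s[:, 5]
        return t


def build_fe_model(mesh: TetMesh, table: MaterialTable, pressure_kpa: float = 17.0,
                   steps: int = 10, law: str = "linear") -> FEModel:
    """Derive boundary sets from tags and bundle the static problem.

    Pressure faces: boundary faces tagged lumen (main vessel and branch
    luminal wall carry the same tag). Fixed nodes: all nodes of proximal,
    distal and branch end caps, in every axis.
    """
    if mesh.boundary_faces is None or mesh.boundary_tags is None:
        raise ValueError("mesh carries no tagged boundary")
    if mesh.material is None:
        raise ValueError("mesh has no material labels")
    tags = mesh.boundary_tags
    if not np.isin(tags, [int(t) for t in FIXED_TAGS]).any():
        raise ValueError("no cap faces found; cannot fix the model")
    press = np.isin(tags, [int(t) for t in PRESSURE_TAGS])
    if not press.any():
        raise ValueError("no lumen faces found; nothing to pressurize")

    fixed_sel = np.isin(tags, [int(t) for t in FIXED_TAGS])
    fixed_nodes = np.unique(mesh.boundary_faces[fixed_sel])
    faces = mesh.boundary_faces[press]
    owner = mesh.boundary_owner[press]

    if mesh.is_tet10:
        fixed_nodes = _with_midside(mesh, fixed_nodes)
        faces = _tet10_faces(mesh, faces)

    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)[None, :]).ravel()
    return FEModel(mesh=mesh, table=table, pressure_kpa=pressure_kpa, steps=steps,
                   law=law, fixed_dofs=fixed_dofs, pressure_faces=faces,
                   pressure_owner=owner)


def _edge_mid_lookup(mesh: TetMesh):
    pairs = mesh.tet10_parent["edge_nodes"]
    n_corner = mesh.tet10_parent["n_corner_nodes"]
    key = pairs[:, 0] * n_corner + pairs[:, 1]
    order = np.argsort(key)
    return key[order], order + n_corner, n_corner


def _tet10_faces(mesh: TetMesh, faces: np.ndarray) -> np.ndarray:
    """Expand corner triangles to 6-node faces using the edge-node table."""
    key_s, mid_s, n_corner = _edge_mid_lookup(mesh)
    out = np.empty((len(faces), 6), dtype=np.int64)
    out[:, :3] = faces
    for k, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        p = np.sort(faces[:, [i, j]], axis=1)
        kk = p[:, 0] * n_corner + p[:, 1]
        pos = np.searchsorted(key_s, kk)
        out[:, 3 + k] = mid_s[pos]
    return out


def _with_midside(mesh: TetMesh, corner_nodes: np.ndarray) -> np.ndarray:
    """Corner node set plus every mid-edge node both of whose parents are in it."""
    pairs = mesh.tet10_parent["edge_nodes"]
    n_corner = mesh.tet10_parent["n_corner_nodes"]
    inset = np.zeros(n_corner, dtype=bool)
    inset[corner_nodes] = True
    mids = np.flatnonzero(inset[pairs[:, 0]] & inset[pairs[:, 1]]) + n_corner
    return np.concatenate([corner_nodes, mids])


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------


def _elastic_moduli(model: FEModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-element Lame parameters (kPa)."""
    E = model.table.youngs_kpa(model.mesh.material)
    nu = model.table.poisson(model.mesh.material)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    return lam, mu


def _d_matrices(lam: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """(E, 6, 6) isotropic stiffness in Voigt order xx yy zz xy yz zx."""
    n = len(lam)
    D = np.zeros((n, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def _tet4_gradients(nodes: np.ndarray, elements: np.ndarray):
    """Shape-function gradients (E, 4, 3) and volumes (E,) for tet4."""
    x = nodes[elements[:, :4]]
    J = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=1)
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    invJ = np.linalg.inv(J)
    # dN/dxi for L2, L3, L4; L1 = 1 - sum
    dN_nat = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0],
                       [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    grads = np.einsum("aj,eij->eai", dN_nat, invJ)
    return grads, vol


def _b_matrix_from_grads(grads: np.ndarray) -> np.ndarray:
    """(E, n_nodes, 3) gradients -> (E, 6, 3*n_nodes) strain-displacement."""
    e, nn, _ = grads.shape
    B = np.zeros((e, 6, 3 * nn))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    idx = np.arange(nn)
    B[:, 0, 3 * idx] = gx
    B[:, 1, 3 * idx + 1] = gy
    B[:, 2, 3 * idx + 2] = gz
    B[:, 3, 3 * idx] = gy
    B[:, 3, 3 * idx + 1] = gx
    B[:, 4, 3 * idx + 1] = gz
    B[:, 4, 3 * idx + 2] = gy
    B[:, 5, 3 * idx] = gz
    B[:, 5, 3 * idx + 2] = gx
    return B


# tet10 shape functions in barycentric form; node order: 4 corners then
# mid-edges 01 12 20 03 13 23 (matching volume_mesh._TET10_EDGES)
_GAUSS_A, _GAUSS_B = 0.5854101966249685, 0.1381966011250105
_TET_GAUSS = np.array([
    [_GAUSS_A, _GAUSS_B, _GAUSS_B, _GAUSS_B],
    [_GAUSS_B, _GAUSS_A, _GAUSS_B, _GAUSS_B],
    [_GAUSS_B, _GAUSS_B, _GAUSS_A, _GAUSS_B],
    [_GAUSS_B, _GAUSS_B, _GAUSS_B, _GAUSS_A],
])


def _tet10_dN_dL(L: np.ndarray) -> np.ndarray:
    """d(shape)/d(barycentric) at one barycentric point; (10, 4)."""
    L1, L2, L3, L4 = L
    d = np.zeros((10, 4))
    for c, Lc in enumerate((L1, L2, L3, L4)):
        d[c, c] = 4 * Lc - 1
    for k, (i, j) in enumerate(_TET10_EDGES):
        d[4 + k, i] = 4 * L[j]
        d[4 + k, j] = 4 * L[i]
    return d


def _tet10_gradients(nodes: np.ndarray, elements: np.ndarray):
    """Per-Gauss-point gradients (G, E, 10, 3) and weights (G, E)."""
    x = nodes[elements[:, :4]]
    J = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=1)
    vol = np.linalg.det(J) / 6.0
    invJ = np.linalg.inv(J)
    # dL/dx: L2..L4 map to natural coords; dL1/dx = -sum
    grads_g = []
    for g in range(len(_TET_GAUSS)):
        dNdL = _tet10_dN_dL(_TET_GAUSS[g])          # (10, 4)
        dNdnat = dNdL[:, 1:] - dNdL[:, :1]          # (10, 3) chain through L1
        grads_g.append(np.einsum("aj,eij->eai", dNdnat, invJ))
    w = vol / len(_TET_GAUSS)
    return np.stack(grads_g), w


def assemble_stiffness(model: FEModel, chunk: int = 60000) -> sparse.csr_matrix:
    """Global linear-elastic stiffness (kPa * mm) in CSR form."""
    mesh = model.mesh
    lam, mu = _elastic_moduli(model)
    D = _d_matrices(lam, mu)
    n_dof = model.n_dofs
    K = sparse.csr_matrix((n_dof, n_dof))
    elements = mesh.elements
    for lo in range(0, len(elements), chunk):
        sel = slice(lo, lo + chunk)
        els = elements[sel]
        if mesh.is_tet10:
            grads_g, w = _tet10_gradients(mesh.nodes, els)
            ke = 0.0
            for g in range(grads_g.shape[0]):
                B = _b_matrix_from_grads(grads_g[g])
                ke = ke + np.einsum("eik,eij,ejl,e->ekl", B, D[sel], B, w)
        else:
            grads, vol = _tet4_gradients(mesh.nodes, els)
            B = _b_matrix_from_grads(grads)
            ke = np.einsum("eik,eij,ejl,e->ekl", B, D[sel], B, vol)
        dofs = (3 * els[:, :, None] + np.arange(3)[None, None, :]).reshape(len(els), -1)
        nn = dofs.shape[1]
        rows = np.repeat(dofs, nn, axis=1).ravel()
        cols = np.tile(dofs, (1, nn)).ravel()
        K = K + sparse.coo_matrix((ke.ravel(), (rows, cols)),
                                  shape=(n_dof, n_dof)).tocsr()
    return K


def pressure_load(model: FEModel, coords: np.ndarray | None = None,
                  pressure: float | None = None) -> np.ndarray:
    """Consistent nodal forces (mN) for uniform pressure on the lumen faces.

    The face normal is directed into the wall (pressure pushes the solid).
    tet4 faces spread p*A/3 to each corner; straight-sided tet10 faces put
    p*A/3 on each mid-edge node and zero on corners (the consistent load
    for a quadratic triangle under constant pressure).
    """
    mesh = model.mesh
    x = mesh.nodes if coords is None else coords
    p = model.pressure_kpa if pressure is None else pressure
    faces = model.pressure_faces
    tri = x[faces[:, :3]]
    av = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area vectors
    # orient into the owning element
    own_cent = x[mesh.elements[model.pressure_owner][:, :4]].mean(axis=1)
    toward = own_cent - tri.mean(axis=1)
    sign = np.sign(np.einsum("ij,ij->i", av, toward))
    sign[sign == 0] = 1.0
    av *= sign[:, None]

    f = np.zeros((len(x), 3))
    if faces.shape[1] == 3:
        contrib = (p / 3.0) * av
        for k in range(3):
            np.add.at(f, faces[:, k], contrib)
    else:
        contrib = (p / 3.0) * av
        for k in range(3, 6):
            np.add.at(f, faces[:, k], contrib)
    return f.ravel()


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _solve_spd(K: sparse.csr_matrix, f: np.ndarray, method: str,
               rtol: float = 1e-10) -> tuple[np.ndarray, dict]:
    """Solve the reduced SPD system; returns (u, info)."""
    n = K.shape[0]
    info: dict = {"method": method, "n_dofs": n}
    if method == "direct":
        lu = spla.splu(K.tocsc())
        return lu.solve(f), info
    # Jacobi-preconditioned conjugate gradients
    d = K.diagonal()
    d[d <= 0] = 1.0
    inv_d = 1.0 / d
    M = spla.LinearOperator(K.shape, matvec=lambda r: inv_d * r)
    iters = 0

    def cb(_):
        nonlocal iters
        iters += 1

    u, code = spla.cg(K, f, M=M, rtol=rtol, atol=0.0, maxiter=40000, callback=cb)
    if code != 0:
        raise RuntimeError(f"CG failed to converge (code {code}, {iters} iterations)")
    info["iterations"] = iters
    return u, info


def _choose_method(model: FEModel, n_free: int) -> str:
    # SuperLU fill-in makes direct factorization uncompetitive beyond a few
    # tens of thousands of dofs for these quasi-shell meshes
    return "direct" if n_free <= 30_000 else "cg-jacobi"


def solve_static(model: FEModel, solver: str = "auto", rtol: float = 1e-10) -> FEResult:
    """Solve the pressurized static problem and post-process stresses.

    Linear law: one assembled solve at full load (identical to the ramped
    multi-step result by superposition). Neo-Hookean: Newton iterations per
    load increment with a follower pressure on the deformed lumen faces.
    """
    mesh = model.mesh
    n_dof = model.n_dofs
    free = np.setdiff1d(np.arange(n_dof), model.fixed_dofs)
    if len(free) == 0:
        raise ValueError("all degrees of freedom are fixed")

    if model.law == "neo-hookean":
        u, info = _solve_neo_hookean(model, free, rtol)
    else:
        K = assemble_stiffness(model)
        f = pressure_load(model)
        K_ff = K[free][:, free].tocsr()
        method = solver if solver != "auto" else _choose_method(model, len(free))
        u_f, info = _solve_spd(K_ff, f[free], method, rtol=rtol)
        u = np.zeros(n_dof)
        u[free] = u_f
        info["law"] = "linear"

    disp = u.reshape(-1, 3)
    cauchy = element_stress(model, disp)
    vm = von_mises(cauchy)
    vm_nodal = nodal_smooth(mesh, vm)
    return FEResult(displacement=disp, cauchy=cauchy, von_mises_element=vm,
                    von_mises_nodal=vm_nodal, solver_info=info)


def _solve_neo_hookean(model: FEModel, free: np.ndarray, rtol: float):
    mesh = model.mesh
    if mesh.is_tet10:
        raise NotImplementedError("neo-Hookean law supports tet4 meshes only")
    lam, mu = _elastic_moduli(model)
    grads, vol = _tet4_gradients(mesh.nodes, mesh.elements)
    n_dof = model.n_dofs
    u = np.zeros(n_dof)
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(
        len(mesh.elements), -1)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    total_newton = 0
    for step in range(1, model.steps + 1):
        p_step = model.pressure_kpa * step / model.steps
        for it in range(40):
            coords = mesh.nodes + u.reshape(-1, 3)
            f_ext = pressure_load(model, coords=coords, pressure=p_step)
            Fg = _def_gradients(mesh, grads, u)
            Pk, A = _neo_hookean_pk_tangent(Fg, lam, mu)
            f_int = np.zeros(n_dof)
            fi = np.einsum("e,eiJ,eaJ->eai", vol, Pk, grads).reshape(len(vol), -1)
            np.add.at(f_int, dofs.ravel(), fi.ravel())
            r = f_ext - f_int
            rn = np.linalg.norm(r[free])
            fn = max(np.linalg.norm(f_ext[free]), 1e-12)
            if rn / fn < 1e-8:
                break
            ke = np.einsum("e,eaJ,eiJkL,ebL->eaibk", vol, grads, A, grads)
            ke = ke.reshape(len(vol), 12, 12)
            K = sparse.coo_matrix((ke.ravel(), (rows, cols)),
                                  shape=(n_dof, n_dof)).tocsr()
            du = np.zeros(n_dof)
            du[free], _ = _solve_spd(K[free][:, free].tocsr(), r[free], "direct")
            u += du
            total_newton += 1
        else:
            raise RuntimeError(
                f"Newton failed to converge at step {step} ({it + 1} iterations)")
    return u, {"law": "neo-hookean", "newton_iterations": total_newton,
               "steps": model.steps}


def _def_gradients(mesh: TetMesh, grads: np.ndarray, u: np.ndarray) -> np.ndarray:
    ue = u.reshape(-1, 3)[mesh.elements[:, :4]]          # (E, 4, 3)
    H = np.einsum("eai,eaJ->eiJ", ue, grads)
    return np.eye(3)[None] + H


def _neo_hookean_pk_tangent(F: np.ndarray, lam: np.ndarray, mu: np.ndarray):
    """First Piola stress and tangent A_iJkL for the compressible
    neo-Hookean potential W = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2."""
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise RuntimeError("element inversion during Newton iteration")
    Finv = np.linalg.inv(F)
    FinvT = np.transpose(Finv, (0, 2, 1))
    lnJ = np.log(J)
    P = mu[:, None, None] * (F - FinvT) + (lam * lnJ)[:, None, None] * FinvT
    I3 = np.eye(3)
    coef = (lam * lnJ - mu)
    A = (mu[:, None, None, None, None] * np.einsum("ik,JL->iJkL", I3, I3)[None]
         + lam[:, None, None, None, None] * np.einsum("eiJ,ekL->eiJkL", FinvT, FinvT)
         - coef[:, None, None, None, None] * np.einsum("eiL,ekJ->eiJkL", FinvT, FinvT))
    return P, A


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def element_stress(model: FEModel, displacement: np.ndarray) -> np.ndarray:
    """Cauchy stress per element, Voigt (E, 6), kPa.

    Linear law: small-strain Hooke stress (constant per tet4; evaluated at
    the centroid for tet10). Neo-Hookean: sigma = J^-1 P F^T from the
    element deformation gradient.
    """
    mesh = model.mesh
    u = displacement.reshape(-1, 3)
    lam, mu = _elastic_moduli(model)
    if model.law == "neo-hookean":
        grads, _ = _tet4_gradients(mesh.nodes, mesh.elements)
        F = _def_gradients(mesh, grads, u.ravel())
        P, _ = _neo_hookean_pk_tangent(F, lam, mu)
        sig = np.einsum("e,eiJ,ekJ->eik", 1.0 / np.linalg.det(F), P, F)
        return _tensor_to_voigt(sig)

    D = _d_matrices(lam, mu)
    if mesh.is_tet10:
        # centroid gradients
        x = mesh.nodes[mesh.elements[:, :4]]
        Jm = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=1)
        invJ = np.linalg.inv(Jm)
        dNdL = _tet10_dN_dL(np.full(4, 0.25))
        dNdnat = dNdL[:, 1:] - dNdL[:, :1]
        grads = np.einsum("aj,eij->eai", dNdnat, invJ)
    else:
        grads, _ = _tet4_gradients(mesh.nodes, mesh.elements)
    B = _b_matrix_from_grads(grads)
    ue = u[mesh.elements].reshape(len(mesh.elements), -1)
    strain = np.einsum("eij,ej->ei", B, ue)
    return np.einsum("eij,ej->ei", D, strain)


def _tensor_to_voigt(t: np.ndarray) -> np.ndarray:
    sym = 0.5 * (t + np.transpose(t, (0, 2, 1)))
    return np.column_stack([sym[:, 0, 0], sym[:, 1, 1], sym[:, 2, 2],
                            sym[:, 0, 1], sym[:, 1, 2], sym[:, 2, 0]])


def von_mises(cauchy_voigt: np.ndarray) -> np.ndarray:
    """Effective (Von Mises) stress from Voigt stresses."""
    s = np.asarray(cauchy_voigt)
    sxx, syy, szz, sxy, syz, szx = (s[..., k] for k in range(6))
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                   + 3.0 * (sxy**2 + syz**2 + szx**2))


def nodal_smooth(mesh: TetMesh, element_field: np.ndarray) -> np.ndarray:
    """Volume-weighted average of an element field onto the nodes.

    Every node's value is a convex combination of its adjacent elements'
    values, so nodal extrema never exceed elemental extrema. Nodes that
    belong to no element are an error.
    """
    vols = np.abs(mesh.volumes())
    num = np.zeros(len(mesh.nodes))
    den = np.zeros(len(mesh.nodes))
    for k in range(mesh.elements.shape[1]):
        np.add.at(num, mesh.elements[:, k], vols * element_field)
        np.add.at(den, mesh.elements[:, k], vols)
    if np.any(den == 0):
        raise ValueError(f"{int((den == 0).sum())} isolated nodes have no adjacent element")
    return num / den


def stress_report(result: FEResult, mesh: TetMesh, table: MaterialTable) -> dict:
    """Per-material elemental Von Mises statistics plus global summaries."""
    vm = result.von_mises_element
    vols = mesh.volumes()
    out: dict[str, dict] = {"per_material": {}}
    for lbl in np.unique(mesh.material):
        sel = mesh.material == lbl
        name = TISSUE_NAMES[Tissue(int(lbl))]
        out["per_material"][name] = {
            "n_elements": int(sel.sum()),
            "volume_mm3": float(vols[sel].sum()),
            "mean_vm_kpa": float(vm[sel].mean()),
            "max_vm_kpa": float(vm[sel].max()),
        }
    out["max_nodal_vm_kpa"] = float(result.von_mises_nodal.max())
    out["mean_nodal_vm_kpa"] = float(result.von_mises_nodal.mean())
    out["max_displacement_mm"] = float(np.linalg.norm(result.displacement, axis=1).max())
    return out


def equilibrium_residual(model: FEModel, result: FEResult) -> float:
    """Relative imbalance between reactions at fixed dofs and applied loads.

    At convergence the reaction forces R = (K u - f)|fixed satisfy
    sum(R) + sum(f_applied) = 0 componentwise; returns the norm ratio.
    """
    K = assemble_stiffness(model)
    f = pressure_load(model)
    r = K @ result.displacement.ravel() - f
    fixed = np.asarray(model.fixed_dofs)
    reactions = r[fixed].reshape(-1, 3).sum(axis=0)
    applied = f.reshape(-1, 3).sum(axis=0)
    return float(np.linalg.norm(reactions + applied) /
                 max(np.linalg.norm(f.reshape(-1, 3), axis=1).sum(), 1e-12))
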