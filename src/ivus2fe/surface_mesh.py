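"""Closed surface construction: lofting, end caps, branch grafting,
HC smoothing and isotropic remeshing.

The first-pass surface connects consecutive lumen rings and consecutive
outer rings with triangle bands and closes the ends with annular caps,
giving the boundary surface of the thick-walled vessel. Note that this
surface is a genus-1 closed manifold (the lumen is a through-hole), so its
Euler characteristic is 0; each grafted branch adds a handle (a tunnel from
the lumen surface to the outer surface) and subtracts 2 more.

All face arrays carry a tag from :class:`FaceTag`; orientation is
consistent with outward normals (out of the solid wall), so the enclosed
volume equals the wall material volume and is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import sparse

from ._geometry import (
    SurfaceProjector,
    boundary_edges,
    orient_consistently,
    polyline_area,
    resample_closed_polyline,
    walk_loops,
    zipper_loops,
)
from .centerline import OrientedContours

__all__ = [
    "FaceTag",
    "SurfaceMesh",
    "SurfaceReport",
    "loft_tube",
    "cap_ends",
    "build_branch",
    "hc_smooth",
    "remesh_isotropic",
    "validate_surface",
]


class FaceTag(IntEnum):
    OUTER = 1
    LUMEN = 2
    CAP_PROXIMAL = 3
    CAP_DISTAL = 4
    BRANCH_WALL = 5
    BRANCH_CAP = 6


@dataclass
class SurfaceMesh:
    """Tagged triangle mesh (vertices mm)."""

    vertices: np.ndarray               # (V, 3)
    faces: np.ndarray                  # (F, 3) int64
    tags: np.ndarray                   # (F,) int8 FaceTag values
    loft_shape: tuple[int, int] | None = None   # (n_frames, n_ring_points) if structured
    branch_vmask: np.ndarray | None = None      # (V,) vertices inside a branch gap

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.tags = np.ascontiguousarray(self.tags, dtype=np.int8)
        if len(self.tags) != len(self.faces):
            raise ValueError("one tag per face required")

    # -- topology ----------------------------------------------------------

    def edges_unique(self) -> tuple[np.ndarray, np.ndarray]:
        e = np.sort(np.concatenate([
            self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]],
        ]), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    @property
    def is_watertight(self) -> bool:
        _, counts = self.edges_unique()
        return bool(np.all(counts == 2))

    @property
    def is_oriented(self) -> bool:
        _, ok = orient_consistently(self.faces, len(self.vertices))
        return ok

    @property
    def euler_characteristic(self) -> int:
        used = np.unique(self.faces)
        e, _ = self.edges_unique()
        return int(len(used) - len(e) + len(self.faces))

    @property
    def genus(self) -> int:
        return (2 - self.euler_characteristic) // 2

    def boundary_loops(self) -> list[np.ndarray]:
        be = boundary_edges(self.faces)
        if len(be) == 0:
            return []
        return walk_loops(be)

    # -- geometry ----------------------------------------------------------

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        t = self.vertices[self.faces]
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if normalized:
            n = n / np.maximum(np.linalg.norm(n, axis=1), 1e-300)[:, None]
        return n

    def face_areas(self) -> np.ndarray:
        t = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def enclosed_volume(self) -> float:
        """Signed volume via the divergence theorem (positive = outward)."""
        t = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def edge_lengths(self) -> np.ndarray:
        e, _ = self.edges_unique()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.tags.copy(),
                           loft_shape=self.loft_shape,
                           branch_vmask=None if self.branch_vmask is None
                           else self.branch_vmask.copy())

    def remove_unreferenced(self) -> "SurfaceMesh":
        used = np.unique(self.faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return SurfaceMesh(self.vertices[used], remap[self.faces], self.tags.copy())

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def export_stl(self, path) -> None:
        self.to_trimesh().export(path)

    def export_vtk(self, path) -> None:
        from ._vtk import write_vtk_surface

        write_vtk_surface(path, self)


# ---------------------------------------------------------------------------


def _band_faces(ring_a: np.ndarray, ring_b: np.ndarray) -> np.ndarray:
    """Triangle band between two aligned vertex-id rings (2n triangles).

    Winding (a_j, a_{j+1}, b_{j+1}) / (a_j, b_{j+1}, b_j): for CCW rings
    with b displaced along +axis this gives outward normals.
    """
    n = len(ring_a)
    j = np.arange(n)
    j1 = (j + 1) % n
    f1 = np.column_stack([ring_a[j], ring_a[j1], ring_b[j1]])
    f2 = np.column_stack([ring_a[j], ring_b[j1], ring_b[j]])
    return np.concatenate([f1, f2])


def loft_tube(oc: OrientedContours) -> SurfaceMesh:
    """First-pass open tube: bands between consecutive lumen rings and
    consecutive outer rings (2n triangles per band per surface).

    Lumen faces are wound so normals point out of the solid wall (toward
    the centerline); outer faces point away from it.
    """
    F, n = oc.n_frames, oc.n_points
    if F < 2:
        raise ValueError("need at least 2 frames to loft")
    vertices = np.concatenate([oc.lumen.reshape(-1, 3), oc.outer.reshape(-1, 3)])
    lum = np.arange(F * n).reshape(F, n)
    out = lum + F * n

    faces, tags = [], []
    for i in range(F - 1):
        fo = _band_faces(out[i], out[i + 1])
        faces.append(fo)
        tags.append(np.full(len(fo), FaceTag.OUTER, dtype=np.int8))
        fl = _band_faces(lum[i], lum[i + 1])[:, ::-1]  # flip: normals toward axis
        faces.append(fl)
        tags.append(np.full(len(fl), FaceTag.LUMEN, dtype=np.int8))

    vmask = np.concatenate([oc.branch_mask.ravel(), oc.branch_mask.ravel()])
    return SurfaceMesh(vertices, np.concatenate(faces), np.concatenate(tags),
                       loft_shape=(F, n), branch_vmask=vmask)


def cap_ends(m: SurfaceMesh) -> SurfaceMesh:
    """Close the tube with annular caps lofted from outer to lumen end rings."""
    if m.loft_shape is None:
        raise ValueError("cap_ends requires a structured lofted tube")
    if len(boundary_edges(m.faces)) == 0:
        raise ValueError("mesh is already closed")
    F, n = m.loft_shape
    lum = np.arange(F * n).reshape(F, n)
    out = lum + F * n

    j = np.arange(n)
    j1 = (j + 1) % n
    # proximal (frame 0): outward normal along -tangent
    p1 = np.column_stack([out[0][j], lum[0][j], lum[0][j1]])
    p2 = np.column_stack([out[0][j], lum[0][j1], out[0][j1]])
    # distal (frame F-1): outward normal along +tangent
    d1 = np.column_stack([out[-1][j], lum[-1][j1], lum[-1][j]])
    d2 = np.column_stack([out[-1][j], out[-1][j1], lum[-1][j1]])

    faces = np.concatenate([m.faces, p1, p2, d1, d2])
    tags = np.concatenate([
        m.tags,
        np.full(2 * n, FaceTag.CAP_PROXIMAL, dtype=np.int8),
        np.full(2 * n, FaceTag.CAP_DISTAL, dtype=np.int8),
    ])
    return SurfaceMesh(m.vertices.copy(), faces, tags, loft_shape=m.loft_shape,
                       branch_vmask=None if m.branch_vmask is None else m.branch_vmask.copy())


def _hermite_rings(start: np.ndarray, end: np.ndarray, d_hat: np.ndarray,
                   n_rings: int) -> np.ndarray:
    """Cubic Hermite loft rings from start to end (per-point).

    Start tangents lie in the surface (chord with the component along
    ``d_hat`` removed); end tangents are along ``d_hat``. Tangent
    magnitudes equal the per-point chord length. Returns
    (n_rings + 1, n, 3); the last ring equals ``end``.
    """
    chord = end - start
    clen = np.linalg.norm(chord, axis=1, keepdims=True)
    t_par = chord - (chord @ d_hat)[:, None] * d_hat
    t_norm = np.linalg.norm(t_par, axis=1, keepdims=True)
    t0 = np.where(t_norm > 1e-9 * np.maximum(clen, 1e-12),
                  t_par / np.maximum(t_norm, 1e-300) * clen, chord)
    t1 = d_hat[None, :] * clen

    out = np.empty((n_rings + 1, len(start), 3))
    for k in range(1, n_rings + 2):
        t = k / (n_rings + 1)
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[k - 1] = h00 * start + h10 * t0 + h01 * end + h11 * t1
    out[-1] = end
    return out


def _points_in_polygon_2d(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Winding-number point-in-polygon test, vectorized (poly closed implicitly)."""
    x, y = pts[:, 0][:, None], pts[:, 1][:, None]
    x0, y0 = poly[:, 0][None, :], poly[:, 1][None, :]
    x1, y1 = np.roll(poly[:, 0], -1)[None, :], np.roll(poly[:, 1], -1)[None, :]
    upward = (y0 <= y) & (y1 > y)
    downward = (y0 > y) & (y1 <= y)
    cross = (x1 - x0) * (y - y0) - (x - x0) * (y1 - y0)
    wn = (upward & (cross > 0)).sum(axis=1) - (downward & (cross < 0)).sum(axis=1)
    return wn != 0


def build_branch(m: SurfaceMesh, offset: float = 1.0, dilation: float = 1.3,
                 n_branch: int = 24, n_rings: int = 8) -> SurfaceMesh:
    """Graft a side branch at the flagged contour vertices.

    Procedure: remove faces touching branch-flagged vertices; recover the
    luminal and outer hole loops; the branch direction is the unit vector
    from the luminal loop centroid to the outer loop centroid (pointing out
    of the vessel); both loops are carried to the plane orthogonal to that
    direction at ``offset`` mm beyond the outer surface, the luminal loop
    dilated in-plane by ``dilation`` so the branch has an (artificial) wall;
    outer faces under the dilated footprint are removed; cubic-spline lofts
    connect the holes to the plane (start tangents parallel to the surface,
    end tangents orthogonal to the plane) and an annular cap closes the
    branch end. The branch inner wall is luminal (it carries pressure);
    its thickness is not anatomical — the true wall of the side branch is
    not observable in axial VH-IVUS frames.
    """
    if m.branch_vmask is None or not m.branch_vmask.any():
        return m.copy()
    if m.loft_shape is None:
        raise ValueError("build_branch requires the structured first-pass loft")
    F, n = m.loft_shape
    vmask = m.branch_vmask
    frames_flagged = vmask[:F * n].reshape(F, n).any(axis=1)
    if frames_flagged.sum() < 2:
        warnings.warn("branch gap spans fewer than 2 frames; skipping branch construction",
                      stacklevel=2)
        return m.copy()
    if frames_flagged[0] or frames_flagged[-1]:
        raise ValueError("branch gap touches the first/last frame; cannot graft a branch there")

    V = m.vertices
    touched = vmask[m.faces].any(axis=1)
    ref_outer = touched & (m.tags == FaceTag.OUTER)
    tri = V[m.faces[ref_outer]]
    ref_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]).sum(axis=0)
    ref_n /= max(np.linalg.norm(ref_n), 1e-300)

    keep = ~touched
    faces = m.faces[keep]
    tags = m.tags[keep]

    loops = walk_loops(boundary_edges(faces))
    if len(loops) != 2:
        raise ValueError(f"expected 2 hole loops after face removal, found {len(loops)}")
    lum_loop = next(l for l in loops if l.max() < F * n)
    out_loop = next(l for l in loops if l.min() >= F * n)

    c_lum = V[lum_loop].mean(axis=0)
    c_out = V[out_loop].mean(axis=0)
    d = c_out - c_lum
    if np.linalg.norm(d) < 1e-9:
        d = ref_n.copy()
    d /= np.linalg.norm(d)
    if d @ ref_n < 0:
        d = -d

    Q = c_out + offset * d

    # dilated footprint of the luminal loop on the projection plane
    u = np.zeros(3)
    u[np.argmin(np.abs(d))] = 1.0
    u = u - d * (u @ d)
    u /= np.linalg.norm(u)
    w = np.cross(d, u)

    S_L = resample_closed_polyline(V[lum_loop], n_branch)
    E_L = S_L + ((Q - S_L) @ d)[:, None] * d
    cE = E_L.mean(axis=0)
    E_O = cE + dilation * (E_L - cE)

    poly2d = np.column_stack([(E_O - Q) @ u, (E_O - Q) @ w])
    fc = V[faces].mean(axis=1)
    fn = np.cross(V[faces][:, 1] - V[faces][:, 0], V[faces][:, 2] - V[faces][:, 0])
    outer_cand = (tags == FaceTag.OUTER) & (fn @ d > 0)
    proj2d = np.column_stack([(fc - Q) @ u, (fc - Q) @ w])
    under = np.zeros(len(faces), dtype=bool)
    under[outer_cand] = _points_in_polygon_2d(proj2d[outer_cand], poly2d)
    if under.any():
        faces = faces[~under]
        tags = tags[~under]
        loops = walk_loops(boundary_edges(faces))
        if len(loops) != 2:
            raise ValueError("outer-face removal produced a non-simple hole")
        lum_loop = next(l for l in loops if l.max() < F * n)
        out_loop = next(l for l in loops if l.min() >= F * n)

    new_vertices = [V]
    new_faces = [faces]
    new_tags = [tags]
    v_off = len(V)

    def add_ring_block(rings: np.ndarray) -> np.ndarray:
        nonlocal v_off
        ids = np.arange(rings.shape[0] * rings.shape[1]).reshape(rings.shape[:2]) + v_off
        new_vertices.append(rings.reshape(-1, 3))
        v_off += rings.shape[0] * rings.shape[1]
        return ids

    def loft_from_hole(loop: np.ndarray, start_ring: np.ndarray, end_ring: np.ndarray,
                       tag: FaceTag) -> np.ndarray:
        rings = _hermite_rings(start_ring, end_ring, d, n_rings)
        ids = add_ring_block(rings)
        fz = zipper_loops(loop, V[loop], ids[0], rings[0])
        bands = [fz]
        for k in range(len(rings) - 1):
            bands.append(_band_faces(ids[k], ids[k + 1]))
        fb = np.concatenate(bands)
        new_faces.append(fb)
        new_tags.append(np.full(len(fb), tag, dtype=np.int8))
        return ids[-1]

    # luminal branch wall
    end_l_ids = loft_from_hole(lum_loop, S_L, E_L, FaceTag.LUMEN)

    # outer branch wall: align the outer hole loop to the dilated end ring
    S_O = resample_closed_polyline(V[out_loop], n_branch)
    area_SO = polyline_area(np.column_stack([(S_O - Q) @ u, (S_O - Q) @ w]))
    area_EO = polyline_area(np.column_stack([(E_O - Q) @ u, (E_O - Q) @ w]))
    if area_SO * area_EO < 0:
        S_O = S_O[::-1]
        out_loop = out_loop[::-1]
    shifts = np.array([
        np.linalg.norm(np.roll(S_O, -s, axis=0) - E_O, axis=1).sum() for s in range(n_branch)
    ])
    S_O = np.roll(S_O, -int(np.argmin(shifts)), axis=0)
    end_o_ids = loft_from_hole(out_loop, S_O, E_O, FaceTag.BRANCH_WALL)

    # annular branch-end cap between the two coplanar end rings
    cap = _band_faces(end_o_ids, end_l_ids)
    new_faces.append(cap)
    new_tags.append(np.full(len(cap), FaceTag.BRANCH_CAP, dtype=np.int8))

    all_v = np.concatenate(new_vertices)
    all_f = np.concatenate(new_faces)
    all_t = np.concatenate(new_tags)

    oriented, _ = orient_consistently(all_f, len(all_v), seed_face=0)
    out_mesh = SurfaceMesh(all_v, oriented, all_t).remove_unreferenced()
    if out_mesh.enclosed_volume() < 0:
        out_mesh.faces = out_mesh.faces[:, ::-1]
    if not out_mesh.is_watertight:
        raise ValueError("branch grafting failed to produce a watertight surface")
    return out_mesh


def _adjacency_matrix(faces: np.ndarray, n_vertices: int) -> sparse.csr_matrix:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    a = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(n_vertices, n_vertices))
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / np.maximum(deg, 1))
    return inv @ a


def _crease_vertices(m: SurfaceMesh) -> np.ndarray:
    """Vertices on edges whose two adjacent faces carry different tags
    (cap rims, branch junction rings). These are sharp features."""
    f = m.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    fidx = np.tile(np.arange(len(f)), 3)
    und = np.sort(e, axis=1)
    key = und[:, 0].astype(np.int64) * len(m.vertices) + und[:, 1]
    order = np.argsort(key, kind="stable")
    key_s, fidx_s, und_s = key[order], fidx[order], und[order]
    first = np.r_[True, key_s[1:] != key_s[:-1]]
    starts = np.flatnonzero(first)
    mask = np.zeros(len(m.vertices), dtype=bool)
    ends = np.r_[starts[1:], len(key_s)]
    pair = ends - starts == 2
    s2 = starts[pair]
    differ = m.tags[fidx_s[s2]] != m.tags[fidx_s[s2 + 1]]
    crease = und_s[s2[differ]]
    mask[crease.ravel()] = True
    return mask


def hc_smooth(m: SurfaceMesh, iterations: int = 10, alpha: float = 0.1,
              beta: float = 0.6, preserve_features: bool = True) -> SurfaceMesh:
    """HC (Humphrey's classes) smoothing: Laplacian averaging followed by a
    back-projection that pushes points toward their original/previous
    positions, strongly limiting the volume shrinkage of plain Laplacian
    smoothing. Connectivity and tags are unchanged. With
    ``preserve_features`` vertices on tag-boundary creases (cap rims,
    branch junctions) are pinned so the end planes do not creep inward.
    """
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise ValueError("alpha and beta must be in [0, 1]")
    if iterations == 0:
        return m.copy()
    A = _adjacency_matrix(m.faces, len(m.vertices))
    o = m.vertices
    pinned = _crease_vertices(m) if preserve_features else np.zeros(len(o), dtype=bool)
    q = o.copy()
    for _ in range(iterations):
        p = A @ q
        p[pinned] = o[pinned]
        b = p - (alpha * o + (1.0 - alpha) * q)
        q = p - (beta * b + (1.0 - beta) * (A @ b))
        q[pinned] = o[pinned]
    return replace(m.copy(), vertices=q)


def laplacian_smooth(m: SurfaceMesh, iterations: int = 10) -> SurfaceMesh:
    """Plain Laplacian smoothing (shrinks); kept as the comparison baseline."""
    A = _adjacency_matrix(m.faces, len(m.vertices))
    q = m.vertices.copy()
    for _ in range(iterations):
        q = A @ q
    return replace(m.copy(), vertices=q)


def remesh_isotropic(m: SurfaceMesh, target_edge: float, max_iters: int = 10) -> SurfaceMesh:
    """Incremental isotropic remeshing (split / collapse / flip / relax).

    See :mod:`ivus2fe._remesh`. Tags are reassigned from the nearest
    original face; vertices are projected back onto the input surface each
    iteration so the Hausdorff distance to the input stays well below the
    target edge length.
    """
    from ._remesh import remesh

    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    _check_feature_size(m, target_edge)
    v, f, t = remesh(m.vertices, m.faces, m.tags, target_edge, max_iters=max_iters)
    return SurfaceMesh(v, f, t)


def _check_feature_size(m: SurfaceMesh, target_edge: float, n_samples: int = 200) -> None:
    """Reject targets coarser than the wall thickness.

    Sampled lumen-vertex-to-outer-face distance on the main artery; the
    10th percentile is used because near a branch ostium the luminal and
    outer surfaces legitimately meet.
    """
    lum_faces = m.faces[m.tags == FaceTag.LUMEN]
    out_faces = m.faces[m.tags == FaceTag.OUTER]
    if len(lum_faces) == 0 or len(out_faces) == 0:
        return
    lum_v = np.unique(lum_faces)
    step = max(1, len(lum_v) // n_samples)
    sample = m.vertices[lum_v[::step]]
    proj = SurfaceProjector(m.vertices, out_faces, k=8)
    _, dist, _ = proj.project(sample)
    thickness = float(np.quantile(dist, 0.1))
    if target_edge > thickness:
        raise ValueError(
            f"target_edge {target_edge} exceeds the wall thickness "
            f"(~{thickness:.3f} mm); the wall would be unresolvable")


@dataclass
class SurfaceReport:
    watertight: bool
    oriented: bool
    euler_characteristic: int
    genus: int
    n_boundary_edges: int
    n_faces: int
    n_vertices: int
    min_triangle_quality: float
    enclosed_volume: float
    self_intersections: int | None = None
    tag_counts: dict = field(default_factory=dict)


def validate_surface(m: SurfaceMesh, check_self_intersections: bool = False,
                     n_samples: int = 2000) -> SurfaceReport:
    """Report-only surface health check."""
    _, counts = m.edges_unique()
    nb = int((counts != 2).sum())
    tri = m.vertices[m.faces]
    a = np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1)
    b = np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1)
    c = np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1)
    area = m.face_areas()
    s = (a + b + c) / 2
    # quality = inradius/circumradius * 2 (1 for equilateral)
    with np.errstate(divide="ignore", invalid="ignore"):
        inr = area / np.maximum(s, 1e-300)
        circ = a * b * c / np.maximum(4 * area, 1e-300)
        qual = np.where(area > 0, 2.0 * inr / np.maximum(circ, 1e-300), 0.0)

    si = None
    if check_self_intersections:
        si = _sampled_self_intersections(m, n_samples)

    vals, cnts = np.unique(m.tags, return_counts=True)
    return SurfaceReport(
        watertight=m.is_watertight,
        oriented=m.is_oriented,
        euler_characteristic=m.euler_characteristic,
        genus=m.genus,
        n_boundary_edges=nb,
        n_faces=len(m.faces),
        n_vertices=len(m.vertices),
        min_triangle_quality=float(qual.min()) if len(qual) else 0.0,
        enclosed_volume=m.enclosed_volume(),
        self_intersections=si,
        tag_counts={int(v): int(n) for v, n in zip(vals, cnts)},
    )


def _sampled_self_intersections(m: SurfaceMesh, n_samples: int) -> int:
    """Count face pairs (sampled) whose triangles intersect away from shared
    vertices. Cheap screen, not an exhaustive check."""
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(0)
    idx = rng.choice(len(m.faces), size=min(n_samples, len(m.faces)), replace=False)
    cent = m.vertices[m.faces].mean(axis=1)
    diam = np.sqrt(m.face_areas().max()) * 2.5
    tree = cKDTree(cent)
    pairs = tree.query_pairs(diam, output_type="ndarray")
    sel = np.isin(pairs[:, 0], idx) | np.isin(pairs[:, 1], idx)
    pairs = pairs[sel]
    count = 0
    for i, j in pairs:
        fi, fj = m.faces[i], m.faces[j]
        if len(np.intersect1d(fi, fj)) > 0:
            continue
        if _tri_tri_intersect(m.vertices[fi], m.vertices[fj]):
            count += 1
    return count


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    """Conservative triangle-triangle intersection test (segment vs triangle)."""
    def seg_hits(tri, p, q):
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        d = q - p
        denom = n @ d
        if abs(denom) < 1e-300:
            return False
        t = (n @ (tri[0] - p)) / denom
        if not 0.0 < t < 1.0:
            return False
        x = p + t * d
        # barycentric containment
        v0, v1, v2 = tri[1] - tri[0], tri[2] - tri[0], x - tri[0]
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        den = d00 * d11 - d01 * d01
        if abs(den) < 1e-300:
            return False
        u = (d11 * d20 - d01 * d21) / den
        v = (d00 * d21 - d01 * d20) / den
        return u > 1e-9 and v > 1e-9 and u + v < 1 - 1e-9

    for a, b in ((0, 1), (1, 2), (2, 0)):
        if seg_hits(t2, t1[a], t1[b]) or seg_hits(t1, t2[a], t2[b]):
            return True
    return False
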