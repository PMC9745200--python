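"""Incremental isotropic remeshing (split / collapse / flip / relax).

Classic edge-based remeshing: edges longer than 4/3 of the target are
split at their midpoint, edges shorter than 4/5 are collapsed (guarded by
the link condition and by flip/length checks), edges are flipped toward
valence 6, and vertices are relaxed tangentially and projected back onto
the original surface. All operations preserve the manifold, watertight
structure of the input; the result's mean edge length converges to the
target with a coefficient of variation well under 25%.
"""

from __future__ import annotations

import numpy as np

from ._geometry import SurfaceProjector


def _unique_edges(faces: np.ndarray, n_vertices: int):
    """Unique undirected edges plus the (up to 2) faces adjacent to each.

    Returns (edges (E,2), edge_faces (E,2) with -1 padding).
    """
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    face_idx = np.tile(np.arange(len(faces)), 3)
    und = np.sort(e, axis=1)
    key = und[:, 0].astype(np.int64) * n_vertices + und[:, 1]
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    uniq_mask = np.r_[True, key_s[1:] != key_s[:-1]]
    starts = np.flatnonzero(uniq_mask)
    edges = und[order[starts]]
    counts = np.diff(np.r_[starts, len(key_s)])
    ef = np.full((len(edges), 2), -1, dtype=np.int64)
    fidx_s = face_idx[order]
    ef[:, 0] = fidx_s[starts]
    two = counts >= 2
    ef[two, 1] = fidx_s[starts[two] + 1]
    return edges, ef


def _split_long(vertices: list[np.ndarray], faces: np.ndarray, thresh: float) -> np.ndarray:
    """Split all edges longer than thresh (several batched passes)."""
    v = np.concatenate(vertices) if len(vertices) > 1 else vertices[0]
    for _ in range(30):
        edges, ef = _unique_edges(faces, len(v))
        lens = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
        long_idx = np.flatnonzero(lens > thresh)
        if len(long_idx) == 0:
            break
        order = long_idx[np.argsort(-lens[long_idx], kind="stable")]
        face_used = np.zeros(len(faces), dtype=bool)
        chosen = []
        for ei in order:
            f1, f2 = ef[ei]
            if face_used[f1] or (f2 >= 0 and face_used[f2]):
                continue
            face_used[f1] = True
            if f2 >= 0:
                face_used[f2] = True
            chosen.append(ei)
        if not chosen:
            break
        chosen = np.array(chosen)
        mids = 0.5 * (v[edges[chosen, 0]] + v[edges[chosen, 1]])
        new_ids = np.arange(len(mids)) + len(v)
        v = np.concatenate([v, mids])

        del_faces = []
        add_faces = []
        for k, ei in enumerate(chosen):
            u, w = edges[ei]
            mid = new_ids[k]
            for fid in ef[ei]:
                if fid < 0:
                    continue
                tri = faces[fid]
                # find directed occurrence of the edge in this face
                for a in range(3):
                    p, q = tri[a], tri[(a + 1) % 3]
                    if (p == u and q == w) or (p == w and q == u):
                        opp = tri[(a + 2) % 3]
                        add_faces.append((p, mid, opp))
                        add_faces.append((mid, q, opp))
                        break
                del_faces.append(fid)
        keep = np.ones(len(faces), dtype=bool)
        keep[del_faces] = False
        faces = np.concatenate([faces[keep], np.array(add_faces, dtype=np.int64)])
    vertices.clear()
    vertices.append(v)
    return faces


def _collapse_short(v: np.ndarray, faces: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Collapse edges shorter than lo into their midpoint (batched, guarded)."""
    edges, ef = _unique_edges(faces, len(v))
    lens = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    cand = np.flatnonzero(lens < lo)
    if len(cand) == 0:
        return faces
    cand = cand[np.argsort(lens[cand], kind="stable")]

    nbrs: dict[int, set] = {}
    vfaces: dict[int, set] = {}
    f = faces.copy()
    for fid, (a, b, c) in enumerate(f):
        for x in (a, b, c):
            vfaces.setdefault(int(x), set()).add(fid)
        nbrs.setdefault(int(a), set()).update((int(b), int(c)))
        nbrs.setdefault(int(b), set()).update((int(a), int(c)))
        nbrs.setdefault(int(c), set()).update((int(a), int(b)))

    pos = v.copy()
    dead_f: set = set()
    dead_v: set = set()
    touched: set = set()
    hi2 = hi * hi

    for ei in cand:
        u, w = int(edges[ei, 0]), int(edges[ei, 1])
        if u in dead_v or w in dead_v or u in touched or w in touched:
            continue
        shared = (vfaces[u] & vfaces[w]) - dead_f
        if len(shared) != 2:
            continue
        opposite = set()
        for fid in shared:
            opposite.update(int(x) for x in f[fid] if x != u and x != w)
        if (nbrs[u] & nbrs[w]) != opposite:
            continue  # link condition: collapse would pinch the surface
        mid = 0.5 * (pos[u] + pos[w])
        ring = (nbrs[u] | nbrs[w]) - {u, w}
        d2 = np.sum((pos[list(ring)] - mid) ** 2, axis=1)
        if np.any(d2 > hi2):
            continue
        # normal-flip guard on surviving incident faces
        ok = True
        for fid in (vfaces[u] | vfaces[w]) - shared - dead_f:
            tri = f[fid]
            p_old = pos[tri]
            p_new = p_old.copy()
            for j in range(3):
                if tri[j] == u or tri[j] == w:
                    p_new[j] = mid
            n_old = np.cross(p_old[1] - p_old[0], p_old[2] - p_old[0])
            n_new = np.cross(p_new[1] - p_new[0], p_new[2] - p_new[0])
            if n_old @ n_new <= 1e-12 * max(n_old @ n_old, 1e-30):
                ok = False
                break
        if not ok:
            continue
        # apply
        pos[u] = mid
        dead_v.add(w)
        dead_f.update(shared)
        for fid in vfaces[w] - shared - dead_f:
            f[fid] = np.where(f[fid] == w, u, f[fid])
            vfaces[u].add(fid)
        nbrs[u] = ring
        for x in ring:
            nbrs[x].discard(w)
            nbrs[x].add(u)
        touched.update(ring | {u})

    keep = np.ones(len(f), dtype=bool)
    keep[list(dead_f)] = False
    return f[keep]


def _flip_valence(v: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip interior edges where it moves vertex valences toward 6."""
    edges, ef = _unique_edges(faces, len(v))
    val = np.zeros(len(v), dtype=np.int64)
    np.add.at(val, edges[:, 0], 1)
    np.add.at(val, edges[:, 1], 1)
    edge_set = {(int(a), int(b)) for a, b in edges}

    f = faces.copy()
    face_touched = np.zeros(len(f), dtype=bool)
    interior = np.flatnonzero(ef[:, 1] >= 0)
    for ei in interior:
        f1, f2 = int(ef[ei, 0]), int(ef[ei, 1])
        if face_touched[f1] or face_touched[f2]:
            continue
        u, w = int(edges[ei, 0]), int(edges[ei, 1])
        t1, t2 = f[f1], f[f2]
        if u not in t1 or w not in t1 or u not in t2 or w not in t2:
            continue  # stale adjacency after earlier flips
        a = int([x for x in t1 if x != u and x != w][0])
        b = int([x for x in t2 if x != u and x != w][0])
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key in edge_set:
            continue
        before = (val[u] - 6) ** 2 + (val[w] - 6) ** 2 + (val[a] - 6) ** 2 + (val[b] - 6) ** 2
        after = (val[u] - 7) ** 2 + (val[w] - 7) ** 2 + (val[a] - 5) ** 2 + (val[b] - 5) ** 2
        if after >= before or val[u] <= 3 or val[w] <= 3:
            continue
        # fa holds the directed edge u->w, fb holds w->u
        if _has_directed(t1, u, w):
            fa, fb = f1, f2
        elif _has_directed(t2, u, w):
            fa, fb = f2, f1
        else:
            continue
        a_op = int([x for x in f[fa] if x != u and x != w][0])
        b_op = int([x for x in f[fb] if x != u and x != w][0])
        n_old = np.cross(v[t1[1]] - v[t1[0]], v[t1[2]] - v[t1[0]]) + \
            np.cross(v[t2[1]] - v[t2[0]], v[t2[2]] - v[t2[0]])
        nf1 = np.array([a_op, u, b_op], dtype=np.int64)
        nf2 = np.array([b_op, w, a_op], dtype=np.int64)
        n1 = np.cross(v[nf1[1]] - v[nf1[0]], v[nf1[2]] - v[nf1[0]])
        n2 = np.cross(v[nf2[1]] - v[nf2[0]], v[nf2[2]] - v[nf2[0]])
        nn = max(float(n_old @ n_old), 1e-30)
        if (n1 @ n_old) <= 0.05 * nn or (n2 @ n_old) <= 0.05 * nn:
            continue
        f[fa] = nf1
        f[fb] = nf2
        face_touched[fa] = face_touched[fb] = True
        val[u] -= 1
        val[w] -= 1
        val[a] += 1
        val[b] += 1
        edge_set.discard((u, w) if u < w else (w, u))
        edge_set.add(key)
    return f


def _has_directed(tri, u, w) -> bool:
    for i in range(3):
        if tri[i] == u and tri[(i + 1) % 3] == w:
            return True
    return False


def _relax_project(v: np.ndarray, faces: np.ndarray, projector: SurfaceProjector,
                   lam: float = 0.5) -> np.ndarray:
    """Tangential Laplacian relaxation followed by projection to the
    original surface."""
    from scipy import sparse

    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(v), len(v)))
    deg = np.maximum(np.asarray(A.sum(axis=1)).ravel(), 1.0)
    c = (A @ v) / deg[:, None]

    tri = v[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(v)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    vn /= np.maximum(np.linalg.norm(vn, axis=1), 1e-300)[:, None]

    disp = c - v
    disp -= np.einsum("ij,ij->i", disp, vn)[:, None] * vn
    moved = v + lam * disp
    proj, _, _ = projector.project(moved, normals=vn)
    return proj


def _edge_stats(v: np.ndarray, faces: np.ndarray) -> tuple[float, float]:
    edges, _ = _unique_edges(faces, len(v))
    lens = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    return float(lens.mean()), float(lens.std() / lens.mean())


def remesh(vertices: np.ndarray, faces: np.ndarray, tags: np.ndarray,
           target_edge: float, max_iters: int = 10):
    """Remesh to uniform edge length; returns (vertices, faces, tags).

    Tags are reassigned to each new face from the nearest face of the
    input mesh (ties broken by candidate order, deterministic).
    """
    projector = SurfaceProjector(vertices, faces, k=8)
    L = target_edge / 1.07  # structured grids have mean edge ~1.07x spacing
    v = np.array(vertices, dtype=float)
    f = np.array(faces, dtype=np.int64)

    for it in range(max_iters):
        buf = [v]
        f = _split_long(buf, f, 4.0 / 3.0 * L)
        v = buf[0]
        f = _collapse_short(v, f, 0.8 * L, 4.0 / 3.0 * L)
        f = _flip_valence(v, f)
        v = _relax_project(v, f, projector)
        mean, cv = _edge_stats(v, f)
        if it >= 1 and abs(mean - target_edge) <= 0.08 * target_edge and cv < 0.22:
            break

    # compact unused vertices
    used = np.unique(f)
    remap = np.full(len(v), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    v = v[used]
    f = remap[f]

    cent = v[f].mean(axis=1)
    tri = v[f]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fn /= np.maximum(np.linalg.norm(fn, axis=1), 1e-300)[:, None]
    _, _, face_idx = projector.project(cent, normals=fn)
    new_tags = np.asarray(tags, dtype=np.int8)[face_idx]
    return v, f, new_tags
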