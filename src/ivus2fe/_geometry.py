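"""Low-level geometry utilities shared by the meshing modules.

Everything here is pure numpy/scipy; nothing depends on the domain types.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

# ---------------------------------------------------------------------------
# angular intervals (degrees, with wrap-around at 360)
# ---------------------------------------------------------------------------


def angle_in_interval(theta: np.ndarray, start: float, end: float) -> np.ndarray:
    """True where angle ``theta`` (deg) lies in [start, end), modulo 360.

    Supports wrapped intervals (start > end), e.g. (340, 20).
    """
    theta = np.asarray(theta) % 360.0
    start %= 360.0
    span = (end - start) % 360.0
    if span == 0.0:
        span = 360.0
    return (theta - start) % 360.0 < span


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Whether two angular intervals (deg, wrap-aware) intersect."""
    a0, a1 = a
    b0, b1 = b
    sa = (a1 - a0) % 360.0 or 360.0
    sb = (b1 - b0) % 360.0 or 360.0
    d = (b0 - a0) % 360.0
    return d < sa or (a0 - b0) % 360.0 < sb


def runs_of_true(mask: np.ndarray, circular: bool = True) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array as (start, length) pairs.

    With ``circular`` a run may wrap from the end of the array to the start.
    """
    n = len(mask)
    if n == 0 or not mask.any():
        return []
    if mask.all():
        return [(0, n)]
    m = np.asarray(mask, dtype=bool)
    # rotate so position 0 is False; runs then never wrap
    first_false = int(np.flatnonzero(~m)[0]) if circular else 0
    rm = np.roll(m, -first_false) if circular else m
    diff = np.diff(rm.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if rm[0]:
        starts = np.r_[0, starts]
    if rm[-1]:
        ends = np.r_[ends, n]
    return [((int(s) + first_false) % n, int(e - s)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# point / triangle queries
# ---------------------------------------------------------------------------


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on triangle ``tri[i]`` to ``points[i]``, vectorized.

    Parameters
    ----------
    points : (n, 3)
    tri : (n, 3, 3) triangle vertices

    Returns
    -------
    closest : (n, 3)
    dist2 : (n,) squared distances
    """
    # Ericson, Real-Time Collision Detection, 5.1.5 (vectorized)
    p = np.asarray(points, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def _set(mask, val):
        m = mask & ~done
        out[m] = val[m] if val.ndim == 2 else val
        done[m] = True

    _set((d1 <= 0) & (d2 <= 0), a)
    _set((d3 >= 0) & (d4 <= d3), b)
    _set((d6 >= 0) & (d5 <= d6), c)

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3 + 1e-300), 0.0)
    _set((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)

    vb = d5 * d2 - d1 * d6
    w_ac = d2 / (d2 - d6 + 1e-300)
    _set((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)

    va = d3 * d6 - d5 * d4
    w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6) + 1e-300)
    _set((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    denom = va + vb + vc
    v = vb / (denom + 1e-300)
    w = vc / (denom + 1e-300)
    _set(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)

    d = p - out
    return out, np.einsum("ij,ij->i", d, d)


class SurfaceProjector:
    """Project points onto a triangle mesh (nearest point / nearest face).

    Candidate faces come from a KD-tree over face centroids; the exact
    point-triangle distance is evaluated on the ``k`` nearest candidates.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 12):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.vertices[self.faces]
        self.centroids = self.tri.mean(axis=1)
        fn = np.cross(self.tri[:, 1] - self.tri[:, 0], self.tri[:, 2] - self.tri[:, 0])
        self.face_normals = fn / np.maximum(np.linalg.norm(fn, axis=1), 1e-300)[:, None]
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(self.faces))

    def project(self, points: np.ndarray, normals: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, distances, face indices).

        If per-point ``normals`` are given, candidate faces whose normal
        opposes the query normal are rejected (unless all candidates do);
        this keeps projections on the correct sheet where two surfaces of
        a thin wall run close together.

        Large queries are processed in chunks to bound the candidate
        expansion memory.
        """
        points = np.asarray(points, dtype=float)
        chunk = max(1, 1_200_000 // max(self.k, 1))
        if len(points) > chunk:
            parts = [
                self.project(points[lo:lo + chunk],
                             None if normals is None else normals[lo:lo + chunk])
                for lo in range(0, len(points), chunk)
            ]
            return (np.concatenate([p[0] for p in parts]),
                    np.concatenate([p[1] for p in parts]),
                    np.concatenate([p[2] for p in parts]))
        _, cand = self.tree.query(points, k=self.k)
        if self.k == 1:
            cand = cand[:, None]
        n, k = cand.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tri = self.tri[cand.ravel()]
        closest, d2 = closest_point_on_triangles(flat_pts, flat_tri)
        d2 = d2.reshape(n, k)
        if normals is not None:
            align = np.einsum("nkj,nj->nk", self.face_normals[cand], normals)
            masked = np.where(align > 0.0, d2, np.inf)
            any_ok = np.isfinite(masked).any(axis=1)
            d2 = np.where(any_ok[:, None], masked, d2)
        best = np.argmin(d2, axis=1)
        idx = np.arange(n)
        face_idx = cand[idx, best]
        return (
            closest.reshape(n, k, 3)[idx, best],
            np.sqrt(d2[idx, best]),
            face_idx,
        )


def points_inside_surface(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray,
                          chunk: int = 300_000) -> np.ndarray:
    """Inside/outside classification of points w.r.t. a watertight surface.

    Uses ray-parity along +z with a uniform 2D grid over triangle (x, y)
    bounding boxes. Query coordinates are nudged by a tiny deterministic
    offset so lattice-aligned points never hit triangle edges exactly.
    Large queries are processed in chunks to bound the candidate-pair
    expansion memory.
    """
    p_all = np.asarray(points, dtype=float)
    if len(p_all) > chunk:
        return np.concatenate([
            points_inside_surface(vertices, faces, p_all[lo:lo + chunk])
            for lo in range(0, len(p_all), chunk)
        ])
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    p = p_all
    if len(p) == 0:
        return np.zeros(0, dtype=bool)

    eps = 1.3e-7 * max(1.0, float(np.abs(v).max()))
    q = p[:, :2] + np.array([eps, 2.1 * eps])

    tri = v[f]  # (F, 3, 3)
    lo = tri[:, :, :2].min(axis=1)
    hi = tri[:, :, :2].max(axis=1)

    # grid sized to the median triangle footprint
    cell = max(float(np.median(hi - lo)), 1e-9)
    gmin = lo.min(axis=0)
    tlo = np.floor((lo - gmin) / cell).astype(np.int64)
    thi = np.floor((hi - gmin) / cell).astype(np.int64)
    ncell = thi.max(axis=0) + 1

    # triangle -> cells expansion
    spans = (thi - tlo + 1)
    reps = (spans[:, 0] * spans[:, 1]).astype(np.int64)
    tri_idx = np.repeat(np.arange(len(f)), reps)
    # local offsets per triangle
    offs = np.concatenate([
        np.stack(np.meshgrid(np.arange(sx), np.arange(sy), indexing="ij"), axis=-1).reshape(-1, 2)
        if (sx > 1 or sy > 1) else np.zeros((1, 2), dtype=np.int64)
        for sx, sy in spans
    ]) if len(f) else np.zeros((0, 2), dtype=np.int64)
    tri_cells = tlo[tri_idx] + offs
    tri_key = tri_cells[:, 0] * ncell[1] + tri_cells[:, 1]

    pq = np.floor((q - gmin) / cell).astype(np.int64)
    np.clip(pq[:, 0], 0, ncell[0] - 1, out=pq[:, 0])
    np.clip(pq[:, 1], 0, ncell[1] - 1, out=pq[:, 1])
    p_key = pq[:, 0] * ncell[1] + pq[:, 1]

    # bucket join: for each point, candidate triangles sharing its cell
    order_t = np.argsort(tri_key, kind="stable")
    tri_key_s = tri_key[order_t]
    tri_idx_s = tri_idx[order_t]
    starts = np.searchsorted(tri_key_s, p_key, side="left")
    ends = np.searchsorted(tri_key_s, p_key, side="right")
    counts = ends - starts

    if int(counts.sum()) == 0:
        return np.zeros(len(p), dtype=bool)

    crossings = np.zeros(len(p), dtype=np.int64)
    # process point groups bounded by candidate-pair count: cells under a
    # near-vertical wall can hold hundreds of stacked triangles, so pair
    # counts — not point counts — determine the memory footprint
    cum = np.cumsum(counts)
    max_pairs = 4_000_000
    group_starts = [0]
    while group_starts[-1] < len(p):
        s0 = group_starts[-1]
        base = cum[s0 - 1] if s0 > 0 else 0
        nxt = int(np.searchsorted(cum, base + max_pairs, side="right"))
        group_starts.append(max(nxt, s0 + 1))

    for s0, s1 in zip(group_starts[:-1], group_starts[1:]):
        sel = np.arange(s0, min(s1, len(p)))
        sel = sel[counts[sel] > 0]
        if len(sel) == 0:
            continue
        pair_pt = np.repeat(sel, counts[sel])
        pair_tri_pos = np.concatenate(
            [np.arange(starts[i], ends[i]) for i in sel])
        pair_tri = tri_idx_s[pair_tri_pos]

        a = tri[pair_tri, 0]
        b = tri[pair_tri, 1]
        c = tri[pair_tri, 2]
        px = q[pair_pt, 0]
        py = q[pair_pt, 1]

        d1 = (b[:, 0] - a[:, 0]) * (py - a[:, 1]) - (b[:, 1] - a[:, 1]) * (px - a[:, 0])
        d2 = (c[:, 0] - b[:, 0]) * (py - b[:, 1]) - (c[:, 1] - b[:, 1]) * (px - b[:, 0])
        d3 = (a[:, 0] - c[:, 0]) * (py - c[:, 1]) - (a[:, 1] - c[:, 1]) * (px - c[:, 0])
        hit = ((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | ((d1 <= 0) & (d2 <= 0) & (d3 <= 0))
        if not hit.any():
            continue

        pair_pt = pair_pt[hit]
        a, b, c = a[hit], b[hit], c[hit]
        px, py = px[hit], py[hit]

        # z of the triangle plane at (px, py)
        n = np.cross(b - a, c - a)
        nz = n[:, 2]
        ok = np.abs(nz) > 1e-300
        zhit = np.full(len(a), -np.inf)
        zhit[ok] = a[ok, 2] - (
            n[ok, 0] * (px[ok] - a[ok, 0]) + n[ok, 1] * (py[ok] - a[ok, 1])
        ) / nz[ok]
        above = zhit > p[pair_pt, 2]
        np.add.at(crossings, pair_pt[above], 1)

    return (crossings % 2) == 1


# ---------------------------------------------------------------------------
# loops and stitching
# ---------------------------------------------------------------------------


def boundary_edges(faces: np.ndarray) -> np.ndarray:
    """Directed edges of ``faces`` that have no opposite partner (B, 2)."""
    f = np.asarray(faces, dtype=np.int64)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    key_f = e[:, 0] * (f.max() + 1) + e[:, 1]
    key_r = e[:, 1] * (f.max() + 1) + e[:, 0]
    has_opp = np.isin(key_f, key_r)
    return e[~has_opp]


def walk_loops(edges: np.ndarray) -> list[np.ndarray]:
    """Chain directed edges into closed vertex loops.

    Raises ValueError if a vertex has more than one outgoing edge
    (non-manifold boundary).
    """
    nxt: dict[int, int] = {}
    for u, v in edges:
        u, v = int(u), int(v)
        if u in nxt:
            raise ValueError("non-manifold hole boundary (vertex with two outgoing edges)")
        nxt[u] = v
    loops = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            if cur in seen:
                raise ValueError("boundary edges do not form simple loops")
            seen.add(cur)
            cur = nxt[cur]
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def zipper_loops(loop_a: np.ndarray, pts_a: np.ndarray, loop_b: np.ndarray, pts_b: np.ndarray) -> np.ndarray:
    """Triangulate the band between two closed loops of different sizes.

    ``loop_a``/``loop_b`` are vertex index arrays; ``pts_a``/``pts_b`` the
    corresponding 3D positions (ordered along each loop, same winding).
    Greedy shortest-diagonal advance; returns (len_a + len_b, 3) faces wound
    as (a_i, b_j, b_{j+1}) / (a_i, b_j, a_{i+1}).
    """
    m, n = len(loop_a), len(loop_b)
    # align loop_b start to the point nearest loop_a start
    j0 = int(np.argmin(np.linalg.norm(pts_b - pts_a[0], axis=1)))
    lb = np.roll(loop_b, -j0)
    pb = np.roll(pts_b, -j0, axis=0)

    faces = []
    i = j = 0
    while i < m or j < n:
        adv_a = i < m
        adv_b = j < n
        if adv_a and adv_b:
            da = np.linalg.norm(pts_a[(i + 1) % m] - pb[j % n])
            db = np.linalg.norm(pb[(j + 1) % n] - pts_a[i % m])
            adv_a = da <= db
            adv_b = not adv_a
        if adv_a:
            faces.append((loop_a[i % m], lb[j % n], loop_a[(i + 1) % m]))
            i += 1
        else:
            faces.append((loop_a[i % m], lb[j % n], lb[(j + 1) % n]))
            j += 1
    return np.array(faces, dtype=np.int64)


def orient_consistently(faces: np.ndarray, n_vertices: int, seed_face: int = 0,
                        keep_seed: bool = True) -> tuple[np.ndarray, bool]:
    """Propagate a consistent winding over a face-connected mesh.

    Returns (oriented faces, was_consistent). The seed face's winding is kept.
    """
    f = faces.copy()
    # edge -> faces map
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    face_of_edge = np.tile(np.arange(len(f)), 3)
    und = np.sort(edges, axis=1)
    key = und[:, 0].astype(np.int64) * n_vertices + und[:, 1]
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    foe_s = face_of_edge[order]
    dir_s = (edges[order, 0] < edges[order, 1])  # direction flag

    uniq, starts = np.unique(key_s, return_index=True)
    starts = np.r_[starts, len(key_s)]

    adj: list[list[tuple[int, bool]]] = [[] for _ in range(len(f))]
    consistent = True
    for s, e in zip(starts[:-1], starts[1:]):
        fs = foe_s[s:e]
        ds = dir_s[s:e]
        if len(fs) == 2:
            same = ds[0] != ds[1]  # opposite direction => consistent winding
            adj[fs[0]].append((int(fs[1]), bool(same)))
            adj[fs[1]].append((int(fs[0]), bool(same)))

    flip = np.zeros(len(f), dtype=bool)
    visited = np.zeros(len(f), dtype=bool)
    stack = [seed_face]
    visited[seed_face] = True
    while stack:
        cur = stack.pop()
        for nb, same in adj[cur]:
            want = flip[cur] if same else not flip[cur]
            if not visited[nb]:
                visited[nb] = True
                flip[nb] = want
                stack.append(nb)
            elif flip[nb] != want:
                consistent = False
    # unreached faces (disconnected) are left as-is
    if flip.any():
        f[flip] = f[flip][:, [0, 2, 1]]
    return f, (consistent and not flip.any())


def resample_closed_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed 3D polyline to n points at uniform arc length.

    Point 0 of the result coincides with point 0 of the input.
    """
    p = np.asarray(pts, dtype=float)
    closed = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, s, closed[:, k])
    return out


def polyline_area(pts2d: np.ndarray) -> float:
    """Signed shoelace area of a closed 2D polyline (first != last)."""
    x, y = pts2d[:, 0], pts2d[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
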