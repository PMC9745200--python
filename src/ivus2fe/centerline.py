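"""Centerline handling and 3D placement of 2D contours.

The angiography-derived centerline is an ordered list of XYZ points (mm).
Per-point orthonormal frames (tangent, normal, binormal) are built with the
rotation-minimizing double-reflection scheme so successive cross-section
planes differ by the smallest possible rotation — Frenet frames would twist
wildly near straight segments. Contours are placed rigidly into the
normal/binormal plane of their frame; straight mode stacks them along +z at
the same arc-length stations instead.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np

from .vh_image import ContourSet

__all__ = [
    "Centerline",
    "OrientedContours",
    "load_centerline",
    "resample_centerline",
    "compute_frames",
    "place_contours",
]


@dataclass
class Centerline:
    points: np.ndarray                    # (N, 3) mm
    tangents: np.ndarray | None = None    # (N, 3) unit
    normals: np.ndarray | None = None
    binormals: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be (N, 3)")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("centerline contains non-finite coordinates")

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.r_[0.0, np.cumsum(seg)]

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_frames(self) -> bool:
        return self.tangents is not None


@dataclass
class OrientedContours:
    """Per-frame lumen/outer rings placed in 3D (mm)."""

    lumen: np.ndarray         # (F, n, 3)
    outer: np.ndarray         # (F, n, 3)
    branch_mask: np.ndarray   # (F, n) bool
    stations: np.ndarray      # (F,) arc length mm
    centers: np.ndarray       # (F, 3) centerline points used

    @property
    def n_frames(self) -> int:
        return self.lumen.shape[0]

    @property
    def n_points(self) -> int:
        return self.lumen.shape[1]


def load_centerline(source: str) -> Centerline:
    """Parse a centerline CSV (``frame,x_mm,y_mm,z_mm`` or plain ``x,y,z``).

    ``source`` is the file content or a path. Duplicate consecutive points
    are collapsed with a warning; fewer than 2 distinct points is an error.
    """
    text = source
    if "\n" not in source and "," not in source:
        from pathlib import Path

        text = Path(source).read_text()
    rows = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            if not rows:  # header line
                continue
            raise ValueError(f"non-numeric centerline row: {line!r}") from None
        if len(vals) == 4:
            vals = vals[1:]
        if len(vals) != 3:
            raise ValueError(f"expected 3 or 4 columns, got {len(vals)}: {line!r}")
        rows.append(vals)
    pts = np.array(rows, dtype=float)
    if len(pts) < 2:
        raise ValueError("centerline needs at least 2 rows")
    dup = np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-12
    if dup.any():
        warnings.warn(f"collapsed {int(dup.sum())} duplicate consecutive centerline points",
                      stacklevel=2)
        pts = pts[np.r_[True, ~dup]]
    if len(pts) < 2:
        raise ValueError("centerline degenerate after collapsing duplicates")
    return Centerline(points=pts)


def resample_centerline(c: Centerline, n: int) -> Centerline:
    """Resample to n points at uniform arc-length spacing (piecewise linear).

    Endpoints are preserved exactly; frames, if present, are discarded and
    must be recomputed.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    s = c.arc_length
    t = np.linspace(0.0, s[-1], n)
    out = np.column_stack([np.interp(t, s, c.points[:, k]) for k in range(3)])
    out[0] = c.points[0]
    out[-1] = c.points[-1]
    return Centerline(points=out)


def smooth_centerline(c: Centerline, window: int = 3) -> Centerline:
    """Moving-average smoothing (endpoints kept); optional preprocessing."""
    if window < 2:
        return Centerline(points=c.points.copy())
    kernel = np.ones(window) / window
    pts = c.points.copy()
    inner = np.column_stack([
        np.convolve(c.points[:, k], kernel, mode="same") for k in range(3)
    ])
    pts[1:-1] = inner[1:-1]
    return Centerline(points=pts)


def compute_frames(c: Centerline) -> Centerline:
    """Attach rotation-minimizing orthonormal frames to each point.

    Tangents come from central differences (one-sided at the ends). The
    normal/binormal pair is propagated with the double-reflection method of
    Wang et al., which approximates parallel transport and never flips.
    """
    p = c.points
    n = len(p)
    t = np.empty_like(p)
    t[1:-1] = p[2:] - p[:-2]
    t[0] = p[1] - p[0]
    t[-1] = p[-1] - p[-2]
    norms = np.linalg.norm(t, axis=1)
    if np.any(norms < 1e-14):
        raise ValueError("zero-length tangent (repeated centerline points?)")
    t /= norms[:, None]

    # initial normal: least-aligned coordinate axis
    axis = np.zeros(3)
    axis[np.argmin(np.abs(t[0]))] = 1.0
    r0 = axis - t[0] * (axis @ t[0])
    r0 /= np.linalg.norm(r0)

    normals = np.empty_like(p)
    normals[0] = r0
    for i in range(n - 1):
        # double reflection: reflect across the chord bisector plane, then
        # across the bisector of the reflected and next tangent
        v1 = p[i + 1] - p[i]
        c1 = v1 @ v1
        rl = normals[i] - (2.0 / c1) * (v1 @ normals[i]) * v1
        tl = t[i] - (2.0 / c1) * (v1 @ t[i]) * v1
        v2 = t[i + 1] - tl
        c2 = v2 @ v2
        if c2 < 1e-28:
            normals[i + 1] = rl
        else:
            normals[i + 1] = rl - (2.0 / c2) * (v2 @ rl) * v2
        # re-orthonormalize against accumulated error
        normals[i + 1] -= t[i + 1] * (normals[i + 1] @ t[i + 1])
        normals[i + 1] /= np.linalg.norm(normals[i + 1])

    binormals = np.cross(t, normals)
    return Centerline(points=p.copy(), tangents=t, normals=normals, binormals=binormals)


def place_contours(contours: ContourSet, c: Centerline, px_scale: float,
                   straight: bool = False, rotation_offset_deg: float = 0.0) -> OrientedContours:
    """Map 2D contours (px) into 3D along the centerline (mm).

    Each contour point (x, y) px becomes ``P_i + s x N_i + s y B_i`` with
    s = px_scale; in straight mode the centerline is replaced by
    ``(0, 0, station_i)`` with identity frames. The centerline is resampled
    to one point per frame if counts differ. ``rotation_offset_deg`` applies
    a global in-plane rotation (the IVUS rotational orientation about the
    centerline is not observable from the inputs and defaults to zero).
    """
    n_frames = len(contours)
    if n_frames < 2:
        raise ValueError("need at least 2 contour frames")
    if len(c) != n_frames:
        c = resample_centerline(c, n_frames)
    if not c.has_frames:
        c = compute_frames(c)

    stations = c.arc_length
    if straight:
        centers = np.column_stack([np.zeros(n_frames), np.zeros(n_frames), stations])
        N = np.tile(np.array([1.0, 0.0, 0.0]), (n_frames, 1))
        B = np.tile(np.array([0.0, 1.0, 0.0]), (n_frames, 1))
    else:
        centers = c.points
        N, B = c.normals, c.binormals

    rot = np.radians(rotation_offset_deg)
    cr, sr = np.cos(rot), np.sin(rot)

    n_pts = contours.entries[0].n_points
    lum = np.empty((n_frames, n_pts, 3))
    out = np.empty((n_frames, n_pts, 3))
    mask = np.empty((n_frames, n_pts), dtype=bool)
    for i, e in enumerate(contours.entries):
        if e.n_points != n_pts:
            raise ValueError("contour point counts differ across frames")
        for ring2d, dest in ((e.lumen_ring(), lum), (e.outer_ring(), out)):
            xy = ring2d * px_scale
            x = cr * xy[:, 0] - sr * xy[:, 1]
            y = sr * xy[:, 0] + cr * xy[:, 1]
            dest[i] = centers[i] + x[:, None] * N[i] + y[:, None] * B[i]
        mask[i] = e.branch_mask
    return OrientedContours(lumen=lum, outer=out, branch_mask=mask,
                            stations=stations, centers=centers)
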