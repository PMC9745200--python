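"""VH-IVUS image processing.

Turns color-coded VH-IVUS RGB frames into cleaned integer tissue-label
grids, adds the artificial perivascular sleeve, and extracts luminal and
outer contours together with angular branch gaps.

Coordinate conventions
----------------------
Images are indexed (row, col) with origin top-left. The catheter sits at
the image center. For geometry we use centered pixel coordinates
``x = col - c_col`` (right) and ``y = c_row - row`` (up); angles are
measured counter-clockwise from +x in degrees. 1 px = ``px_scale`` mm
(0.02 mm for VH-IVUS exports).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._geometry import angle_in_interval, runs_of_true
from .labels import Tissue

__all__ = [
    "ColorMap",
    "VHFrame",
    "ContourEntry",
    "ContourSet",
    "DEFAULT_COLORMAP",
    "classify_pixels",
    "remove_islands",
    "add_sleeve",
    "extract_contours",
    "detect_branch_gaps",
    "build_contour_set",
]


@dataclass(frozen=True)
class ColorMap:
    """Mapping from reference display RGB values to tissue labels.

    ``entries`` maps label -> (name, (r, g, b)). A pixel is assigned the
    label of the nearest reference color in Euclidean RGB distance if that
    distance is at most ``tolerance``, otherwise background.
    """

    entries: dict[int, tuple[str, tuple[int, int, int]]]
    tolerance: float = 60.0

    def __post_init__(self):
        rgbs = [e[1] for e in self.entries.values()]
        if len({tuple(c) for c in rgbs}) != len(rgbs):
            raise ValueError("reference RGB values must be pairwise distinct")
        if Tissue.BACKGROUND in self.entries:
            raise ValueError("background label is reserved and carries no color")

    @property
    def labels(self) -> np.ndarray:
        return np.array(sorted(self.entries), dtype=np.int64)

    def rgb(self, label: int) -> tuple[int, int, int]:
        return self.entries[label][1]


#: VH display colors. The VH export names the colors (grey, dark green,
#: light green, red, white); the concrete RGB values are configurable and
#: these are the package defaults. Sleeve display color is user-defined;
#: blue by default.
DEFAULT_COLORMAP = ColorMap(
    entries={
        int(Tissue.WALL): ("arterial_wall", (128, 128, 128)),
        int(Tissue.FIBROUS): ("fibrotic", (0, 128, 0)),
        int(Tissue.FIBROFATTY): ("fibrofatty", (144, 238, 144)),
        int(Tissue.NECROTIC): ("necrotic_core", (255, 0, 0)),
        int(Tissue.CALCIUM): ("calcium", (255, 255, 255)),
        int(Tissue.SLEEVE): ("sleeve", (0, 0, 255)),
    }
)


@dataclass
class VHFrame:
    """A classified VH-IVUS frame: integer label grid plus pixel scale."""

    labels: np.ndarray          # (rows, cols) int16
    px_scale: float             # mm per pixel
    frame_index: int = 0
    center: tuple[float, float] | None = None  # (row, col); None = image center

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.px_scale <= 0:
            raise ValueError("px_scale must be positive")
        if self.center is None:
            self.center = ((self.labels.shape[0] - 1) / 2.0,
                           (self.labels.shape[1] - 1) / 2.0)

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0

    def centered_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel centered coordinates (x right, y up) in px."""
        rows, cols = np.indices(self.labels.shape)
        cr, cc = self.center
        return cols - cc, cr - rows


@dataclass
class ContourEntry:
    """Lumen/outer contour of one frame, sampled at uniform angles.

    Polylines are closed (``points[0] == points[-1]``), counter-clockwise,
    in centered pixel coordinates; ``branch_mask[k]`` flags the k-th angular
    station as lying inside a branch gap.
    """

    lumen: np.ndarray        # (n+1, 2) px, closed
    outer: np.ndarray        # (n+1, 2) px, closed
    branch_mask: np.ndarray  # (n,) bool
    angles_deg: np.ndarray   # (n,)
    frame_index: int = 0

    @property
    def n_points(self) -> int:
        return len(self.angles_deg)

    def lumen_ring(self) -> np.ndarray:
        return self.lumen[:-1]

    def outer_ring(self) -> np.ndarray:
        return self.outer[:-1]


@dataclass
class ContourSet:
    entries: list[ContourEntry] = field(default_factory=list)
    branch_intervals: list[list[tuple[float, float]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------


def classify_pixels(rgb: np.ndarray, colormap: ColorMap = DEFAULT_COLORMAP,
                    px_scale: float = 0.02, frame_index: int = 0) -> VHFrame:
    """Assign each pixel the label of the nearest reference RGB.

    Pixels farther than ``colormap.tolerance`` from every reference color
    become background. Input must be an 8-bit RGB image (rows, cols, 3).
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an RGB image of shape (r, c, 3), got {rgb.shape}")
    img = rgb.astype(np.int32)
    labels = sorted(colormap.entries)
    refs = np.array([colormap.rgb(l) for l in labels], dtype=np.int32)
    d2 = np.zeros((len(labels),) + rgb.shape[:2], dtype=np.int32)
    for i, ref in enumerate(refs):
        diff = img - ref[None, None, :]
        d2[i] = np.einsum("rck,rck->rc", diff, diff)
    best = np.argmin(d2, axis=0)
    best_d2 = np.take_along_axis(d2, best[None], axis=0)[0]
    out = np.array(labels, dtype=np.int16)[best]
    out[best_d2 > colormap.tolerance**2] = Tissue.BACKGROUND
    return VHFrame(out, px_scale=px_scale, frame_index=frame_index)


_CONN8 = np.ones((3, 3), dtype=bool)


def remove_islands(frame: VHFrame, min_area: int = 20) -> VHFrame:
    """Area-opening style cleanup of the label grid.

    Every 8-connected same-label component smaller than ``min_area`` pixels
    is relabeled to the dominant label of its bordering pixels (background
    if it borders nothing else). Components of size >= min_area and the
    background are untouched.
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    src = frame.labels
    out = src.copy()
    if min_area == 0:
        return replace(frame, labels=out)
    for label in np.unique(src):
        if label == Tissue.BACKGROUND:
            continue
        comp, n = ndimage.label(src == label, structure=_CONN8)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes[1:] < min_area) + 1
        if len(small) == 0:
            continue
        slices = ndimage.find_objects(comp)
        for cid in small:
            sl = slices[cid - 1]
            sl = (slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, src.shape[0])),
                  slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, src.shape[1])))
            mask = comp[sl] == cid
            ring = ndimage.binary_dilation(mask, structure=_CONN8) & ~mask
            neighbors = src[sl][ring]
            if len(neighbors) == 0:
                out[sl][mask] = Tissue.BACKGROUND
                continue
            vals, counts = np.unique(neighbors, return_counts=True)
            out[sl][mask] = vals[np.argmax(counts)]
    return replace(frame, labels=out)


def add_sleeve(frame: VHFrame, thickness_mm: float = 0.2) -> VHFrame:
    """Add the perivascular sleeve layer around the tissue region.

    The tissue union is dilated isotropically by ``round(thickness /
    px_scale)`` pixels (Euclidean distance transform); new pixels become
    sleeve. Pixels that would fall radially inside the luminal boundary
    (i.e. inside the blood channel) are not sleeved, so the lumen stays
    open; at angles with no tissue (branch gaps) the sleeve is allowed to
    wrap around the cut edges. Existing tissue labels are never overwritten.
    """
    if thickness_mm < 0:
        raise ValueError("sleeve thickness must be non-negative")
    tissue = frame.tissue_mask
    if not tissue.any():
        raise ValueError("frame has no tissue to sleeve")
    radius_px = int(round(thickness_mm / frame.px_scale))
    if radius_px == 0:
        return replace(frame, labels=frame.labels.copy())
    dist = ndimage.distance_transform_edt(~tissue)
    candidates = (dist <= radius_px) & ~tissue

    x, y = frame.centered_xy()
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    bins = np.minimum((theta).astype(np.int64), 359)

    # per-degree innermost tissue radius
    r_in = np.full(360, np.inf)
    tb = bins[tissue]
    np.minimum.at(r_in, tb, r[tissue])

    inner_limit = r_in[bins]
    keep = candidates & ~(np.isfinite(inner_limit) & (r < inner_limit))

    out = frame.labels.copy()
    out[keep] = Tissue.SLEEVE
    return replace(frame, labels=out)


def _ray_occupancy(frame: VHFrame, n_angles: int, step_px: float = 0.25,
                   mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample tissue occupancy along rays from the catheter center.

    Returns (occupancy (n_angles, n_steps) bool, radii (n_steps,) px).
    """
    labels = frame.labels
    cr, cc = frame.center
    r_max = float(min(cr, cc, labels.shape[0] - 1 - cr, labels.shape[1] - 1 - cc))
    radii = np.arange(step_px, r_max, step_px)
    ang = np.radians(np.arange(n_angles) * (360.0 / n_angles))
    cos, sin = np.cos(ang), np.sin(ang)
    rows = np.rint(cr - np.outer(sin, radii)).astype(np.int64)
    cols = np.rint(cc + np.outer(cos, radii)).astype(np.int64)
    np.clip(rows, 0, labels.shape[0] - 1, out=rows)
    np.clip(cols, 0, labels.shape[1] - 1, out=cols)
    m = frame.tissue_mask if mask is None else mask
    return m[rows, cols], radii


def detect_branch_gaps(frame: VHFrame, min_span_deg: float = 10.0) -> list[tuple[float, float]]:
    """Find angular intervals where no tissue lies along the radial ray.

    Rays are cast at 1-degree increments from the catheter center; maximal
    circular runs of empty rays spanning at least ``min_span_deg`` are
    returned as (start_deg, end_deg) intervals.
    """
    occ, _ = _ray_occupancy(frame, 360)
    empty = ~occ.any(axis=1)
    intervals = []
    for start, length in runs_of_true(empty, circular=True):
        if length >= min_span_deg:
            intervals.append((float(start), float((start + length) % 360.0)))
    return intervals


def extract_contours(frame: VHFrame, n_points: int = 72,
                     branch_intervals: list[tuple[float, float]] | None = None) -> ContourEntry:
    """Extract luminal and outer contours at uniform angular spacing.

    Radial rays are cast from the catheter center at ``n_points`` angles;
    the first and last tissue crossing give the lumen and outer radius at
    each angle. Angles inside branch gaps (no tissue) get radii filled by
    periodic linear interpolation and are flagged in ``branch_mask``.
    """
    if not frame.tissue_mask.any():
        raise ValueError("cannot extract contours from an empty frame")
    occ, radii = _ray_occupancy(frame, n_points)
    any_hit = occ.any(axis=1)
    first = np.argmax(occ, axis=1)
    last = occ.shape[1] - 1 - np.argmax(occ[:, ::-1], axis=1)
    r_in = np.where(any_hit, radii[first], np.nan)
    r_out = np.where(any_hit, radii[last], np.nan)

    angles = np.arange(n_points) * (360.0 / n_points)
    branch = ~any_hit
    if branch_intervals:
        for a0, a1 in branch_intervals:
            branch |= angle_in_interval(angles, a0, a1)
    if branch.all():
        raise ValueError("no intact angular station found in frame")

    if branch.any() or np.isnan(r_in).any():
        bad = branch | np.isnan(r_in) | np.isnan(r_out)
        good = ~bad
        # periodic interpolation over angles
        xg = angles[good]
        for arr in (r_in, r_out):
            arr[bad] = np.interp(angles[bad], np.r_[xg, xg[0] + 360.0],
                                 np.r_[arr[good], arr[good][0]], period=360.0)

    if np.any(r_in > r_out):
        raise ValueError("lumen contour not enclosed by outer contour")

    ang = np.radians(angles)
    lum = np.column_stack([r_in * np.cos(ang), r_in * np.sin(ang)])
    out = np.column_stack([r_out * np.cos(ang), r_out * np.sin(ang)])
    return ContourEntry(
        lumen=np.vstack([lum, lum[:1]]),
        outer=np.vstack([out, out[:1]]),
        branch_mask=branch,
        angles_deg=angles,
        frame_index=frame.frame_index,
    )


def build_contour_set(frames: list[VHFrame], n_points: int = 72,
                      min_branch_span_deg: float = 10.0,
                      min_branch_frames: int = 2) -> ContourSet:
    """Contours plus branch-gap flags for a whole classified stack.

    Branch gaps shorter than ``min_branch_frames`` consecutive frames are
    treated as imaging dropouts rather than branches and unflagged.
    """
    intervals = [detect_branch_gaps(f, min_branch_span_deg) for f in frames]
    has_gap = np.array([len(iv) > 0 for iv in intervals])
    # suppress isolated gap frames
    for start, length in runs_of_true(has_gap, circular=False):
        if length < min_branch_frames:
            for i in range(start, start + length):
                intervals[i] = []
    entries = [
        extract_contours(f, n_points=n_points, branch_intervals=iv)
        for f, iv in zip(frames, intervals)
    ]
    return ContourSet(entries=entries, branch_intervals=intervals)
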