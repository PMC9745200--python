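"""Synthetic VH-IVUS phantoms and analytic validation geometries.

The phantom generator emits color-coded image stacks of an annular vessel
wall with embedded tissue inclusions, an optional angular branch gap, and
a matching 3D centerline (straight or helical), together with exact ground
truth (per-frame pixel counts and idealized constituent volumes). It is the
test bed for every downstream stage: the images round-trip through pixel
classification exactly because they are drawn with the default VH colors.

Also provided: a structured tetrahedral mesh of a thick-walled cylinder
and the Lame closed-form stress solution, the analytic oracle used to
validate the finite element solver.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import angle_in_interval, intervals_overlap
from .labels import TISSUE_NAMES, Tissue
from .vh_image import DEFAULT_COLORMAP, ColorMap

__all__ = [
    "Inclusion",
    "Branch",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomStack",
    "generate_vh_stack",
    "default_phantom",
    "generate_lame_cylinder",
    "lame_reference",
]


@dataclass(frozen=True)
class Inclusion:
    """A plaque inclusion in frame-local polar coordinates.

    The inclusion occupies frames ``frames[0]..frames[1]`` (inclusive),
    angles ``angles[0]..angles[1]`` deg (counter-clockwise, wrap-aware) and
    radial fractions ``radial[0]..radial[1]`` of the local wall thickness,
    so it stays inside the wall as the radii vary along the pullback.
    """

    label: int
    frames: tuple[int, int]
    angles: tuple[float, float]
    radial: tuple[float, float]

    def __post_init__(self):
        if not (0.0 <= self.radial[0] < self.radial[1] <= 1.0):
            raise ValueError("inclusion radial range must satisfy 0 <= r0 < r1 <= 1 "
                             "(inclusions must lie inside the wall annulus)")
        if self.frames[0] > self.frames[1]:
            raise ValueError("inclusion frame range reversed")
        if self.label not in (Tissue.FIBROUS, Tissue.FIBROFATTY, Tissue.NECROTIC,
                              Tissue.CALCIUM):
            raise ValueError(f"inclusion label {self.label} is not a plaque tissue")

    def angular_span(self) -> float:
        return (self.angles[1] - self.angles[0]) % 360.0 or 360.0


@dataclass(frozen=True)
class Branch:
    """An angular gap in the wall over a contiguous frame range."""

    frames: tuple[int, int]
    center_deg: float = 0.0
    span_deg: float = 40.0

    def __post_init__(self):
        if self.frames[1] - self.frames[0] + 1 < 2:
            raise ValueError("branch gap must span at least 2 consecutive frames")
        if not (0.0 < self.span_deg < 360.0):
            raise ValueError("branch span must be in (0, 360) degrees")

    @property
    def interval(self) -> tuple[float, float]:
        a0 = (self.center_deg - self.span_deg / 2.0) % 360.0
        return (a0, (a0 + self.span_deg) % 360.0)


@dataclass
class PhantomSpec:
    """Full description of a synthetic VH-IVUS acquisition.

    ``lumen_radius`` and ``wall_thickness`` may be scalars or per-frame
    arrays (mm). Frame spacing defaults to 0.5 mm, emulating a gated
    0.5 mm/s motorized pullback at ~1 frame/s.
    """

    n_frames: int = 20
    image_size: int = 400
    lumen_radius: float | np.ndarray = 1.4
    wall_thickness: float | np.ndarray = 1.0
    inclusions: list[Inclusion] = field(default_factory=list)
    branch: Branch | None = None
    centerline_mode: str = "curved"  # "straight" | "curved"
    frame_spacing: float = 0.5
    px_scale: float = 0.02
    helix_radius: float = 15.0
    helix_pitch: float = 40.0
    seed: int = 0

    def __post_init__(self):
        self.lumen_radius = np.broadcast_to(
            np.asarray(self.lumen_radius, dtype=float), (self.n_frames,)).copy()
        self.wall_thickness = np.broadcast_to(
            np.asarray(self.wall_thickness, dtype=float), (self.n_frames,)).copy()
        if np.any(self.lumen_radius <= 0):
            raise ValueError("lumen radius must be positive")
        if np.any(self.wall_thickness <= 0):
            raise ValueError("wall thickness must be positive")
        if self.centerline_mode not in ("straight", "curved"):
            raise ValueError("centerline_mode must be 'straight' or 'curved'")
        max_r = (self.lumen_radius + self.wall_thickness).max() / self.px_scale
        if max_r >= self.image_size / 2 - 2:
            raise ValueError("vessel does not fit inside the image")
        for inc in self.inclusions:
            if inc.frames[1] >= self.n_frames:
                raise ValueError("inclusion frame range outside the stack")
        for i, a in enumerate(self.inclusions):
            for b in self.inclusions[i + 1:]:
                if a.label == b.label:
                    continue
                frames_overlap = not (a.frames[1] < b.frames[0] or b.frames[1] < a.frames[0])
                radial_overlap = not (a.radial[1] <= b.radial[0] or b.radial[1] <= a.radial[0])
                if frames_overlap and radial_overlap and intervals_overlap(a.angles, b.angles):
                    raise ValueError(
                        f"inclusions of different materials overlap: {a} vs {b}")
        if self.branch is not None and self.branch.frames[1] >= self.n_frames:
            raise ValueError("branch frame range outside the stack")

    @property
    def outer_radius(self) -> np.ndarray:
        return self.lumen_radius + self.wall_thickness


@dataclass
class PhantomTruth:
    """Exact ground truth for a generated phantom stack."""

    spec: PhantomSpec
    pixel_counts: np.ndarray       # (n_frames, n_labels) label-indexed counts
    centerline: np.ndarray         # (n_frames, 3) mm

    @property
    def branch_frames(self) -> list[int]:
        if self.spec.branch is None:
            return []
        return list(range(self.spec.branch.frames[0], self.spec.branch.frames[1] + 1))

    def _frame_areas(self, sleeve_thickness: float = 0.0) -> np.ndarray:
        """Idealized per-frame cross-sectional area (mm^2) per label."""
        s = self.spec
        areas = np.zeros((s.n_frames, len(Tissue)))
        gap = s.branch.interval if s.branch else None
        for i in range(s.n_frames):
            rl = s.lumen_radius[i]
            ro = s.outer_radius[i]
            t = s.wall_thickness[i]
            in_branch = s.branch is not None and s.branch.frames[0] <= i <= s.branch.frames[1]
            gap_frac = (s.branch.span_deg / 360.0) if in_branch else 0.0
            wall = np.pi * (ro**2 - rl**2) * (1.0 - gap_frac)
            for inc in s.inclusions:
                if not (inc.frames[0] <= i <= inc.frames[1]):
                    continue
                span = inc.angular_span()
                if in_branch and intervals_overlap(inc.angles, gap):
                    span -= _interval_intersection_span(inc.angles, gap)
                r0 = rl + inc.radial[0] * t
                r1 = rl + inc.radial[1] * t
                a = (span / 360.0) * np.pi * (r1**2 - r0**2)
                areas[i, inc.label] += a
                wall -= a
            areas[i, Tissue.WALL] = wall
            if sleeve_thickness > 0:
                areas[i, Tissue.SLEEVE] = (np.pi * ((ro + sleeve_thickness)**2 - ro**2)
                                           * (1.0 - gap_frac))
        return areas

    def volumes(self, sleeve_thickness: float = 0.0) -> dict[str, float]:
        """Idealized constituent volumes (mm^3), lofting frames trapezoidally."""
        areas = self._frame_areas(sleeve_thickness)
        slab = self.spec.frame_spacing
        vols = ((areas[:-1] + areas[1:]) / 2.0).sum(axis=0) * slab
        return {TISSUE_NAMES[Tissue(l)]: float(vols[l])
                for l in range(len(Tissue)) if vols[l] > 0}

    def fractions(self, sleeve_thickness: float = 0.0) -> dict[str, float]:
        v = self.volumes(sleeve_thickness)
        total = sum(v.values())
        return {k: 100.0 * x / total for k, x in v.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "pixel_counts": self.pixel_counts.tolist(),
                "centerline": self.centerline.tolist(),
                "branch_frames": self.branch_frames,
                "volumes": self.volumes(),
            },
            indent=2,
        )


def _interval_intersection_span(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Span (deg) of the intersection of two wrap-aware angular intervals."""
    grid = np.arange(0.0, 360.0, 0.05)
    both = angle_in_interval(grid, *a) & angle_in_interval(grid, *b)
    return float(both.sum() * 0.05)


@dataclass
class PhantomStack:
    """Generated phantom: RGB frames, centerline CSV content and truth."""

    images: list[np.ndarray]       # each (N, N, 3) uint8
    label_frames: list[np.ndarray]  # each (N, N) int16, pre-classification truth
    centerline_csv: str
    truth: PhantomTruth

    def write(self, out_dir: str | Path) -> dict[str, object]:
        """Write PNG frames, centerline CSV and truth JSON to a directory."""
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, img in enumerate(self.images):
            p = out / f"frame_{i:04d}.png"
            Image.fromarray(img, mode="RGB").save(p)
            paths.append(p)
        cl = out / "centerline.csv"
        cl.write_text(self.centerline_csv)
        tr = out / "truth.json"
        tr.write_text(self.truth.to_json())
        return {"frames": paths, "centerline": cl, "truth": tr}


def _centerline_points(spec: PhantomSpec) -> np.ndarray:
    s = np.arange(spec.n_frames) * spec.frame_spacing
    if spec.centerline_mode == "straight":
        return np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
    R = spec.helix_radius
    b = spec.helix_pitch / (2.0 * np.pi)
    c = np.hypot(R, b)
    t = s / c
    pts = np.column_stack([R * (np.cos(t) - 1.0), R * np.sin(t), b * t])
    return pts


def generate_vh_stack(spec: PhantomSpec, colormap: ColorMap = DEFAULT_COLORMAP) -> PhantomStack:
    """Render the phantom image stack and its exact ground truth.

    Each frame is an annulus of wall-class pixels around a black lumen;
    inclusion pixels are colored per the VH color map; branch frames have
    all tissue erased over the angular gap. Identical specs (including
    seed) produce byte-identical stacks.
    """
    n = spec.image_size
    c = (n - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    x = (cols - c) * spec.px_scale
    y = (c - rows) * spec.px_scale
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0

    images, label_frames = [], []
    counts = np.zeros((spec.n_frames, len(Tissue)), dtype=np.int64)
    palette = np.zeros((len(Tissue), 3), dtype=np.uint8)
    for lbl in colormap.entries:
        palette[lbl] = colormap.rgb(lbl)

    for i in range(spec.n_frames):
        rl = spec.lumen_radius[i]
        ro = spec.outer_radius[i]
        t = spec.wall_thickness[i]
        labels = np.zeros((n, n), dtype=np.int16)
        wall = (r >= rl) & (r < ro)
        labels[wall] = Tissue.WALL
        for inc in spec.inclusions:
            if not (inc.frames[0] <= i <= inc.frames[1]):
                continue
            frac = (r - rl) / t
            sel = (wall & angle_in_interval(theta, *inc.angles)
                   & (frac >= inc.radial[0]) & (frac < inc.radial[1]))
            labels[sel] = inc.label
        if spec.branch is not None and spec.branch.frames[0] <= i <= spec.branch.frames[1]:
            labels[angle_in_interval(theta, *spec.branch.interval)] = Tissue.BACKGROUND
        counts[i] = np.bincount(labels.ravel(), minlength=len(Tissue))
        images.append(palette[labels])
        label_frames.append(labels)

    cl = _centerline_points(spec)
    buf = io.StringIO()
    buf.write("frame,x_mm,y_mm,z_mm\n")
    for i, p in enumerate(cl):
        buf.write(f"{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")

    truth = PhantomTruth(spec=spec, pixel_counts=counts, centerline=cl)
    return PhantomStack(images=images, label_frames=label_frames,
                        centerline_csv=buf.getvalue(), truth=truth)


def default_phantom(n_frames: int = 20, image_size: int = 400, seed: int = 0,
                    branch: bool = False, centerline_mode: str = "curved") -> PhantomSpec:
    """The package's reference phantom: a mildly tapering, undulating
    vessel with one inclusion of each plaque class.

    The calcium inclusion is deliberately small (a ~60 deg patch over a few
    frames, mid-wall), like spotty calcification; the necrotic core and
    fibrous/fibrofatty regions are larger. Radii follow gentle sinusoids
    plus small seeded perturbations so no two frames are identical.
    """
    rng = np.random.default_rng(seed)
    i = np.arange(n_frames)
    lumen = 1.4 + 0.25 * np.sin(2 * np.pi * i / n_frames) \
        + 0.04 * rng.standard_normal(n_frames).cumsum() / max(np.sqrt(n_frames), 1)
    lumen = np.clip(lumen, 1.0, 1.8)
    wall = 1.0 + 0.2 * np.sin(4 * np.pi * i / n_frames + 1.0)

    def fr(a: float, b: float) -> tuple[int, int]:
        start = int(np.ceil(a * n_frames))
        return (start, min(max(start, int(b * n_frames)), n_frames - 1))

    inclusions = [
        Inclusion(Tissue.CALCIUM, fr(0.40, 0.55), (20.0, 80.0), (0.35, 0.75)),
        Inclusion(Tissue.NECROTIC, fr(0.25, 0.50), (120.0, 210.0), (0.15, 0.60)),
        Inclusion(Tissue.FIBROUS, fr(0.50, 0.85), (230.0, 330.0), (0.10, 0.90)),
        Inclusion(Tissue.FIBROFATTY, fr(0.10, 0.35), (240.0, 320.0), (0.20, 0.70)),
    ]
    br = Branch(frames=fr(0.45, 0.65), center_deg=0.0, span_deg=40.0) if branch else None
    return PhantomSpec(
        n_frames=n_frames,
        image_size=image_size,
        lumen_radius=lumen,
        wall_thickness=wall,
        inclusions=inclusions,
        branch=br,
        centerline_mode=centerline_mode,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# analytic validation geometry
# ---------------------------------------------------------------------------


def generate_lame_cylinder(inner_radius: float, outer_radius: float, length: float,
                           edge_length: float, material: int = int(Tissue.WALL),
                           span_deg: float = 360.0):
    """Structured tet4 mesh of a thick-walled cylinder with face tags.

    Nodes sit on a regular (r, theta, z) grid sized so edges are close to
    ``edge_length``; each hexahedral cell is split into six tetrahedra along
    a consistent main diagonal, which keeps the mesh conforming. Boundary
    faces are tagged lumen / outer / cap_proximal / cap_distal.

    ``span_deg`` < 360 meshes an angular wedge (e.g. a 90-degree quarter
    for symmetry-reduced validation runs; the wedge faces then lie in the
    y=0 and, for 90 degrees, x=0 planes).
    """
    from .surface_mesh import FaceTag
    from .volume_mesh import TetMesh

    a, b, L, h = float(inner_radius), float(outer_radius), float(length), float(edge_length)
    if not 0 < a < b:
        raise ValueError("need 0 < inner_radius < outer_radius")
    if h >= b - a:
        raise ValueError("edge_length larger than wall thickness: wall unresolvable")
    if L < 4.0 * (b - a):
        raise ValueError("length must be at least 4x the wall thickness")
    if not 0.0 < span_deg <= 360.0:
        raise ValueError("span_deg must be in (0, 360]")
    full = span_deg == 360.0
    span = np.radians(span_deg)

    nr = max(2, int(round((b - a) / h)))
    ntheta = max(8, int(round(span * (a + b) / 2.0 / h)))
    nz = max(2, int(round(L / h)))

    rr = np.linspace(a, b, nr + 1)
    n_thnodes = ntheta if full else ntheta + 1
    th = np.arange(n_thnodes) * (span / ntheta)
    zz = np.linspace(0.0, L, nz + 1)

    R, T, Z = np.meshgrid(rr, th, zz, indexing="ij")
    nodes = np.column_stack([(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), Z.ravel()])

    def nid(ir, it, iz):
        return (ir * n_thnodes + (it % n_thnodes if full else it)) * (nz + 1) + iz

    ir, it, iz = np.meshgrid(np.arange(nr), np.arange(ntheta), np.arange(nz), indexing="ij")
    ir, it, iz = ir.ravel(), it.ravel(), iz.ravel()
    v = [
        nid(ir, it, iz), nid(ir + 1, it, iz), nid(ir + 1, it + 1, iz), nid(ir, it + 1, iz),
        nid(ir, it, iz + 1), nid(ir + 1, it, iz + 1), nid(ir + 1, it + 1, iz + 1), nid(ir, it + 1, iz + 1),
    ]
    hex_tets = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6), (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]
    elements = np.concatenate([
        np.column_stack([v[i0], v[i1], v[i2], v[i3]]) for i0, i1, i2, i3 in hex_tets
    ])

    mesh = TetMesh(nodes=nodes, elements=elements)
    mesh.orient_positive()
    mesh.material = np.full(len(mesh.elements), material, dtype=np.int16)

    faces, owner = mesh.boundary_face_list()
    fc = nodes[faces].mean(axis=1)
    rad = np.hypot(fc[:, 0], fc[:, 1])
    tol = 0.25 * (rr[1] - rr[0])
    ztol = 0.25 * (zz[1] - zz[0])
    tags = np.full(len(faces), FaceTag.OUTER, dtype=np.int8)
    tags[rad < a + tol] = FaceTag.LUMEN
    tags[fc[:, 2] < ztol] = FaceTag.CAP_PROXIMAL
    tags[fc[:, 2] > L - ztol] = FaceTag.CAP_DISTAL
    mesh.boundary_faces = faces
    mesh.boundary_tags = tags
    mesh.boundary_owner = owner
    return mesh


def lame_reference(a: float, b: float, p: float, r: float | np.ndarray):
    """Thick-walled-cylinder (Lame) plane-strain stresses at radius r.

    sigma_r = p a^2/(b^2-a^2) (1 - b^2/r^2),
    sigma_theta = p a^2/(b^2-a^2) (1 + b^2/r^2), for internal pressure p
    (same units as the returned stresses).
    """
    r = np.asarray(r, dtype=float)
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    if p < 0:
        raise ValueError("pressure must be non-negative")
    if np.any(r < a - 1e-12) or np.any(r > b + 1e-12):
        raise ValueError("radius outside the wall [a, b]")
    k = p * a**2 / (b**2 - a**2)
    sig_r = k * (1.0 - b**2 / r**2)
    sig_t = k * (1.0 + b**2 / r**2)
    if np.ndim(sig_r) == 0:
        return float(sig_r), float(sig_t)
    return sig_r, sig_t
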