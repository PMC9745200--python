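"""End-to-end reconstruction pipeline and study drivers.

``run_pipeline`` executes classify -> clean -> sleeve -> contours ->
branch detect -> place -> loft -> cap -> branch -> smooth -> remesh ->
tetrahedralize -> assign -> (solve) -> report, writing every intermediate
artifact plus a provenance manifest. ``convergence_sweep`` repeats the
reconstruction over a list of mesh resolutions and tabulates constituent
volumes; ``straight_vs_curved`` compares constituent volumes between the
curved-centerline and straightened reconstructions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .centerline import Centerline, compute_frames, load_centerline, place_contours
from .fea import build_fe_model, solve_static, stress_report
from .materials import (MaterialTable, assign_materials, build_pixel_cloud,
                        build_sections, material_table)
from .surface_mesh import (SurfaceMesh, build_branch, cap_ends, hc_smooth,
                           loft_tube, remesh_isotropic, validate_surface)
from .vh_image import (DEFAULT_COLORMAP, ColorMap, VHFrame, add_sleeve,
                       build_contour_set, classify_pixels, remove_islands)
from .volume_mesh import TetMesh, constituent_volumes, tet4_to_tet10, tetrahedralize

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "convergence_sweep", "straight_vs_curved", "load_frames"]

log = logging.getLogger("ivus2fe")

#: the mesh-resolution range studied for convergence; values outside it
#: are accepted with a warning
RESOLUTION_RANGE = (0.04, 0.4)


@dataclass
class PipelineConfig:
    image_dir: str | Path | None = None
    centerline_path: str | Path | None = None
    output_dir: str | Path = "ivus2fe_out"
    resolution: float = 0.2            # mm, surface/volume edge length
    sleeve_thickness: float = 0.2      # mm
    pressure_kpa: float = 17.0
    straight: bool = False
    element_type: str = "tet4"         # tet4 | tet10
    material_overrides: dict = field(default_factory=dict)
    min_island_area: int = 20          # px^2
    contour_points: int = 72
    px_scale: float = 0.02             # mm / px
    section_length: float = 5.0        # mm, material pre-indexing
    section_overlap: float = 1.0
    branch_offset: float = 1.0         # mm beyond the outer surface
    branch_dilation: float = 1.3
    rotation_offset_deg: float = 0.0
    load_steps: int = 10
    law: str = "linear"
    solve: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (RESOLUTION_RANGE[0] <= self.resolution <= RESOLUTION_RANGE[1]):
            import warnings

            warnings.warn(
                f"resolution {self.resolution} mm is outside the studied "
                f"range {RESOLUTION_RANGE}", stacklevel=2)
        if self.element_type not in ("tet4", "tet10"):
            raise ValueError("element_type must be tet4 or tet10")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    surface: SurfaceMesh
    mesh: TetMesh
    table: MaterialTable
    volumes: dict
    fractions: dict
    fe_result: object | None = None
    report: dict | None = None
    manifest: dict | None = None
    output_dir: Path | None = None


def load_frames(image_dir: str | Path, colormap: ColorMap = DEFAULT_COLORMAP,
                px_scale: float = 0.02, min_island_area: int = 20) -> list[VHFrame]:
    """Read a PNG stack (sorted by name) and classify it."""
    from PIL import Image

    paths = sorted(Path(image_dir).glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG frames found in {image_dir}")
    frames = []
    for i, p in enumerate(paths):
        rgb = np.asarray(Image.open(p).convert("RGB"))
        f = classify_pixels(rgb, colormap, px_scale=px_scale, frame_index=i)
        frames.append(remove_islands(f, min_island_area))
    return frames


def reconstruct(frames: list[VHFrame], c: Centerline, cfg: PipelineConfig,
                timings: dict | None = None) -> tuple[SurfaceMesh, TetMesh, list[VHFrame]]:
    """Image stack + centerline -> labeled tetrahedral mesh (no solve)."""
    timings = timings if timings is not None else {}

    def stage(name):
        timings[name] = time.perf_counter()
        log.info("stage: %s", name)

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    stage("sleeve")
    sleeved = [add_sleeve(f, cfg.sleeve_thickness) for f in frames]
    done("sleeve")

    stage("contours")
    cs = build_contour_set(sleeved, n_points=cfg.contour_points)
    n_branch_frames = sum(1 for iv in cs.branch_intervals if iv)
    log.info("branch frames: %d", n_branch_frames)
    done("contours")

    stage("place")
    oc = place_contours(cs, c, px_scale=cfg.px_scale, straight=cfg.straight,
                        rotation_offset_deg=cfg.rotation_offset_deg)
    done("place")

    stage("loft")
    surf = cap_ends(loft_tube(oc))
    done("loft")

    stage("branch")
    surf = build_branch(surf, offset=cfg.branch_offset, dilation=cfg.branch_dilation)
    done("branch")

    stage("smooth")
    surf = hc_smooth(surf)
    done("smooth")

    stage("remesh")
    surf = remesh_isotropic(surf, cfg.resolution)
    rep = validate_surface(surf)
    if not rep.watertight or not rep.oriented:
        raise RuntimeError(f"remeshed surface failed validation: {rep}")
    done("remesh")

    stage("tetrahedralize")
    mesh = tetrahedralize(surf, cfg.resolution)
    if cfg.element_type == "tet10":
        mesh = tet4_to_tet10(mesh)
    log.info("elements: %d", mesh.n_elements)
    done("tetrahedralize")

    stage("assign")
    cloud = build_pixel_cloud(sleeved, c, straight=cfg.straight,
                              rotation_offset_deg=cfg.rotation_offset_deg)
    index = build_sections(cloud, cfg.section_length, cfg.section_overlap)
    summary = assign_materials(mesh, cloud, index)
    log.info("assignment: %s (escalated %d, far %d)",
             summary.counts, summary.n_escalated, summary.n_far)
    done("assign")

    return surf, mesh, sleeved


def run_pipeline(cfg: PipelineConfig, frames: list[VHFrame] | None = None,
                 c: Centerline | None = None) -> PipelineResult:
    """Execute the full pipeline; inputs may be preloaded or read from disk."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict = {}

    if frames is None:
        if cfg.image_dir is None:
            raise ValueError("no frames given and no image_dir configured")
        if cfg.centerline_path is not None and not Path(cfg.centerline_path).exists():
            raise FileNotFoundError(f"centerline file not found: {cfg.centerline_path}")
        frames = load_frames(cfg.image_dir, px_scale=cfg.px_scale,
                             min_island_area=cfg.min_island_area)
    if c is None:
        if cfg.centerline_path is None:
            raise ValueError("no centerline given and no centerline_path configured")
        c = load_centerline(str(cfg.centerline_path))
    c = compute_frames(c) if not c.has_frames else c

    surf, mesh, sleeved = reconstruct(frames, c, cfg, timings)
    table = material_table(cfg.material_overrides)
    volumes, fractions = constituent_volumes(mesh)

    surf.export_stl(out / "surface.stl")
    mesh.export_vtk(out / "volume_mesh.vtk")

    fe_result = None
    report = None
    if cfg.solve:
        t0 = time.perf_counter()
        fe4 = mesh  # tet10 solve uses the converted mesh directly
        model = build_fe_model(fe4, table, pressure_kpa=cfg.pressure_kpa,
                               steps=cfg.load_steps, law=cfg.law)
        fe_result = solve_static(model)
        report = stress_report(fe_result, mesh, table)
        timings["solve"] = round(time.perf_counter() - t0, 3)
        if not mesh.is_tet10:
            from .febio import export_feb

            export_feb(model, out / "model.feb")
        mesh.export_vtk(out / "result.vtk",
                        point_data={"displacement": fe_result.displacement,
                                    "von_mises_nodal": fe_result.von_mises_nodal},
                        cell_data={"von_mises": fe_result.von_mises_element})
        (out / "stress_report.json").write_text(json.dumps(report, indent=2))

    (out / "volumes.json").write_text(json.dumps(
        {"volumes_mm3": volumes, "fractions_pct": fractions}, indent=2))

    manifest = {
        "config": {k: str(v) for k, v in asdict(cfg).items()},
        "config_hash": cfg.config_hash(),
        "timings_s": timings,
        "n_frames": len(frames),
        "n_elements": mesh.n_elements,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(surface=surf, mesh=mesh, table=table, volumes=volumes,
                          fractions=fractions, fe_result=fe_result, report=report,
                          manifest=manifest, output_dir=out)


def _versions() -> dict:
    import scipy
    import trimesh

    from . import __version__

    return {"ivus2fe": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "trimesh": trimesh.__version__}


def convergence_sweep(frames: list[VHFrame], c: Centerline, cfg: PipelineConfig,
                      resolutions: list[float]) -> dict:
    """Constituent volumes per resolution (one reconstruction per value).

    Failures at individual resolutions are collected, the rest continue.
    """
    if len(resolutions) < 2:
        raise ValueError("need at least 2 resolutions to sweep")
    from dataclasses import replace

    rows: dict[float, dict] = {}
    failures: dict[float, str] = {}
    for res in resolutions:
        try:
            sub = replace(cfg, resolution=res, solve=False)
            timings: dict = {}
            _, mesh, _ = reconstruct(frames, c, sub, timings)
            volumes, fractions = constituent_volumes(mesh)
            rows[res] = {"volumes_mm3": volumes, "fractions_pct": fractions,
                         "n_elements": mesh.n_elements}
        except Exception as exc:  # noqa: BLE001 - sweep must survive one bad run
            log.warning("resolution %.3f failed: %s", res, exc)
            failures[res] = str(exc)
    return {"rows": rows, "failures": failures}


def sweep_table(sweep: dict) -> str:
    """Delimited text table of a convergence sweep (resolution x constituent)."""
    rows = sweep["rows"]
    names = sorted({n for r in rows.values() for n in r["volumes_mm3"]})
    lines = ["resolution_mm\t" + "\t".join(names)]
    for res in sorted(rows, reverse=True):
        vols = rows[res]["volumes_mm3"]
        lines.append(f"{res:g}\t" + "\t".join(f"{vols.get(n, 0.0):.4f}" for n in names))
    return "\n".join(lines) + "\n"


def sleeve_sensitivity(frames: list[VHFrame], c: Centerline, cfg: PipelineConfig,
                       thicknesses=(0.0, 0.1, 0.2, 0.3, 0.4)) -> dict:
    """Mean wall stress as a function of sleeve thickness.

    Repeats reconstruction + solve for each sleeve thickness (0 = no
    sleeve) and reports the volume-weighted mean elemental Von Mises
    stress over the true tissue (sleeve excluded) plus the per-material
    table, quantifying how strongly the artificial support layer damps
    wall stress.
    """
    from dataclasses import replace

    from .fea import build_fe_model, solve_static, stress_report
    from .labels import Tissue

    out: dict = {"thickness_mm": list(thicknesses), "mean_vm_kpa": [],
                 "reports": []}
    for t in thicknesses:
        sub = replace(cfg, sleeve_thickness=t, solve=False)
        _, mesh, _ = reconstruct(frames, c, sub, {})
        table = material_table(cfg.material_overrides)
        model = build_fe_model(mesh, table, pressure_kpa=cfg.pressure_kpa,
                               steps=cfg.load_steps, law=cfg.law)
        res = solve_static(model)
        vols = mesh.volumes()
        tissue = mesh.material != Tissue.SLEEVE
        mean_vm = float(np.average(res.von_mises_element[tissue],
                                   weights=vols[tissue]))
        out["mean_vm_kpa"].append(round(mean_vm, 3))
        out["reports"].append(stress_report(res, mesh, table))
    return out


def straight_vs_curved(frames: list[VHFrame], c: Centerline,
                       cfg: PipelineConfig) -> dict:
    """Paired reconstructions with the curved and straightened centerline.

    Returns per-constituent volumes for both modes and their Pearson
    correlation across constituents.
    """
    from dataclasses import replace

    out = {}
    for mode, straight in (("curved", False), ("straight", True)):
        sub = replace(cfg, straight=straight, solve=False)
        _, mesh, _ = reconstruct(frames, c, sub, {})
        volumes, fractions = constituent_volumes(mesh)
        out[mode] = {"volumes_mm3": volumes, "fractions_pct": fractions}

    names = sorted(set(out["curved"]["volumes_mm3"]) | set(out["straight"]["volumes_mm3"]))
    a = np.array([out["curved"]["volumes_mm3"].get(n, 0.0) for n in names])
    b = np.array([out["straight"]["volumes_mm3"].get(n, 0.0) for n in names])
    out["constituents"] = names
    out["pearson_r"] = float(np.corrcoef(a, b)[0, 1])
    return out
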