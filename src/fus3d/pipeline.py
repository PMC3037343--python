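"""End-to-end orchestration: simulate → segment → reconstruct → register →
fuse → estimate volume → evaluate.

A PipelineConfig fully determines a run (one root seed feeds every
random stage), and the summary written at the end is byte-reproducible
from the config alone; per-stage wall times go to the log, not the
summary.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contours import Contour, polygon_to_mask
from .errors import Fus3dError, ReconstructionError
from .io import write_contours, write_frames, write_json, write_transform, write_volume
from .levelset import SegParams, segment_sequence
from .metrics import evaluation_report, relative_volume_error
from .param_opt import ParamGrid, optimize_params
from .phantom import ImageFrame, PhantomSpec, SweepSpec, apply_inter_view_motion, make_phantom_frames
from .reconstruction import (WallSurfaceSet, estimate_volume, extract_wall_mask,
                             fuse_views, planes_to_points, rasterize_to_grid)
from .registration import register_views
from .transforms import RigidTransform

log = logging.getLogger("fus3d")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    views: tuple[SweepSpec, ...] = field(default_factory=lambda: (SweepSpec(),))
    seg: SegParams = field(default_factory=SegParams)
    optimize: bool = False
    grid: ParamGrid | None = None
    criterion: str = "hausdorff"
    seed_contour_scale: float = 0.5
    erosion_radius: int = 4
    registration_spacing: float = 1.0    # mm/voxel of the wall-intensity volumes
    estimate_spacing: float = 0.5        # mm/voxel of the SDF occupancy grid
    register: bool = True
    seed: int = 0

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        def enc_t(t: RigidTransform):
            return t.as_matrix().tolist()

        d = asdict(self)
        d["phantom"]["gap_spec"] = [list(g) for g in self.phantom.gap_spec]
        d["views"] = []
        for v in self.views:
            vd = asdict(v)
            vd["base_pose"] = enc_t(v.base_pose)
            vd["inter_view_transform"] = enc_t(v.inter_view_transform)
            d["views"].append(vd)
        if self.grid is not None:
            d["grid"] = {k: list(v) for k, v in asdict(self.grid).items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        if "gap_spec" in ph:
            ph["gap_spec"] = tuple(tuple(g) for g in ph["gap_spec"])
        for key in ("semi_axes", "center"):
            if key in ph:
                ph[key] = tuple(ph[key])
        views = []
        for vd in d.pop("views", []):
            vd = dict(vd)
            vd["base_pose"] = RigidTransform.from_matrix(np.array(vd["base_pose"]))
            vd["inter_view_transform"] = RigidTransform.from_matrix(
                np.array(vd["inter_view_transform"]))
            for key in ("pixel_spacing", "image_size"):
                if key in vd:
                    vd[key] = tuple(vd[key])
            views.append(SweepSpec(**vd))
        seg = SegParams(**d.pop("seg", {}))
        grid_d = d.pop("grid", None)
        grid = ParamGrid(**{k: tuple(v) for k, v in grid_d.items()}) if grid_d else None
        return cls(phantom=PhantomSpec(**ph), views=tuple(views), seg=seg, grid=grid, **d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------


def middle_seed_contour(frames: list[ImageFrame], scale: float = 0.5) -> Contour:
    """Shrunken analytic contour of the middle frame, the simulation-mode
    stand-in for the user-drawn initial curve."""
    mid = frames[len(frames) // 2]
    if mid.truth_contour is None:
        raise Fus3dError("middle frame does not intersect the phantom; cannot seed")
    return mid.truth_contour.scaled(scale)


def view_wall_points(frames, contours, erosion_radius: int, source_view: str = "",
                     min_area_px: float = 10.0) -> WallSurfaceSet:
    """Wall-surface point set of one segmented view."""
    pairs = []
    for frame, contour in zip(frames, contours):
        if contour is None or contour.area() < min_area_px:
            continue
        mask = polygon_to_mask(frame.shape, contour.points)
        try:
            wall = extract_wall_mask(mask, erosion_radius)
        except ReconstructionError:
            continue  # region too small for the ring on this frame
        pairs.append((frame, wall))
    return planes_to_points(pairs, source_view)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the full flow; returns (and optionally writes) the summary."""
    t0 = time.perf_counter()
    log.info("fus3d %s | config %s | seed %d", __version__, config.config_hash(), config.seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(config.to_yaml())

    def stage(name, start):
        log.info("stage %-12s %.2f s", name, time.perf_counter() - start)
        return time.perf_counter()

    # simulate ------------------------------------------------------------
    t = time.perf_counter()
    views_frames: list[list[ImageFrame]] = []
    for i, sweep in enumerate(config.views):
        frames = make_phantom_frames(config.phantom, sweep, config.seed + i)
        frames = apply_inter_view_motion(frames, sweep.inter_view_transform)
        views_frames.append(frames)
        if outdir is not None:
            write_frames(outdir / f"view_{sweep.window_id}_{sweep.view_axis}", frames)
    t = stage("simulate", t)

    # parameter optimization ----------------------------------------------
    params = config.seg
    opt_block = None
    if config.optimize:
        mid = views_frames[0][len(views_frames[0]) // 2]
        seed_c = middle_seed_contour(views_frames[0], config.seed_contour_scale)
        result = optimize_params(mid, mid.truth_contour, seed_c,
                                 grid=config.grid, criterion=config.criterion, base=params)
        params = result.best_params
        opt_block = {"criterion": config.criterion,
                     "best": {"t_res": params.t_res, "epsilon": params.epsilon,
                              "beta": params.beta1},
                     "best_hausdorff_mm": result.best_hausdorff,
                     "best_mad_mm": result.best_mad}
        if outdir is not None:
            result.error_surface.to_csv(outdir / "error_surface.csv", index=False)
        t = stage("optimize", t)

    # segment ---------------------------------------------------------------
    seg_block = {}
    views_contours = []
    for sweep, frames in zip(config.views, views_frames):
        seed_c = middle_seed_contour(frames, config.seed_contour_scale)
        contours = segment_sequence(frames, seed_c, params)
        views_contours.append(contours)
        spacing = float(np.mean(sweep.pixel_spacing))
        report = evaluation_report(contours, [f.truth_contour for f in frames], spacing)
        key = f"{sweep.window_id}/{sweep.view_axis}"
        per_frame = report[report.frame_index >= 0]
        seg_block[key] = {
            "n_frames": len(frames),
            "n_segmented": int(sum(c is not None for c in contours)),
            "mean_mad_mm": round(float(per_frame.mad_mm.mean()), 6) if len(per_frame) else None,
            "mean_hausdorff_mm": round(float(per_frame.hausdorff_mm.mean()), 6) if len(per_frame) else None,
        }
        if outdir is not None:
            vdir = outdir / f"view_{sweep.window_id}_{sweep.view_axis}"
            write_contours(vdir / "contours", contours)
            report.to_csv(vdir / "evaluation.csv", index=False)
    t = stage("segment", t)

    # reconstruct ------------------------------------------------------------
    wall_sets = []
    for sweep, frames, contours in zip(config.views, views_frames, views_contours):
        wall_sets.append(view_wall_points(frames, contours, config.erosion_radius,
                                          f"{sweep.window_id}/{sweep.view_axis}"))
    volumes = [rasterize_to_grid(w, config.registration_spacing) for w in wall_sets]
    t = stage("reconstruct", t)

    # register ----------------------------------------------------------------
    n_views = len(config.views)
    n_planes = [sum(c is not None for c in vc) for vc in views_contours]
    ref_idx = max(range(n_views), key=lambda i: (n_planes[i], wall_sets[i].n_points))
    transforms = [RigidTransform.identity()] * n_views
    reg_block = None
    if config.register and n_views > 1:
        reg_block = {}
        for i in range(n_views):
            if i == ref_idx:
                continue
            res = register_views(wall_sets[ref_idx], wall_sets[i],
                                 spacing=config.registration_spacing)
            transforms[i] = res.transform
            key = wall_sets[i].source_view
            reg_block[key] = {
                "rotation_deg": round(res.transform.rotation_angle_deg(), 6),
                "translation_mm": [round(v, 6) for v in res.transform.translation],
                "objective": round(res.objective, 8),
                "objective_init": round(res.objective_init, 8),
                "n_overlap": res.n_overlap,
                "converged": res.converged,
            }
            if outdir is not None:
                write_transform(outdir / f"transform_{key.replace('/', '_')}.txt", res.transform)
        t = stage("register", t)

    # fuse ----------------------------------------------------------------------
    order = [ref_idx] + [i for i in range(n_views) if i != ref_idx]
    fused = fuse_views([volumes[i] for i in order], [transforms[i] for i in order])
    if outdir is not None:
        write_volume(outdir / "fused_walls.nii.gz", fused)
    t = stage("fuse", t)

    # estimate volume -------------------------------------------------------------
    true_cc = config.phantom.volume_cc
    vol_block = {"true_cc": round(true_cc, 6), "per_view": {}, }
    for sweep, frames, contours, tr in zip(config.views, views_frames, views_contours, transforms):
        planes = [(f, c) for f, c in zip(frames, contours) if c is not None]
        key = f"{sweep.window_id}/{sweep.view_axis}"
        try:
            est = estimate_volume(planes, spacing=config.estimate_spacing)
            vol_block["per_view"][key] = {
                "estimate_cc": round(est, 6),
                "relative_error_pct": round(relative_volume_error(est, true_cc), 6)}
        except ReconstructionError as exc:
            vol_block["per_view"][key] = {"error": str(exc)}
    all_planes, all_transforms = [], []
    for frames, contours, tr in zip(views_frames, views_contours, transforms):
        for f, c in zip(frames, contours):
            if c is not None:
                all_planes.append((f, c))
                all_transforms.append(tr)
    est = estimate_volume(all_planes, all_transforms, spacing=config.estimate_spacing)
    vol_block["combined"] = {"estimate_cc": round(est, 6),
                             "n_planes": len(all_planes),
                             "relative_error_pct": round(relative_volume_error(est, true_cc), 6)}
    t = stage("estimate", t)

    summary = {
        "fus3d_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_views": n_views,
        "reference_view": wall_sets[ref_idx].source_view,
        "parameters": {"t_res": params.t_res, "epsilon": params.epsilon,
                       "beta1": params.beta1, "beta2": params.beta2},
        "segmentation": seg_block,
        "volumes": vol_block,
    }
    if opt_block is not None:
        summary["optimization"] = opt_block
    if reg_block is not None:
        summary["registration"] = reg_block
    if outdir is not None:
        write_json(outdir / "summary.json", summary)
    log.info("pipeline done in %.2f s", time.perf_counter() - t0)
    return summary
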