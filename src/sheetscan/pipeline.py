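"""End-to-end orchestration: simulate -> IVM -> detect -> evaluate -> report.

A pipeline run renders a main synthetic dish, detects and scores it against
ground truth, simulates microscope-style k-of-25 field sampling, renders a
series of replicate dishes across a density range to correlate detected and
true totals, and writes everything (images, CSVs, JSON report) into one
output directory.  All randomness flows from a single top-level seed, so a
re-run with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fov, io
from .detect import DetectorConfig, count_whole_vessel
from .errors import classify_errors, match_detections, r_squared
from .ivm import DISPLAY_GAIN, amplify_clip, brightness_stats, compute_ivm, \
    cross_entropy, object_contrast
from .phase import cell_region_from_phase
from .synthetic import SceneParams, render_scene

log = logging.getLogger("sheetscan")


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; round-trips losslessly through YAML."""

    out_dir: str = "sheetscan_out"
    seed: int = 0
    scene: SceneParams = field(default_factory=SceneParams)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    match_radius_px: float = 5.0
    n_replicate_dishes: int = 15
    replicate_cells_range: tuple[int, int] = (50, 500)
    replicate_size_px: int = 512
    fov_ks: tuple = fov.DEFAULT_KS
    fov_n_combos: int = fov.DEFAULT_N_COMBOS
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = io._params_to_dict(self.scene)
        d["replicate_cells_range"] = list(self.replicate_cells_range)
        d["fov_ks"] = list(self.fov_ks)
        d["scene"]["cell_diameter_um"] = list(d["scene"]["cell_diameter_um"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .pattern import PatternSpec

        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scene" in d:
            sd = dict(d["scene"])
            s_known = {f.name for f in dataclasses.fields(SceneParams)}
            s_unknown = set(sd) - s_known
            if s_unknown:
                raise ValueError(f"unknown scene keys: {sorted(s_unknown)}")
            if sd.get("pattern") is not None:
                sd["pattern"] = PatternSpec(**sd["pattern"])
            if "cell_diameter_um" in sd:
                sd["cell_diameter_um"] = tuple(sd["cell_diameter_um"])
            d["scene"] = SceneParams(**sd)
        if "detector" in d:
            d["detector"] = DetectorConfig(**d["detector"])
        if "replicate_cells_range" in d:
            d["replicate_cells_range"] = tuple(d["replicate_cells_range"])
        if "fov_ks" in d:
            d["fov_ks"] = tuple(d["fov_ks"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary report dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline seed = %d", config.seed)
    config.to_yaml(out / "config.yaml")

    # --- main dish -------------------------------------------------------
    scene_params = dataclasses.replace(config.scene, seed=config.seed)
    scene = render_scene(scene_params)
    io.write_scene(scene, out / "scene")

    ivm = compute_ivm(scene.scan)
    display = amplify_clip(ivm, DISPLAY_GAIN)
    io.write_image16(out / "ivm_display.tif", display)

    det = count_whole_vessel(scene.scan, cfg=config.detector)
    io.write_detections_csv(out / "detections.csv", det)

    matching = match_detections(det, scene.truth, config.match_radius_px)
    report = classify_errors(
        matching, det, scene.truth, pixel_size_um=scene_params.pixel_size_um
    )
    region = cell_region_from_phase(scene.phase)
    bmean, bsd = brightness_stats(scene.scan)
    px_um = scene_params.pixel_size_um
    area_px = scene_params.width_px * scene_params.height_px

    err_dict = dataclasses.asdict(report)
    if report.n_truth:
        err_dict.update(report.percentages())
    io.write_json(out / "error_report.json", err_dict)

    # --- FOV sampling on the main dish ----------------------------------
    fov_rows = None
    try:
        grid = fov.place_fields(
            np.ones(scene.scan.shape, dtype=bool),
            field_w_px=min(fov.DEFAULT_FIELD_W_PX, scene_params.width_px // 6),
            field_h_px=min(fov.DEFAULT_FIELD_H_PX, scene_params.height_px // 6),
            pixel_size_um=px_um,
        )
        counts = fov.field_counts(scene.truth.cell_centroids, grid)
        if scene.truth.cell_centroids.size:
            rng = np.random.default_rng(config.seed + 1)
            fov_rows = fov.timeseries_discrepancy(
                [counts], [len(scene.truth.cell_centroids)], grid,
                ks=config.fov_ks, n_combos=config.fov_n_combos, rng=rng,
            )
            fov_rows.to_csv(out / "fov_sampling.csv", index=False,
                            float_format="%.4f")
    except ValueError as exc:
        log.warning("FOV sampling skipped: %s", exc)

    # --- replicate dishes for the density correlation --------------------
    lo, hi = config.replicate_cells_range
    truth_totals, det_totals = [], []
    for i in range(config.n_replicate_dishes):
        n_cells = int(round(lo + (hi - lo) * i / max(config.n_replicate_dishes - 1, 1)))
        rp = dataclasses.replace(
            config.scene,
            width_px=config.replicate_size_px,
            height_px=config.replicate_size_px,
            n_cells=n_cells,
            seed=config.seed + 100 + i,
        )
        rs = render_scene(rp)
        rdet = count_whole_vessel(rs.scan, cfg=config.detector)
        truth_totals.append(len(rs.truth.cell_centroids))
        det_totals.append(len(rdet))
    r2 = r_squared(truth_totals, det_totals)

    summary = {
        "seed": config.seed,
        "total_count_detected": int(len(det)),
        "total_count_truth": int(len(scene.truth.cell_centroids)),
        "density_detected_cells_per_cm2": len(det) / (area_px * (px_um * 1e-4) ** 2),
        "density_truth_cells_per_cm2": len(scene.truth.cell_centroids)
        / (area_px * (px_um * 1e-4) ** 2),
        "brightness_mean": bmean,
        "brightness_sd": bsd,
        "object_contrast": object_contrast(ivm),
        "cross_entropy_ivm_vs_phase_region": cross_entropy(region.pixels, display),
        "r_squared_replicates": r2,
        "replicate_truth_totals": truth_totals,
        "replicate_detected_totals": det_totals,
        "error_report": err_dict,
    }
    if fov_rows is not None:
        spread = (
            fov_rows.groupby("k")["discrepancy_pct"]
            .agg(lambda s: float(s.max() - s.min()))
            .to_dict()
        )
        summary["fov_discrepancy_spread_pct_by_k"] = {
            str(k): v for k, v in spread.items()
        }
    io.write_json(out / "summary.json", summary)
    return summary
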