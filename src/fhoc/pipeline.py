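"""End-to-end orchestration on synthetic data.

``run_end_to_end`` wires the whole analysis together: generate synthetic
masks and a measurement cohort, measure every mask, evaluate segmentation and
landmark metrics against the analytic ground truth, run the agreement battery
on paired AI-vs-reader measurements, and fit per-sex growth charts with
percentile tables and age-bin errors.  Every output (CSV/JSON/PNG) plus the
run configuration and a log with stage timings is written to one directory;
identical configurations produce identical tabular outputs.

A single top-level seed deterministically derives an independent seed per
stage (by hashing the stage name), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, growthchart, seg_metrics, synthetic
from .measurement import measure_mask, save_mask
from .reference import DEFAULT_TAUS, SEXES

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable configuration of an end-to-end run."""

    seed: int = 0
    output_dir: str = "fhoc_run"
    # mask stage
    spacing_mm: float = 0.2
    n_masks: int = 30
    image_size: int = 192
    mask_noise_sd_px: float = 0.6
    # cohort stage
    n_per_sex_per_agegroup: int = 25
    bilateral_corr: float = 0.98
    reader_bias_mm: float = 0.0
    reader_noise_sd_mm: float = 0.96
    # growth chart stage
    taus: tuple[float, ...] = DEFAULT_TAUS
    degree: int = 3
    grid_step_years: float = 0.25
    n_boot: int = 1000

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of ``"{seed}:{stage}"``, below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _random_shape(rng: np.random.Generator, image_size: int,
                  noise_sd: float) -> synthetic.ShapeParams:
    a = rng.uniform(18, image_size * 0.28)
    b = a * rng.uniform(0.6, 1.0)
    return synthetic.ShapeParams(
        semi_axis_a=a, semi_axis_b=b,
        center=(image_size / 2 + rng.uniform(-5, 5), image_size / 2 + rng.uniform(-5, 5)),
        rotation_deg=rng.uniform(-30, 30),
        boundary_noise_sd=noise_sd,
        crescent_fraction=float(rng.uniform(0.0, 0.3)) if rng.random() < 0.5 else 0.0,
    )


def run_end_to_end(config: RunConfig) -> dict[str, Path]:
    """Run the full synthetic pipeline; returns a dict of output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    (out / "config.json").write_text(config.to_json())
    paths["config"] = out / "config.json"

    def stage(name: str):
        s = derive_seed(config.seed, name)
        logger.info("stage %s: seed=%d", name, s)
        return s, time.perf_counter()

    try:
        # ------------------------------------------------------- masks
        seed, t0 = stage("masks")
        rng = np.random.default_rng(seed)
        truth_rows, meas_rows, seg_rows = [], [], []
        pred_pts, true_pts = [], []
        for i in range(config.n_masks):
            mask_id = f"mask_{i:03d}"
            try:
                params = _random_shape(rng, config.image_size, config.mask_noise_sd_px)
                shape = (config.image_size, config.image_size)
                noisy, truth = synthetic.gen_fhoc_mask(
                    params, shape, config.spacing_mm, seed=seed + i + 1)
                clean_params = dataclasses.replace(params, boundary_noise_sd=0.0)
                clean, _ = synthetic.gen_fhoc_mask(clean_params, shape, config.spacing_mm)
                save_mask(noisy, out / "masks" / f"{mask_id}.png")
                save_mask(clean, out / "masks" / f"{mask_id}_truth.png")
                res = measure_mask(noisy, side="unknown")
                truth_rows.append({
                    "mask_id": mask_id,
                    "true_min_row_px": truth.point_min_col[0], "true_min_col_px": truth.point_min_col[1],
                    "true_max_row_px": truth.point_max_col[0], "true_max_col_px": truth.point_max_col[1],
                    "true_diameter_mm": truth.diameter_mm,
                })
                meas_rows.append({
                    "mask_id": mask_id,
                    "size_mm": res.size_mm,
                    "true_diameter_mm": truth.diameter_mm,
                    "abs_error_mm": abs(res.size_mm - truth.diameter_mm),
                    "n_components_found": res.n_components_found,
                })
                seg_rows.append({
                    "mask_id": mask_id,
                    "dice": seg_metrics.dice(noisy, clean),
                    "hausdorff_mm": seg_metrics.hausdorff(noisy, clean, config.spacing_mm),
                })
                pred_pts += [res.landmarks.medial, res.landmarks.lateral]
                true_pts += [truth.point_min_col, truth.point_max_col]
            except Exception as e:  # noqa: BLE001 - annotate with the input id
                raise PipelineStageError(f"stage 'masks' failed on input {mask_id}: {e}") from e
        pd.DataFrame(truth_rows).to_csv(out / "mask_truth.csv", index=False)
        pd.DataFrame(meas_rows).to_csv(out / "measurements.csv", index=False)
        pd.DataFrame(seg_rows).to_csv(out / "seg_metrics.csv", index=False)
        sdr = seg_metrics.radial_errors(np.array(pred_pts), np.array(true_pts),
                                        config.spacing_mm)
        pd.DataFrame({
            "threshold_mm": sdr.thresholds_mm, "sdr_pct": sdr.rates_pct,
            "mre_mm": [sdr.mre_mm] * len(sdr.thresholds_mm),
        }).to_csv(out / "landmark_metrics.csv", index=False)
        paths.update(mask_truth=out / "mask_truth.csv", measurements=out / "measurements.csv",
                     seg_metrics=out / "seg_metrics.csv", landmark_metrics=out / "landmark_metrics.csv")
        logger.info("stage masks: %d masks in %.2fs", config.n_masks, time.perf_counter() - t0)

        # ------------------------------------------------------- cohort
        seed, t0 = stage("cohort")
        try:
            gen_cfg = synthetic.GeneratorConfig(
                n_per_sex_per_agegroup=config.n_per_sex_per_agegroup,
                bilateral_corr=config.bilateral_corr,
                reader_bias_mm=config.reader_bias_mm,
                reader_noise_sd_mm=config.reader_noise_sd_mm,
                seed=seed,
            )
            cohort = synthetic.gen_cohort(gen_cfg)
            cohort = synthetic.gen_paired_measurements(
                cohort, bias_mm=config.reader_bias_mm,
                noise_sd_mm=config.reader_noise_sd_mm,
                seed=derive_seed(config.seed, "reader"),
            )
            synthetic.save_cohort(cohort, out / "cohort.csv")
        except Exception as e:
            raise PipelineStageError(f"stage 'cohort' failed: {e}") from e
        paths["cohort"] = out / "cohort.csv"
        logger.info("stage cohort: %d rows in %.2fs", len(cohort), time.perf_counter() - t0)

        # ------------------------------------------------------- agreement
        seed, t0 = stage("agreement")
        try:
            for name, by in (("overall", None), ("by_sex", "sex"),
                             ("by_side", "side"), ("by_age_sex", ("age", "sex"))):
                res = agreement.stratified_agreement(cohort, by=by, n_boot=config.n_boot,
                                                     seed=seed)
                agreement.strata_to_frame(res).to_csv(out / f"agreement_{name}.csv",
                                                      index=False)
                paths[f"agreement_{name}"] = out / f"agreement_{name}.csv"
        except Exception as e:
            raise PipelineStageError(f"stage 'agreement' failed: {e}") from e
        logger.info("stage agreement: %.2fs", time.perf_counter() - t0)

        # ------------------------------------------------------- growth chart
        seed, t0 = stage("growthchart")
        try:
            models = growthchart.fit_quantile_curves(
                cohort, taus=config.taus, degree=config.degree,
                grid_step=config.grid_step_years)
            growthchart.save_models(models, out / "models.json")
            paths["models"] = out / "models.json"
            for sex in SEXES:
                if sex not in models:
                    continue
                model = models[sex]
                sub = cohort[cohort["sex"] == sex]
                growthchart.predict_percentiles(model).to_csv(
                    out / f"percentile_table_{sex}.csv", index=False)
                errs = growthchart.group_errors(model, sub, n_boot=config.n_boot,
                                                seed=seed)
                errs.to_csv(out / f"age_bin_errors_{sex}.csv", index=False)
                r2 = growthchart.adjusted_r2(model, sub["age_years"], sub["size_mm"])
                (out / f"adjusted_r2_{sex}.json").write_text(
                    json.dumps({"adjusted_r2": r2, "n": len(sub)}))
                ax = growthchart.plot_growth_chart(model, sub)
                ax.figure.savefig(out / f"growth_chart_{sex}.png", dpi=110)
                import matplotlib.pyplot as plt
                plt.close(ax.figure)
                paths[f"percentile_table_{sex}"] = out / f"percentile_table_{sex}.csv"
                paths[f"age_bin_errors_{sex}"] = out / f"age_bin_errors_{sex}.csv"
        except PipelineStageError:
            raise
        except Exception as e:
            raise PipelineStageError(f"stage 'growthchart' failed: {e}") from e
        logger.info("stage growthchart: %.2fs", time.perf_counter() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    paths["log"] = log_path
    return paths
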