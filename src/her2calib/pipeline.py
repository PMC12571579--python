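"""End-to-end orchestration: simulate -> quantify -> analyse -> report.

Every run is parameterised by a :class:`RunConfig` whose JSON serialisation
(and hash) is echoed into each report, so any numeric output is traceable to
the exact configuration and seed that produced it.  Outputs are plain CSV
(comma-separated, UTF-8, header row, "." decimal, scores serialised from the
set {0, 0.5, 1, 2, 3}) and JSON; calibrator images are 8-bit RGB PNG.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__, consensus, diagnostics, dynamic_range, lod, synthetic
from .consensus import LabCriterion

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("her2calib")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for actionable messages."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Serialisable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "her2calib-run"
    write_images: bool = False        # calibrator PNGs are bulky; opt in
    n_image_labs: int = 3             # how many labs get rendered slides
    include_ultralow: bool = True
    alpha: float = 0.05
    bin_centers: tuple[float, ...] = dynamic_range.DEFAULT_BIN_CENTERS
    bin_halfwidth: float = dynamic_range.DEFAULT_HALFWIDTH
    gold_lod_above: float = 40_000.0
    mismatch_lod_below: float = 20_000.0
    trastuzumab_group: tuple[float, float] = (30_000.0, 60_000.0)
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Stages: simulate the study tables (and optionally calibrator slide
    images), recover LODs from the rendered slides, compute consensus scores
    and aggregate dynamic-range regressions for both readout arms, diagnostic
    accuracy against ISH for the predicate-range group, and the LOD-mismatch
    accuracy profiles.  Returns the report dict (also written as
    ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash,
        "config": json.loads(config.to_json()),
        "stages": {},
    }
    sim = dataclasses.replace(config.sim, seed=config.seed)

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        study = synthetic.simulate_study(sim)
        for name, df in study.items():
            _write_csv(df, out / f"{name}.csv")
        (out / "config.json").write_text(config.to_json(), encoding="utf-8")
        report["stages"][stage] = {
            "n_cores": len(study["cores"]),
            "n_labs": len(study["labs"]),
            "n_scores": len(study["scores"]),
        }
        log.info("simulate: %d cores, %d lab arms", len(study["cores"]),
                 len(study["labs"]))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- calibrator images + LOD recovery ---------------------------------
    stage = "lod"
    try:
        labs = study["labs"]
        physical = labs[labs["readout"] == "manual"].head(config.n_image_labs)
        rows = []
        for i, lab in enumerate(physical.itertuples(index=False)):
            imgs = []
            for dup in range(2):
                img, _ = synthetic.generate_calibrator_image(
                    lab.true_lod, sim.curve, sim.bead_noise_sd,
                    seed=config.seed + 7919 * (2 * i + dup) + 1)
                imgs.append(img)
                if config.write_images:
                    iio.imwrite(out / f"calibrator_{lab.lab_id}_{dup}.png", img)
            est = lod.lod_from_images(imgs[0], imgs[1])
            rows.append({"lab_id": lab.lab_id, "true_lod": lab.true_lod,
                         "estimated_lod": est.lod, "r_squared": est.r_squared,
                         "n_points_used": est.n_points_used,
                         "extrapolated": est.extrapolated_below_lowest})
        lod_table = pd.DataFrame(rows)
        _write_csv(lod_table, out / "lod_estimates.csv")
        report["stages"][stage] = {
            "n_slides": len(rows),
            "max_rel_error": float(
                (abs(lod_table["estimated_lod"] - lod_table["true_lod"])
                 / lod_table["true_lod"]).max()) if rows else None,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- consensus for the predicate-range group --------------------------
    stage = "consensus"
    try:
        lo, hi = config.trastuzumab_group
        crit = LabCriterion.interval(lo, hi, readout="manual")
        group = consensus.select_labs(labs, crit)
        cons = consensus.consensus_scores(study["scores"], group,
                                          config.include_ultralow)
        _write_csv(cons, out / "consensus_scores.csv")
        report["stages"][stage] = {
            "criterion": crit.description, "n_labs": len(group),
            "aggregate_score": float(cons["rounded_score"].mean()),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- dynamic range -----------------------------------------------------
    stage = "dynrange"
    try:
        bins = dynamic_range.bin_labs(labs, config.bin_centers,
                                      config.bin_halfwidth)
        slopes = {}
        for readout in ("image_analysis", "manual"):
            res = dynamic_range.dynamic_range_slope(
                bins, study["scores"], labs, config.include_ultralow, readout)
            slopes[readout] = res
        p_cmp = dynamic_range.compare_slopes(slopes["image_analysis"],
                                             slopes["manual"])
        report["stages"][stage] = {
            r: {"slope": s.slope, "se": s.se_slope, "p_value": s.p_value,
                "n_bins": s.n_points}
            for r, s in slopes.items()
        }
        report["stages"][stage]["compare_slopes_p"] = p_cmp
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- diagnostic accuracy vs ISH ---------------------------------------
    stage = "accuracy"
    try:
        counts = diagnostics.trastuzumab_confusion(cons, study["ish"])
        metrics = diagnostics.diagnostic_metrics(counts, config.alpha)
        report["stages"][stage] = {
            "confusion": dataclasses.asdict(counts),
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "ppv": metrics.ppv, "npv": metrics.npv,
            "accuracy": metrics.accuracy,
            "ci": {k: list(v) for k, v in metrics.ci.items()},
            "alpha": config.alpha,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- LOD mismatch modelling -------------------------------------------
    stage = "mismatch"
    try:
        rule = diagnostics.TreatmentRule(include_ultralow=config.include_ultralow)
        profiles = {}
        for tag, crit in (
            ("gold_insensitive",
             LabCriterion.lod_above(config.gold_lod_above, readout="image_analysis")),
            ("gold_sensitive",
             LabCriterion.lod_below(config.mismatch_lod_below, readout="image_analysis")),
        ):
            gold = diagnostics.tdxd_gold_standard(
                study["scores"], labs, crit, rule, study["ish"])
            prof = diagnostics.lab_accuracy_profile(
                study["scores"], labs, gold, rule, study["ish"],
                readout="image_analysis")
            _write_csv(prof, out / f"accuracy_profile_{tag}.csv")
            hi_m = prof.loc[prof["lod"] >= config.gold_lod_above, "accuracy"].mean()
            lo_m = prof.loc[prof["lod"] < config.mismatch_lod_below, "accuracy"].mean()
            profiles[tag] = {"criterion": crit.description,
                             "mean_accuracy_lod_ge_40k": float(hi_m),
                             "mean_accuracy_lod_lt_20k": float(lo_m)}
        report["stages"][stage] = profiles
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float),
        encoding="utf-8")
    return report
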