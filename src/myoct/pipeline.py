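"""End-to-end orchestration: phantom cohort → densitometry → physiology →
diagnostics, with a structured config and a reproducible report bundle.

Stages communicate only through the cohort table, so each stage can be
re-run independently on saved intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import densitometry, diagnostics, physiology
from .densitometry import SliceROI
from .phantom import CohortDesign, PhantomSpec, PhantomVolume, default_design, generate_cohort
from .volume_io import AnimalRecord, CohortTable, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "measure_phantom", "derive_cohort_table", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (detected before any computation)."""


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    output_dir: str = "myoct_run"
    n_animals: int = 12
    seed: int = 0
    fat_window: tuple[float, float] = (-300.0, -30.0)
    lean_window: tuple[float, float] = (-30.0, 300.0)
    bone_threshold: float = 300.0
    muscle_window: tuple[float, float] = (-250.0, 300.0)
    biopsy_target_volume: float = 1.3  # cm^3, auto-scaled to the liver
    density_bins: tuple = diagnostics.DENSITY_BINS
    hu_offset: float = densitometry.HU_OFFSET
    cutoff_rule: str = "youden"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    save_volumes: bool = False

    def validate(self) -> None:
        if self.n_animals < 0:
            raise ConfigError("n_animals must be non-negative")
        f_lo, f_hi = self.fat_window
        l_lo, l_hi = self.lean_window
        if not (f_lo < f_hi <= l_lo < l_hi <= self.bone_threshold):
            raise ConfigError("tissue windows must be ordered and non-overlapping")
        if self.biopsy_target_volume <= 0:
            raise ConfigError("biopsy target volume must be positive")
        if self.cutoff_rule != "youden":
            raise ConfigError(f"unknown cutoff rule {self.cutoff_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom_kwargs = raw.pop("phantom", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fat_window", "lean_window", "muscle_window", "density_bins"):
            if key in raw:
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in raw[key]) if key == "density_bins" else tuple(raw[key])
        cfg = cls(phantom=PhantomSpec(**phantom_kwargs), **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def measure_phantom(phantom: PhantomVolume, config: RunConfig | None = None) -> dict:
    """Run all three densitometry analyses on one phantom.

    Returns the derived imaging columns for the cohort table: compartment
    volumes, CT-estimated body weight, dorsal-muscle areas and densities,
    visceral fat area, liver biopsy density, spleen density and the
    spleen-normalized ratios.
    """
    cfg = config or RunConfig()
    vol = phantom.calibrated()
    labels = densitometry.classify_tissues(
        vol, cfg.fat_window, cfg.lean_window, cfg.bone_threshold
    )
    est_bw = densitometry.estimate_body_weight(labels)
    roi_l4 = SliceROI(phantom.slice_index_l4, phantom.masks["dorsal_muscle_l4"])
    roi_l5 = SliceROI(phantom.slice_index_l5, phantom.masks["dorsal_muscle_l5"])
    metrics = densitometry.dorsal_muscle_metrics(vol, roi_l4, roi_l5, cfg.muscle_window)
    vfat = densitometry.visceral_fat_area(
        vol,
        SliceROI(phantom.slice_index_l4, np.ones(phantom.grey_volume.shape[1:], dtype=bool)),
        cfg.fat_window,
    )
    biopsy = densitometry.virtual_liver_biopsy(
        vol,
        phantom.masks["liver"],
        phantom.masks["liver_vessels"],
        target_volume=cfg.biopsy_target_volume,
        seed=phantom.spec.seed,
    )
    spleen_hu = densitometry.spleen_density(vol, phantom.masks["spleen"])
    ratios = densitometry.normalize_densities(
        metrics.dorsal_muscle_hu_mean,
        biopsy.mean_hu,
        spleen_hu,
        metrics.dorsal_muscle_area_mean,
        est_bw,
        offset=cfg.hu_offset,
    )
    return {
        "v_fat_cm3": labels.v_fat,
        "v_lean_cm3": labels.v_lean,
        "v_bone_cm3": labels.v_bone,
        "ct_body_weight": est_bw,
        "true_mass": phantom.truth.mass,
        "true_muscle_lipid_fraction": phantom.truth.muscle_lipid_fraction,
        "true_liver_lipid_fraction": phantom.truth.liver_lipid_fraction,
        "dorsal_muscle_area_mean": metrics.dorsal_muscle_area_mean,
        "dorsal_muscle_hu_mean": metrics.dorsal_muscle_hu_mean,
        "visceral_fat_area_l4": vfat,
        "liver_biopsy_hu": biopsy.mean_hu,
        "spleen_hu": spleen_hu,
        "muscle_density_ratio": ratios.muscle_density_ratio,
        "liver_density_ratio": ratios.liver_density_ratio,
        "relative_muscle_area": ratios.relative_muscle_area,
        "roi_flags": ";".join(metrics.flags),
    }


def _physio_columns(record: AnimalRecord) -> dict:
    out: dict = {}
    if record.glycaemia is not None and record.insulinaemia is not None:
        out["homa_ir"] = physiology.homa_ir(record.glycaemia, record.insulinaemia)
    if len(record.grip_trials) >= 2:
        out["grip_strength"] = physiology.grip_strength_summary(record.grip_trials)
    if None not in (record.steatosis, record.inflammation, record.ballooning):
        lab = physiology.classify_liver(record.steatosis, record.inflammation, record.ballooning)
        out["nas_total"] = lab.nas_total
        out["liver_label"] = lab.label
        out["nash"] = int(lab.label == "NASH")
    return out


def derive_cohort_table(pairs, config: RunConfig | None = None) -> CohortTable:
    """Measure every (phantom, record) pair and assemble the cohort table."""
    cfg = config or RunConfig()
    records = []
    for phantom, record in pairs:
        t0 = time.perf_counter()
        record.derived.update(measure_phantom(phantom, cfg))
        record.derived.update(_physio_columns(record))
        logger.info(
            "measured %s in %.2f s", record.animal_id, time.perf_counter() - t0
        )
        records.append(record)
    return CohortTable.from_records(records)


def _diagnose(table: CohortTable, cfg: RunConfig) -> dict:
    df = table.df
    if "nash" not in df.columns or "muscle_density_ratio" not in df.columns:
        raise ConfigError("diagnostics need 'nash' and 'muscle_density_ratio' columns")
    scores = df["muscle_density_ratio"].to_numpy(dtype=float)
    labels = df["nash"].to_numpy(dtype=int)
    roc = diagnostics.roc_curve(scores, labels, direction="lower")
    cutoff = diagnostics.select_cutoff(roc, scores, labels, rule=cfg.cutoff_rule)
    strata = diagnostics.stratify_density(scores, labels, bins=cfg.density_bins)
    out = {"roc": roc, "cutoff": cutoff, "strata": strata, "logistic": None}
    predictors = [
        c for c in ("muscle_density_ratio", "homa_ir", "visceral_fat_area_l4") if c in df.columns
    ]
    try:
        out["logistic"] = diagnostics.logistic_fit(labels, df[predictors])
    except diagnostics.SeparationError as exc:
        logger.warning("logistic adjustment skipped: %s", exc)
    return out


def run_pipeline(config: RunConfig, design: CohortDesign | None = None) -> dict:
    """Simulate, measure and diagnose a phantom cohort; write the bundle.

    Writes into ``config.output_dir``: the echoed config, the derived
    per-animal cohort CSV, ROC points CSV, cutoff report JSON, the density
    stratification CSV, the logistic fit JSON and a run log. Re-running
    with an identical config is bit-identical for all deterministic
    stages.
    """
    config.validate()
    t_start = time.perf_counter()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))

    design = design or default_design(config.phantom)
    pairs = generate_cohort(config.n_animals, design, config.seed)
    if config.save_volumes:
        for phantom, record in pairs:
            phantom.save(outdir / "volumes" / record.animal_id)
    table = derive_cohort_table(pairs, config)
    write_cohort(table, outdir / "cohort.csv")

    report: dict = {"n_animals": len(table), "seed": config.seed}
    if len(table) and "nash" in table.df.columns and table.df["nash"].nunique() == 2:
        diag = _diagnose(table, config)
        pd.DataFrame({"fpr": diag["roc"].fpr, "tpr": diag["roc"].tpr}).to_csv(
            outdir / "roc_points.csv", index=False
        )
        cut = diag["cutoff"]
        (outdir / "cutoff.json").write_text(
            json.dumps(
                {
                    "cutoff": cut.cutoff,
                    "direction": cut.direction,
                    "sensitivity": cut.sensitivity,
                    "specificity": cut.specificity,
                    "ci_sens": cut.ci_sens,
                    "ci_spec": cut.ci_spec,
                    "lr_positive": None if np.isinf(cut.lr_positive) else cut.lr_positive,
                    "counts": {"tp": cut.tp, "fp": cut.fp, "tn": cut.tn, "fn": cut.fn},
                },
                indent=2,
            )
        )
        diag["strata"].to_csv(outdir / "strata.csv", index=False)
        if diag["logistic"] is not None:
            fit = diag["logistic"]
            (outdir / "logistic.json").write_text(
                json.dumps(
                    {"params": fit.params, "bse": fit.bse, "pvalues": fit.pvalues, "n": fit.n},
                    indent=2,
                )
            )
        report.update(
            auroc=diag["roc"].auroc,
            cutoff=cut.cutoff,
            sensitivity=cut.sensitivity,
            specificity=cut.specificity,
        )
    else:
        logger.info("diagnostics skipped: need both NASH and non-NASH animals")

    report["elapsed_s"] = time.perf_counter() - t_start
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
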