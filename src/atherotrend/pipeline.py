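"""End-to-end orchestration: simulate -> quantify -> fit -> summarize.

A single YAML-style config drives every stage; each run writes its
measurement table, posterior-draw archive, summary CSVs, convergence
report and a machine-readable manifest (seed, package versions, config
hash) so that any output is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortConfig, render_synthetic_images, simulate_cohort,
                     write_measurements, read_measurements,
                     MEASUREMENT_COLUMNS)
from .diagnostics import DEFAULT_ESS_MIN, DEFAULT_RHAT_MAX
from .estimator import LatentTrajectoryModel
from .imaging import ImageFrame, measure_signal_area
from .model import PriorSpec

logger = logging.getLogger("atherotrend")

DEFAULT_SUMMARY_WEEKS = (5, 8, 10)


@dataclass
class SamplerConfig:
    n_chains: int = 4
    n_draws: int = 1000
    n_warmup: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    prior: PriorSpec = field(default_factory=lambda: PriorSpec(
        data_rescale=100.0))
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    share_sigma_state: bool = True
    summary_weeks: Sequence[int] = DEFAULT_SUMMARY_WEEKS
    control: str = "HCD"
    ci_level: float = 0.89
    interval: str = "eti"
    rhat_max: float = DEFAULT_RHAT_MAX
    ess_min: float = DEFAULT_ESS_MIN
    data_csv: Optional[str] = None
    render_images: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["groups"] = list(self.cohort.groups)
        d["cohort"]["n_mice"] = [int(n) for n in self.cohort.n_mice]
        d["cohort"]["image_shape"] = (
            list(self.cohort.image_shape)
            if self.cohort.image_shape is not None else None)
        d["summary_weeks"] = [int(w) for w in self.summary_weeks]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        cohort_kw = dict(raw.pop("cohort", {}) or {})
        if cohort_kw.get("image_shape") is not None:
            cohort_kw["image_shape"] = tuple(cohort_kw["image_shape"])
        prior_kw = dict(raw.pop("prior", {}) or {})
        sampler_kw = dict(raw.pop("sampler", {}) or {})
        model_kw = dict(raw.pop("model", {}) or {})
        summary_kw = dict(raw.pop("summary", {}) or {})
        kw = dict(
            cohort=CohortConfig(**cohort_kw),
            prior=PriorSpec(**prior_kw),
            sampler=SamplerConfig(**sampler_kw),
        )
        if "share_sigma_state" in model_kw:
            kw["share_sigma_state"] = bool(model_kw["share_sigma_state"])
        if "weeks" in summary_kw:
            kw["summary_weeks"] = [int(w) for w in summary_kw["weeks"]]
        for key in ("control", "ci_level", "interval"):
            if key in summary_kw:
                kw[key] = summary_kw[key]
        for key in ("data_csv", "render_images", "rhat_max", "ess_min",
                    "share_sigma_state", "summary_weeks", "control",
                    "ci_level", "interval"):
            if key in raw and raw[key] is not None:
                kw[key] = raw[key]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self) -> str:
        d = self.to_dict()
        out = {
            "cohort": d["cohort"],
            "prior": d["prior"],
            "model": {"share_sigma_state": d["share_sigma_state"]},
            "sampler": d["sampler"],
            "summary": {"weeks": d["summary_weeks"],
                        "control": d["control"],
                        "ci_level": d["ci_level"],
                        "interval": d["interval"]},
            "rhat_max": d["rhat_max"],
            "ess_min": d["ess_min"],
            "data_csv": d["data_csv"],
            "render_images": d["render_images"],
        }
        return yaml.safe_dump(out, sort_keys=False)


def demo_config() -> RunConfig:
    """Bundled demonstration config: the four-diet study design with a
    sampler budget sized for a quick desk run."""
    return RunConfig(
        cohort=CohortConfig(seed=2024),
        prior=PriorSpec(data_rescale=100.0),
        sampler=SamplerConfig(n_chains=4, n_draws=5000, n_warmup=1000,
                              seed=7),
    )


def validate_measurements(table: pd.DataFrame,
                          groups: Optional[Sequence[str]] = None,
                          ) -> tuple[pd.DataFrame, dict]:
    """Schema and sanity checks on a long-format measurement table.

    Enforces the ``mouse_id,group,week,signal_area`` schema, non-negative
    areas, integer non-negative weeks, and uniqueness of (mouse, week);
    missing mouse-week cells are allowed (the likelihood simply skips
    them) and reported as gaps.  Returns the cleaned table (stable row
    order, canonical dtypes) and a report dict with per-cell counts.
    """
    missing_cols = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    t = table.loc[:, list(MEASUREMENT_COLUMNS)].copy()
    week_float = t["week"].astype(float)
    if not np.allclose(week_float, np.round(week_float)):
        raise ValueError("weeks must be integers")
    t["week"] = week_float.round().astype(int)
    if (t["week"] < 0).any():
        bad = t.index[t["week"] < 0].tolist()
        raise ValueError(f"negative week at rows {bad}")
    t["signal_area"] = t["signal_area"].astype(float)
    bad_area = t.index[~np.isfinite(t["signal_area"])
                       | (t["signal_area"] < 0)].tolist()
    if bad_area:
        raise ValueError(f"negative or non-finite signal_area at rows "
                         f"{bad_area}")
    dup = t.duplicated(subset=["mouse_id", "week"], keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate (mouse_id, week) at rows {t.index[dup].tolist()}")
    if groups is not None:
        unknown = sorted(set(t["group"]) - set(groups))
        if unknown:
            raise ValueError(f"unknown group label(s): {unknown}")

    cell_counts = (t.groupby(["group", "week"], sort=True)
                   .size().unstack(fill_value=0))
    mice_per_group = t.groupby("group")["mouse_id"].nunique().to_dict()
    weeks = sorted(t["week"].unique())
    gaps = []
    for (g, m), sub in t.groupby(["group", "mouse_id"], sort=True):
        missing_weeks = sorted(set(weeks) - set(sub["week"]))
        if missing_weeks:
            gaps.append({"group": g, "mouse_id": m, "weeks": missing_weeks})
    n_zero = int((t["signal_area"] == 0).sum())
    report = {
        "n_rows": int(len(t)),
        "groups": sorted(t["group"].unique()),
        "mice_per_group": mice_per_group,
        "weeks": [int(w) for w in weeks],
        "cells_per_group": {g: int((cell_counts.loc[g] > 0).sum())
                            for g in cell_counts.index},
        "cell_counts": {g: cell_counts.loc[g].to_dict()
                        for g in cell_counts.index},
        "gaps": gaps,
        "n_zero_area": n_zero,
    }
    return t, report


def _stage(name: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, extras)


def run_end_to_end(config: RunConfig, out_dir) -> dict:
    """Execute all pipeline stages and write the artifact set.

    Returns a dict of output paths.  Idempotent given the config seeds:
    rerunning into a fresh directory reproduces byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {}

    # -- data stage -------------------------------------------------------
    t0 = time.time()
    if config.data_csv is not None:
        table = read_measurements(config.data_csv)
        _stage("load", t0, path=config.data_csv, rows=len(table))
    else:
        truth, table = simulate_cohort(config.cohort)
        truth_df = pd.DataFrame(truth.A, columns=list(config.cohort.groups))
        truth_df.insert(0, "week", np.arange(config.cohort.n_weeks))
        truth_path = out / "latent_truth.csv"
        truth_df.to_csv(truth_path, index=False, float_format="%.10g")
        outputs["latent_truth"] = str(truth_path)
        _stage("simulate", t0, seed=config.cohort.seed, rows=len(table))

    if config.render_images:
        t0 = time.time()
        if config.cohort.image_shape is None:
            raise ValueError("render_images requires cohort.image_shape")
        image_set = render_synthetic_images(table, config.cohort)
        counts = [measure_signal_area(ImageFrame(
                      pixels=img, roi_mask=image_set.roi_mask,
                      scale_min=config.cohort.scale_min,
                      scale_max=config.cohort.scale_max))
                  for img in image_set.images]
        table = table.reset_index(drop=True).copy()
        table["signal_area"] = np.asarray(counts, dtype=float)
        _stage("quantify", t0, images=len(counts))

    meas_path = out / "measurements.csv"
    write_measurements(table, meas_path)
    outputs["measurements"] = str(meas_path)

    # -- validation (and control check, before any sampling) --------------
    t0 = time.time()
    table, report = validate_measurements(table)
    if config.control not in report["groups"]:
        raise ValueError(
            f"control group {config.control!r} not present in the data "
            f"(groups: {report['groups']})")
    bad_weeks = sorted(set(config.summary_weeks) - set(report["weeks"]))
    if bad_weeks:
        raise ValueError(f"summary weeks {bad_weeks} not observed "
                         f"(weeks: {report['weeks']})")
    fit_table = table[table["signal_area"] > 0]
    n_dropped = len(table) - len(fit_table)
    _stage("validate", t0, rows=report["n_rows"], dropped_zero=n_dropped)
    report_path = out / "validation.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    outputs["validation"] = str(report_path)

    # -- fit ---------------------------------------------------------------
    t0 = time.time()
    group_order = [config.control] + [
        g for g in config.cohort.groups if g != config.control
        and g in set(fit_table["group"])]
    group_order += [g for g in report["groups"] if g not in group_order]
    model = LatentTrajectoryModel(
        prior_sigma_obs_scale=config.prior.sigma_obs_scale,
        prior_sigma_state_scale=config.prior.sigma_state_scale,
        data_rescale=config.prior.data_rescale,
        share_sigma_state=config.share_sigma_state,
        n_chains=config.sampler.n_chains, n_draws=config.sampler.n_draws,
        n_warmup=config.sampler.n_warmup,
        random_state=config.sampler.seed, control=config.control,
        ci_level=config.ci_level, interval=config.interval,
        rhat_max=config.rhat_max, ess_min=config.ess_min)
    model.fit(fit_table, groups=group_order)
    _stage("fit", t0, seed=config.sampler.seed,
           chains=config.sampler.n_chains, draws=config.sampler.n_draws,
           accept="%.2f" % float(np.mean(
               model.draws_.meta["acceptance_rates"])))

    draws_path = out / "draws.npz"
    model.draws_.save(draws_path)
    outputs["draws"] = str(draws_path)

    conv = model.convergence_
    conv_path = out / "convergence.txt"
    conv_path.write_text(str(conv) + "\n")
    conv.table.to_csv(out / "convergence.csv", index=False,
                      float_format="%.6g")
    outputs["convergence"] = str(conv_path)
    logger.info("stage=convergence passed=%s rhat_max=%.4f ess_min=%.0f",
                conv.passed, conv.table["rhat"].max(),
                conv.table["ess"].min())

    # -- summaries ---------------------------------------------------------
    t0 = time.time()
    summary = model.summary(weeks=list(config.summary_weeks))
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.10g")
    outputs["summary"] = str(summary_path)
    trajectory = model.summary()
    traj_path = out / "trajectory.csv"
    trajectory.to_csv(traj_path, index=False, float_format="%.10g")
    outputs["trajectory"] = str(traj_path)
    _stage("summarize", t0, weeks=list(config.summary_weeks),
           control=config.control)

    # -- manifest ----------------------------------------------------------
    manifest = {
        "package": "atherotrend",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.config_hash(),
        "seeds": {"cohort": config.cohort.seed,
                  "sampler": config.sampler.seed},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "convergence_passed": bool(conv.passed),
        "outputs": sorted(Path(p).name for p in outputs.values()),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = str(manifest_path)
    return outputs
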