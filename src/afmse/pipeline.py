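"""End-to-end orchestration: simulate -> features -> cohort stats -> figures.

Stages communicate only through files in the run directory:

    <out>/config.lock          exact configuration used (YAML)
    <out>/sim/patient_XXX.csv  one beat-annotation CSV per patient
    <out>/sim/cohort.csv       covariates, follow-up and outcomes
    <out>/features/features.csv   per-patient feature table
    <out>/features/quarantine.csv patients whose extraction failed, with reason
    <out>/stats/summary.json   group tests, C-statistic, Cox, CV, log-rank
    <out>/figures/*.png        MSE profile and cumulative-hazard figures

Each stage records a content hash of its inputs; re-running a stage with
unchanged inputs and existing outputs is a no-op.  A failure in one
patient's feature extraction quarantines that patient (with the reason) and
the run continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import riskstats
from .features import FEATURE_COLUMNS, extract_features
from .mse import SampEnParams
from .preprocess import read_beats_csv, write_beats_csv
from .synthetic import SynthConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for a full synthetic-cohort analysis run."""

    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    sampen: SampEnParams = dataclasses.field(default_factory=SampEnParams)
    min_points: int = 200
    cv_folds: int = 4
    threshold_rule: str = "youden"
    stats_seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.synth, dict):
            self.synth = SynthConfig(**self.synth)
        if isinstance(self.sampen, dict):
            self.sampen = SampEnParams(**self.sampen)
        if self.min_points < 5:
            raise ValueError("min_points: must be at least 5")
        if self.cv_folds < 2:
            raise ValueError("cv_folds: must be at least 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_obj(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, Path):
            h.update(p.read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _stage_fresh(stage_dir: Path, input_hash: str) -> bool:
    mark = stage_dir / ".input_hash"
    return mark.exists() and mark.read_text() == input_hash


def _stage_done(stage_dir: Path, input_hash: str) -> None:
    (stage_dir / ".input_hash").write_text(input_hash)


def _simulate(config: PipelineConfig, sim_dir: Path) -> None:
    cohort = generate_cohort(
        config.synth, features="holter",
        sampen_params=config.sampen, min_points=config.min_points,
    )
    for pid, beats in cohort.beats.items():
        write_beats_csv(beats, sim_dir / f"patient_{pid:03d}.csv")
    cov_cols = ["patient_id", "age", "female", "chf", "hypertension", "diabetes",
                "stroke_tia", "vascular", "antithrombotic", "cha2ds2_vasc",
                "follow_up_months", "event"]
    cohort.table[cov_cols].to_csv(sim_dir / "cohort.csv", index=False,
                                  float_format="%.6f")


def _features(config: PipelineConfig, sim_dir: Path, feat_dir: Path) -> None:
    rows, quarantined = [], []
    for path in sorted(sim_dir.glob("patient_*.csv")):
        pid = int(path.stem.split("_")[1])
        try:
            beats = read_beats_csv(path)
            rec = extract_features(beats, sampen_params=config.sampen,
                                   min_points=config.min_points)
            rows.append({"patient_id": pid, **rec})
        except Exception as exc:  # quarantine, keep going
            log.warning("patient %d quarantined: %s", pid, exc)
            quarantined.append({"patient_id": pid, "reason": str(exc)})
    if not rows:
        raise RuntimeError("no patient could be analyzed")
    feats = pd.DataFrame(rows)[["patient_id"] + FEATURE_COLUMNS]
    feats.to_csv(feat_dir / "features.csv", index=False, float_format="%.10g")
    pd.DataFrame(quarantined, columns=["patient_id", "reason"]).to_csv(
        feat_dir / "quarantine.csv", index=False)


def _cohort_stats(config: PipelineConfig, sim_dir: Path, feat_dir: Path,
                  stats_dir: Path) -> dict:
    feats = pd.read_csv(feat_dir / "features.csv")
    cov = pd.read_csv(sim_dir / "cohort.csv")
    table = cov.merge(feats, on="patient_id")
    table.to_csv(stats_dir / "cohort_features.csv", index=False,
                 float_format="%.10g")

    out: dict = {"n": len(table), "n_events": int(table["event"].sum())}
    usable = table.dropna(subset=["mean_en_vlf2"])
    out["n_usable"] = len(usable)
    ev = usable["event"].astype(int)
    if 0 < ev.sum() < len(usable):
        cmp_ = riskstats.compare_groups(usable, "mean_en_vlf2")
        out["mean_en_vlf2_by_group"] = {
            "means": cmp_.means, "sds": cmp_.sds, "p": cmp_.p_value}
        out["c_statistic"] = dataclasses.asdict(
            riskstats.c_statistic(usable, "mean_en_vlf2"))
        if ev.sum() >= 2:
            try:
                cox = riskstats.cox_fit(
                    usable, "mean_en_vlf2",
                    adjusters=["age", "cha2ds2_vasc", "antithrombotic"])
                out["cox"] = dataclasses.asdict(cox)
            except Exception as exc:
                out["cox"] = {"error": str(exc)}
        try:
            ci = riskstats.cumulative_incidence(usable)
            out["logrank_p"] = ci.logrank_p
            out["group_sizes"] = ci.group_sizes
        except Exception as exc:
            out["logrank"] = {"error": str(exc)}
        if ev.sum() >= config.cv_folds and (1 - ev).sum() >= config.cv_folds:
            cv = riskstats.cross_validate(
                usable, "mean_en_vlf2", k=config.cv_folds,
                threshold_rule=config.threshold_rule, seed=config.stats_seed)
            out["cross_validation"] = {
                "sensitivity": cv.sensitivity, "specificity": cv.specificity,
                "k": cv.k}
    with open(stats_dir / "summary.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)
    return out


def _figures(stats_dir: Path, fig_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = pd.read_csv(stats_dir / "cohort_features.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    for flag, label, color in [(1, "event", "tab:blue"), (0, "no event", "tab:red")]:
        sub = table[table["event"] == flag]["mean_en_vlf2"].dropna()
        if len(sub):
            ax.errorbar([label], [sub.mean()], yerr=[sub.std(ddof=1) or 0],
                        fmt="o", color=color, capsize=4)
    ax.set_ylabel("MeanEn_VLF2")
    fig.tight_layout()
    fig.savefig(fig_dir / "mean_en_vlf2_by_group.png", dpi=120)
    plt.close(fig)

    try:
        ci = riskstats.cumulative_incidence(table.dropna(subset=["mean_en_vlf2"]))
        fig, ax = plt.subplots(figsize=(5, 4))
        for g, curve in ci.curves.items():
            ax.step(curve.index, curve.iloc[:, 0], where="post", label=str(g))
        ax.set_xlabel("follow-up (months)")
        ax.set_ylabel("cumulative hazard")
        ax.legend(title="MeanEn_VLF2")
        fig.tight_layout()
        fig.savefig(fig_dir / "nelson_aalen.png", dpi=120)
        plt.close(fig)
    except Exception as exc:
        log.warning("skipping survival figure: %s", exc)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run all stages into ``out_dir``; returns the run directory.

    Stages are skipped when their recorded input hash matches (no-op re-run);
    outputs of one stage are never mutated by another.
    """
    out = Path(out_dir)
    sim_dir, feat_dir = out / "sim", out / "features"
    stats_dir, fig_dir = out / "stats", out / "figures"
    for d in (out, sim_dir, feat_dir, stats_dir, fig_dir):
        d.mkdir(parents=True, exist_ok=True)

    with open(out / "config.lock", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    h_sim = _hash_obj(config.to_dict())
    if not _stage_fresh(sim_dir, h_sim):
        log.info("stage simulate: %d patients", config.synth.n_patients)
        _simulate(config, sim_dir)
        _stage_done(sim_dir, h_sim)
    else:
        log.info("stage simulate: up to date")

    h_feat = _hash_obj(h_sim, *sorted(sim_dir.glob("patient_*.csv")))
    if not _stage_fresh(feat_dir, h_feat):
        log.info("stage features")
        _features(config, sim_dir, feat_dir)
        _stage_done(feat_dir, h_feat)
    else:
        log.info("stage features: up to date")

    h_stats = _hash_obj(h_feat, feat_dir / "features.csv")
    if not _stage_fresh(stats_dir, h_stats):
        log.info("stage cohort-stats")
        _cohort_stats(config, sim_dir, feat_dir, stats_dir)
        _stage_done(stats_dir, h_stats)
    else:
        log.info("stage cohort-stats: up to date")

    if config.make_figures:
        h_fig = _hash_obj(h_stats, stats_dir / "cohort_features.csv")
        if not _stage_fresh(fig_dir, h_fig):
            log.info("stage figures")
            _figures(stats_dir, fig_dir)
            _stage_done(fig_dir, h_fig)
    return out
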