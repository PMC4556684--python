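"""Synthetic AF-like VRI series and outcome-coupled cohorts.

The ventricular response of permanent atrial fibrillation has a
characteristic two-regime power spectrum: approximately 1/f^beta at low
frequencies (periods longer than a crossover of roughly 200 s) and flat,
white-noise-like power above the crossover.  :func:`generate_vri_series`
builds interval series with exactly that structure by spectral synthesis:
Gaussian random-phase Fourier coefficients whose squared amplitude is

    |X(f)|^2  ∝  w  +  (1 - w) * esf^2 * max((f/f_c)^(-beta) - 1, 0)

with ``w = white_fraction``, crossover frequency ``f_c = 1/crossover_period_s``
and per-patient ``esf = entropy_scale_factor`` scaling only the sub-crossover
(long-time-scale) excess, so long-scale irregularity varies across patients
while the short-scale behaviour stays AF-like.  ``w = 1`` gives pure white
noise; ``w = 0`` with a sub-second crossover gives pure 1/f^beta noise.  The
inverse transform is rescaled to the target interval SD, shifted to the
target mean, and clipped to the physiological range [200, 3000] ms (the
clipped fraction is tracked and expected below 0.1%).

:func:`generate_cohort` wraps this in a study-like cohort: per-patient
clinical covariates, a long-scale entropy level, and ischemic-stroke
follow-up drawn from an exponential proportional-hazards model whose
per-1-SD log hazard ratio on MeanEn_VLF2 is a configuration knob.  Features
can be drawn parametrically (fast, for statistical studies) or computed from
fully generated Holter recordings.  A single global seed expands to
independent per-patient substreams via ``numpy.random.SeedSequence`` spawn
keys, so cohorts are reproducible regardless of generation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import extract_features
from .mse import SampEnParams
from .preprocess import BeatSeries
from .riskstats import cha2ds2_vasc

__all__ = ["CovariateMix", "SynthConfig", "SyntheticCohort",
           "generate_vri_series", "generate_cohort"]

log = logging.getLogger(__name__)

CLIP_MS = (200.0, 3000.0)
MAX_CLIP_FRACTION = 1e-3


@dataclass
class CovariateMix:
    """Marginal distributions of the clinical covariates (study-like defaults)."""

    age_mean: float = 69.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (30.0, 89.0)
    p_female: float = 0.29
    p_chf: float = 0.38
    p_hypertension: float = 0.60
    p_diabetes: float = 0.09
    p_stroke_tia: float = 0.28
    p_vascular: float = 0.10
    p_antithrombotic: float = 0.63


@dataclass
class SynthConfig:
    """All generator knobs; identical seed + config gives bit-identical output.

    Series knobs: 24-h recordings with mean VRI 811 ms / SD 230 ms, a 1/f
    spectrum below the 200-s crossover period and white-noise-like power
    above it.  Cohort knobs: hazard model per-1-SD log HR on MeanEn_VLF2
    (default ln 1.80), baseline annualized event rate 5.8%, administrative
    horizon 96 months with exponential censoring averaging 60 months, and a
    Normal(0.60, 0.14) patient-level MeanEn_VLF2 distribution.
    """

    # --- single-series knobs -------------------------------------------------
    duration_h: float = 24.0
    mean_vri_ms: float = 811.0
    sd_vri_ms: float = 230.0
    spectral_exponent_beta: float = 1.0
    crossover_period_s: float = 200.0
    white_fraction: float = 0.68
    entropy_scale_factor: float = 1.0
    ve_fraction: float = 0.0
    start_clock: str = "09:00:00"
    seed: int = 0
    # --- cohort knobs --------------------------------------------------------
    n_patients: int = 173
    log_hr_per_sd: float = math.log(1.80)
    baseline_annual_rate: float = 0.058
    censor_months_mean: float = 60.0
    admin_horizon_months: float = 96.0
    mean_en_mu: float = 0.60
    mean_en_sd: float = 0.14
    entropy_scale_sigma: float = 0.35
    covariate_mix: CovariateMix = field(default_factory=CovariateMix)

    def __post_init__(self) -> None:
        if isinstance(self.covariate_mix, dict):
            self.covariate_mix = CovariateMix(**self.covariate_mix)
        if not self.duration_h > 0:
            raise ValueError("duration_h must be positive")
        if not self.sd_vri_ms > 0:
            raise ValueError("sd_vri_ms must be positive")
        if not 0.0 <= self.white_fraction <= 1.0:
            raise ValueError("white_fraction must lie in [0, 1]")
        if not self.crossover_period_s > 0:
            raise ValueError("crossover_period_s must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """Per-patient covariates, features and outcomes, plus optional beat streams."""

    table: pd.DataFrame
    beats: dict[int, BeatSeries] = field(default_factory=dict)
    config: SynthConfig | None = None

    def __len__(self) -> int:
        return len(self.table)


def _patient_rng(seed: int, patient: int, stream: int = 0) -> np.random.Generator:
    # counter-based substream: (patient, stream) spawn key off the global seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(patient, stream))
    )


def generate_vri_series(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> BeatSeries:
    """Generate one AF-like beat stream by two-regime spectral synthesis."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean_s = config.mean_vri_ms / 1000.0
    n_int = int(round(config.duration_h * 3600.0 / mean_s))
    if n_int < 2:
        raise ValueError("duration too short for the requested mean interval")

    freqs = np.fft.rfftfreq(n_int, d=mean_s)
    f_c = 1.0 / config.crossover_period_s
    w = config.white_fraction
    amp2 = np.full_like(freqs, w)
    low = (freqs > 0) & (freqs < f_c)
    amp2[low] += (
        (1.0 - w)
        * config.entropy_scale_factor**2
        * ((freqs[low] / f_c) ** (-config.spectral_exponent_beta) - 1.0)
    )
    amp = np.sqrt(amp2)
    amp[0] = 0.0  # zero-mean fluctuation; mean added back below

    coef = amp * (rng.standard_normal(len(amp)) + 1j * rng.standard_normal(len(amp)))
    x = np.fft.irfft(coef, n=n_int)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate spectral configuration (no power)")
    intervals_ms = config.mean_vri_ms + x * (config.sd_vri_ms / sd)

    clipped = (intervals_ms < CLIP_MS[0]) | (intervals_ms > CLIP_MS[1])
    frac = clipped.mean()
    if frac > 0:
        log.info("clipped %.4f%% of intervals to [%g, %g] ms", 100 * frac, *CLIP_MS)
    if frac > MAX_CLIP_FRACTION:
        log.warning("clipping fraction %.3f%% exceeds %.3f%%",
                    100 * frac, 100 * MAX_CLIP_FRACTION)
    intervals_ms = np.clip(intervals_ms, *CLIP_MS)

    onsets = np.concatenate(([0.0], np.cumsum(intervals_ms) / 1000.0))
    labels = np.full(len(onsets), "N", dtype="U1")
    if config.ve_fraction > 0:
        n_ve = int(round(config.ve_fraction * len(onsets)))
        labels[rng.choice(len(onsets), size=n_ve, replace=False)] = "V"
    return BeatSeries(onsets_s=onsets, labels=labels, start_clock=config.start_clock)


def _draw_covariates(rng: np.random.Generator, mix: CovariateMix) -> dict:
    age = float(np.clip(rng.normal(mix.age_mean, mix.age_sd), *mix.age_range))
    cov = {
        "age": age,
        "female": int(rng.random() < mix.p_female),
        "chf": int(rng.random() < mix.p_chf),
        "hypertension": int(rng.random() < mix.p_hypertension),
        "diabetes": int(rng.random() < mix.p_diabetes),
        "stroke_tia": int(rng.random() < mix.p_stroke_tia),
        "vascular": int(rng.random() < mix.p_vascular),
        "antithrombotic": int(rng.random() < mix.p_antithrombotic),
    }
    cov["cha2ds2_vasc"] = cha2ds2_vasc(
        age=age, female=bool(cov["female"]), chf=bool(cov["chf"]),
        hypertension=bool(cov["hypertension"]), diabetes=bool(cov["diabetes"]),
        stroke_tia=bool(cov["stroke_tia"]), vascular=bool(cov["vascular"]),
    )
    return cov


def generate_cohort(
    config: SynthConfig,
    features: str = "parametric",
    sampen_params: SampEnParams | None = None,
    min_points: int | None = None,
) -> SyntheticCohort:
    """Generate an outcome-coupled synthetic cohort.

    ``features="parametric"`` draws each patient's MeanEn_VLF2 from
    Normal(``mean_en_mu``, ``mean_en_sd``) directly — the fast path for
    statistical studies.  ``features="holter"`` generates a full beat stream
    per patient (with a log-normal per-patient ``entropy_scale_factor``,
    sigma ``entropy_scale_sigma``) and computes all features through the
    analysis pipeline; beat streams are kept on the cohort object.

    Stroke follow-up: event times are exponential with monthly rate
    ``baseline_annual_rate/12 * exp(log_hr_per_sd * z)`` where ``z`` is the
    within-cohort standardized MeanEn_VLF2; censoring is the minimum of an
    independent exponential (mean ``censor_months_mean``) and the
    administrative horizon.
    """
    if config.n_patients < 2:
        raise ValueError("need at least 2 patients")
    if features not in {"parametric", "holter"}:
        raise ValueError("features must be 'parametric' or 'holter'")

    rows = []
    beats_by_id: dict[int, BeatSeries] = {}
    for pid in range(config.n_patients):
        rng_cov = _patient_rng(config.seed, pid, stream=0)
        row = {"patient_id": pid, **_draw_covariates(rng_cov, config.covariate_mix)}
        if features == "parametric":
            row["mean_en_vlf2"] = float(
                rng_cov.normal(config.mean_en_mu, config.mean_en_sd)
            )
        else:
            rng_ser = _patient_rng(config.seed, pid, stream=1)
            esf = float(np.exp(rng_ser.normal(0.0, config.entropy_scale_sigma)))
            pcfg = SynthConfig(**{**config.to_dict(), "entropy_scale_factor": esf})
            beats = generate_vri_series(pcfg, rng=rng_ser)
            beats_by_id[pid] = beats
            rec = extract_features(
                beats, sampen_params=sampen_params,
                min_points=min_points if min_points is not None else 200,
            )
            row.update(rec)
            row["entropy_scale_factor"] = esf
        rows.append(row)
    table = pd.DataFrame(rows)

    me = table["mean_en_vlf2"].to_numpy(dtype=float)
    sd = np.nanstd(me)
    z = (me - np.nanmean(me)) / sd if sd > 0 else np.zeros_like(me)
    z = np.nan_to_num(z)

    monthly_rate = config.baseline_annual_rate / 12.0
    follow, event = np.empty(len(table)), np.empty(len(table), dtype=int)
    for pid in range(config.n_patients):
        rng_out = _patient_rng(config.seed, pid, stream=2)
        lam = monthly_rate * math.exp(config.log_hr_per_sd * z[pid])
        t_event = rng_out.exponential(1.0 / lam)
        t_cens = min(rng_out.exponential(config.censor_months_mean),
                     config.admin_horizon_months)
        follow[pid] = max(min(t_event, t_cens), 1e-6)
        event[pid] = int(t_event <= t_cens)
    table["follow_up_months"] = follow
    table["event"] = event
    return SyntheticCohort(table=table, beats=beats_by_id, config=config)
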