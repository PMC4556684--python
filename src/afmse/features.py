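"""Per-recording feature extraction: one beat stream in, one flat record out.

Combines the preprocessing, MSE and conventional-HRV stages into a single
record holding every Holter-derived feature used downstream (MeanEn/SlopeEn
per band, time- and frequency-domain measures, scattering index) plus the
eligibility screen.
"""

from __future__ import annotations

import numpy as np

from . import hrv as hrv_mod
from . import mse as mse_mod
from .preprocess import BeatSeries, build_vri, check_eligibility, resample_uniform

__all__ = ["extract_features", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = [
    "mean_vri_ms", "sdvri_ms", "sdavri_ms", "n_ve",
    "ulf_ln", "vlf_ln", "lf_ln", "hf_ln", "scattering_index",
    "mean_en_hf", "mean_en_lf", "mean_en_vlf", "mean_en_vlf1", "mean_en_vlf2",
    "slope_en_hf", "slope_en_lf", "slope_en_vlf", "slope_en_vlf1", "slope_en_vlf2",
    "duration_h", "ve_fraction", "artifact_fraction", "eligible",
]


def extract_features(
    beats: BeatSeries,
    sampen_params: mse_mod.SampEnParams | None = None,
    min_points: int = mse_mod.DEFAULT_MIN_POINTS,
    ve_policy: str = "drop",
) -> dict:
    """All HRV and MSE features of one recording as a flat dict.

    ``min_points`` is the minimum coarse-grained length for an MSE scale to
    be defined; short (sub-24-h) recordings leave long-scale bands NaN.
    Eligibility is reported in the record, never enforced.
    """
    vri = build_vri(beats, ve_policy=ve_policy)
    report = check_eligibility(vri)
    u = resample_uniform(vri)

    feats = hrv_mod.hrv_features(vri, u)
    profile = mse_mod.mse_profile(u, params=sampen_params, min_points=min_points)

    rec: dict = {
        "mean_vri_ms": feats.mean_vri_ms,
        "sdvri_ms": feats.sdvri_ms,
        "sdavri_ms": feats.sdavri_ms,
        "n_ve": feats.n_ve,
        "ulf_ln": feats.ulf_ln if feats.ulf_defined else np.nan,
        "vlf_ln": feats.vlf_ln,
        "lf_ln": feats.lf_ln,
        "hf_ln": feats.hf_ln,
        "scattering_index": feats.scattering_index,
        "duration_h": vri.duration_h,
        "ve_fraction": vri.ve_fraction,
        "artifact_fraction": vri.artifact_fraction,
        "eligible": report.eligible,
    }
    for band in mse_mod.BANDS:
        summ = mse_mod.band_summary(profile, band)
        rec[f"mean_en_{band.lower()}"] = summ.mean_en
        rec[f"slope_en_{band.lower()}"] = summ.slope_en
    return rec
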