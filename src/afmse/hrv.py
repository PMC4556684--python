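"""Conventional time- and frequency-domain VRI variability measures.

Time domain: mean VRI, SDVRI (SD of all intervals) and SDAVRI (SD of the
5-minute window averages).  Frequency domain: ULF (<0.0033 Hz), VLF
(0.0033–0.04 Hz), LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) band powers of the
2 Hz resampled signal, reported as ln(ms^2).  The Lorenz-plot scattering
index — a dispersion measure of the lag-1 return map used as a proxy for
AV-nodal concealed conduction — is implemented as the root of the mean of
the two principal-axis variances of the (VRI_n, VRI_{n+1}) point cloud; the
literature does not fix a single formula, so the definition is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import UniformSeries, VRISeries

__all__ = [
    "FREQ_BANDS",
    "HRVFeatures",
    "time_domain",
    "spectral_powers",
    "scattering_index",
    "hrv_features",
]

#: Frequency bands in Hz (lo, hi); ULF lower edge is the DC-exclusive origin.
FREQ_BANDS: dict[str, tuple[float, float]] = {
    "ULF": (0.0, 0.0033),
    "VLF": (0.0033, 0.04),
    "LF": (0.04, 0.15),
    "HF": (0.15, 0.4),
}

WELCH_SEGMENT_S = 1024.0  # Hann-windowed, 50% overlap, for VLF/LF/HF
SDAVRI_WINDOW_S = 300.0
SDAVRI_MIN_COVERAGE_S = 30.0
ULF_MIN_DURATION_H = 22.0


@dataclass
class HRVFeatures:
    mean_vri_ms: float
    sdvri_ms: float
    sdavri_ms: float
    n_ve: int
    ulf_ln: float
    vlf_ln: float
    lf_ln: float
    hf_ln: float
    scattering_index: float
    ulf_defined: bool = True


def time_domain(vri: VRISeries) -> tuple[float, float, float]:
    """Mean VRI, SDVRI and SDAVRI in ms.

    SDAVRI is the SD over non-overlapping 5-minute window means, windows
    anchored at the first interval onset; windows covering less than 30 s of
    interval time are dropped.
    """
    if len(vri) == 0:
        raise ValueError("empty VRI series")
    x = vri.interval_ms
    mean_vri = float(np.mean(x))
    sdvri = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    idx = np.floor((vri.onset_s - vri.onset_s[0]) / SDAVRI_WINDOW_S).astype(int)
    means = []
    for w in np.unique(idx):
        sel = idx == w
        if x[sel].sum() / 1000.0 >= SDAVRI_MIN_COVERAGE_S:
            means.append(x[sel].mean())
    sdavri = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return mean_vri, sdvri, sdavri


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    sel = (freqs > lo) & (freqs <= hi)
    if not sel.any():
        return 0.0
    df = freqs[1] - freqs[0]
    return float(psd[sel].sum() * df)


def spectral_powers(
    u: UniformSeries,
) -> tuple[float, float, float, float, dict[str, bool]]:
    """Band powers (ln ms^2) of the resampled VRI signal.

    VLF/LF/HF are integrated from a Welch estimate (1024-s Hann segments,
    50% overlap, linear detrend); ULF from a single full-length linearly
    detrended periodogram, since Welch segments cannot resolve it.  Bands the
    record is too short to resolve (less than two cycles of the band's
    longest period; 22 h for ULF) are flagged undefined.

    Returns ``(ulf_ln, vlf_ln, lf_ln, hf_ln, defined_flags)``.
    """
    x = u.values_ms
    fs = u.rate_hz
    duration_s = (len(x) - 1) / fs

    nper = min(int(WELCH_SEGMENT_S * fs), len(x))
    f_w, p_w = signal.welch(x, fs=fs, window="hann", nperseg=nper,
                            noverlap=nper // 2, detrend="linear")
    f_p, p_p = signal.periodogram(x, fs=fs, detrend="linear")

    defined = {}
    powers = {}
    for band, (lo, hi) in FREQ_BANDS.items():
        if band == "ULF":
            powers[band] = _band_power(f_p, p_p, lo, hi)
            defined[band] = duration_s >= ULF_MIN_DURATION_H * 3600.0
        else:
            powers[band] = _band_power(f_w, p_w, lo, hi)
            defined[band] = duration_s >= 2.0 / lo
    ln = {b: float(np.log(p)) if p > 0 else float("-inf") for b, p in powers.items()}
    return ln["ULF"], ln["VLF"], ln["LF"], ln["HF"], defined


def scattering_index(vri: VRISeries, min_points: int = 100) -> float:
    """Dispersion of the Lorenz (lag-1 return) plot of the VRIs, in ms.

    Computed as sqrt of the mean of the eigenvalues of the 2x2 covariance of
    the (VRI_n, VRI_{n+1}) cloud — i.e. the RMS principal-axis SD.  For i.i.d.
    intervals with SD sigma this converges to sigma.  Invariant under time
    reversal (the covariance of the reversed cloud is the transpose).
    """
    x = vri.interval_ms
    if len(x) < min_points + 1:
        raise ValueError(f"need at least {min_points + 1} intervals")
    cloud = np.stack([x[:-1], x[1:]])
    cov = np.cov(cloud)
    eig = np.linalg.eigvalsh(cov)
    return float(np.sqrt(np.mean(eig)))


def hrv_features(vri: VRISeries, u: UniformSeries) -> HRVFeatures:
    """All conventional HRV measures for one recording."""
    mean_vri, sdvri, sdavri = time_domain(vri)
    ulf, vlf, lf, hf, defined = spectral_powers(u)
    return HRVFeatures(
        mean_vri_ms=mean_vri,
        sdvri_ms=sdvri,
        sdavri_ms=sdavri,
        n_ve=vri.n_ve,
        ulf_ln=ulf,
        vlf_ln=vlf,
        lf_ln=lf,
        hf_ln=hf,
        scattering_index=scattering_index(vri),
        ulf_defined=defined["ULF"],
    )
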