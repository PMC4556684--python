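"""Time-scale-based multiscale entropy (MSE) of the 2 Hz VRI signal.

Multiscale entropy characterises the irregularity of a time series across
temporal scales in two steps: (1) coarse-graining — replacing the series with
non-overlapping block averages of length ``tau`` — and (2) sample entropy of
each coarse-grained series.  Because the input is resampled at a fixed 2 Hz,
scales are expressed in *seconds* rather than beats, which lets the entropy
bands line up with the conventional HRV frequency bands:

=====  ============  =========================
band   scale range   matching frequency band
=====  ============  =========================
HF     2.5–6.5 s     high frequency
LF     6.5–25 s      low frequency
VLF    25–300 s      very low frequency
VLF1   25–90 s       VLF short-scale subrange
VLF2   90–300 s      VLF long-scale subrange
=====  ============  =========================

Each band is summarised by the mean entropy (MeanEn) and the ordinary
least-squares slope of entropy against log10(scale in seconds) (SlopeEn).
Note the sign convention: entropy is regressed on log10 *scale*; against
log10 *frequency* the slope would be negated.

Sample entropy follows the standard definition: with pattern length ``m``
(default 2) and tolerance ``r`` (default 0.15, as a fraction of a reference
SD), SampEn = −ln(A/B), where B counts template pairs within tolerance
(Chebyshev distance, strict ``<``, self-matches excluded) at length ``m`` and
A at length ``m+1``.  By default the tolerance is fixed once from the SD of
the scale-1 (uncoarse-grained) series and held constant across scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._sampen import match_counts
from .preprocess import UniformSeries

__all__ = [
    "BANDS",
    "SampEnParams",
    "SampEnResult",
    "MSEProfile",
    "BandSummary",
    "coarse_grain",
    "sample_entropy",
    "default_scale_grid",
    "mse_profile",
    "band_summary",
]

#: Scale bands in seconds, closed on both ends.
BANDS: dict[str, tuple[float, float]] = {
    "HF": (2.5, 6.5),
    "LF": (6.5, 25.0),
    "VLF": (25.0, 300.0),
    "VLF1": (25.0, 90.0),
    "VLF2": (90.0, 300.0),
}

#: Minimum coarse-grained length for a scale's entropy to count as defined.
DEFAULT_MIN_POINTS = 200


@dataclass
class SampEnParams:
    """Sample-entropy parameters.

    m : pattern length (default 2).
    r : similarity tolerance as a fraction of the reference SD (default 0.15).
    r_reference : which SD normalises ``r`` — ``"scale1"`` (default) fixes the
        tolerance from the scale-1 resampled series and holds it across all
        scales; ``"per_scale"`` re-normalises to each coarse-grained series.
    """

    m: int = 2
    r: float = 0.15
    r_reference: str = "scale1"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("pattern length m must be >= 1")
        if not self.r > 0:
            raise ValueError("similarity factor r must be positive")
        if self.r_reference not in {"scale1", "per_scale"}:
            raise ValueError("r_reference must be 'scale1' or 'per_scale'")


@dataclass
class SampEnResult:
    value: float
    a_count: int
    b_count: int
    defined: bool


@dataclass
class MSEProfile:
    """Sample entropy as a function of time scale (seconds)."""

    scales_s: np.ndarray
    sampen: np.ndarray
    n_points: np.ndarray
    undefined_mask: np.ndarray
    params: SampEnParams = field(default_factory=SampEnParams)
    tolerance_ms: float = float("nan")

    def defined(self) -> np.ndarray:
        return ~self.undefined_mask


@dataclass
class BandSummary:
    """MeanEn / SlopeEn summary of an MSE profile over one scale band."""

    band: str
    lo_s: float
    hi_s: float
    mean_en: float
    slope_en: float
    n_scales: int
    defined: bool


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of ``tau`` consecutive samples.

    The trailing partial block is discarded; ``tau=1`` returns a copy.
    """
    x = np.asarray(x, dtype=float)
    if tau < 1 or tau != int(tau):
        raise ValueError("tau must be a positive integer")
    tau = int(tau)
    n = len(x) // tau
    if n == 0:
        raise ValueError(f"series of length {len(x)} shorter than tau={tau}")
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(
    x: np.ndarray,
    m: int = 2,
    tolerance: float | None = None,
    r: float = 0.15,
) -> SampEnResult:
    """Sample entropy −ln(A/B) with an explicit or SD-relative tolerance.

    If ``tolerance`` is given it is used as the absolute Chebyshev tolerance
    (same units as ``x``); otherwise it is ``r`` times the SD of ``x``.
    When no template pair matches at either length the entropy is undefined
    and flagged rather than returned as infinity.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 2:
        raise ValueError(f"series too short for m={m}")
    if tolerance is None:
        sd = float(np.std(x))
        if sd == 0:
            raise ValueError("zero-variance series with SD-relative tolerance")
        tolerance = r * sd
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    a, b = match_counts(x, m, float(tolerance))
    if a == 0 or b == 0:
        return SampEnResult(value=float("nan"), a_count=a, b_count=b, defined=False)
    return SampEnResult(value=-math.log(a / b), a_count=a, b_count=b, defined=True)


def default_scale_grid(
    lo_s: float = 2.5,
    hi_s: float = 300.0,
    per_decade: int = 20,
    rate_hz: float = 2.0,
) -> np.ndarray:
    """Log-spaced scale grid snapped to integer coarse-graining factors.

    Scales are laid out with ``per_decade`` points per decade of seconds over
    ``[lo_s, hi_s]``, each rounded to an integer number of samples at
    ``rate_hz``, duplicates removed.  Returned in seconds.
    """
    n = int(np.floor((np.log10(hi_s) - np.log10(lo_s)) * per_decade)) + 1
    raw = 10 ** (np.log10(lo_s) + np.arange(n) / per_decade)
    raw = np.append(raw, hi_s)  # both band edges always on the grid
    taus = np.unique(np.round(raw * rate_hz).astype(int))
    taus = taus[taus >= 1]
    return taus / rate_hz


def mse_profile(
    u: UniformSeries,
    params: SampEnParams | None = None,
    scale_grid_s: np.ndarray | None = None,
    min_points: int = DEFAULT_MIN_POINTS,
) -> MSEProfile:
    """Compute the MSE profile of a uniformly resampled VRI signal.

    Each scale ``s`` maps to the integer coarse-graining factor
    ``tau = round(s * rate_hz)``.  With the default ``r_reference="scale1"``
    the match tolerance is ``r`` times the SD of the full-resolution series,
    held fixed across scales.  Scales whose coarse-grained series is shorter
    than ``min_points``, or whose entropy is undefined (no template matches),
    are flagged in ``undefined_mask``.
    """
    params = params or SampEnParams()
    if scale_grid_s is None:
        scale_grid_s = default_scale_grid(rate_hz=u.rate_hz)
    scale_grid_s = np.asarray(scale_grid_s, dtype=float)
    if scale_grid_s.size == 0:
        raise ValueError("empty scale grid")
    if not np.all(np.diff(scale_grid_s) > 0):
        raise ValueError("scale grid must be strictly increasing")

    x = u.values_ms
    sd1 = float(np.std(x))
    tol_fixed = params.r * sd1 if sd1 > 0 else float("nan")

    n_scales = len(scale_grid_s)
    sampen = np.full(n_scales, np.nan)
    n_points = np.zeros(n_scales, dtype=int)
    undefined = np.ones(n_scales, dtype=bool)

    for i, s in enumerate(scale_grid_s):
        tau = int(round(s * u.rate_hz))
        if tau < 1 or len(x) // max(tau, 1) < max(min_points, params.m + 2):
            continue
        cg = coarse_grain(x, tau)
        n_points[i] = len(cg)
        if params.r_reference == "scale1":
            if not tol_fixed > 0:
                continue  # constant series: every scale degenerate
            tol = tol_fixed
        else:
            sd = float(np.std(cg))
            if sd == 0:
                continue
            tol = params.r * sd
        res = sample_entropy(cg, m=params.m, tolerance=tol)
        if res.defined:
            sampen[i] = res.value
            undefined[i] = False

    return MSEProfile(
        scales_s=scale_grid_s,
        sampen=sampen,
        n_points=n_points,
        undefined_mask=undefined,
        params=params,
        tolerance_ms=tol_fixed,
    )


def band_summary(profile: MSEProfile, band: str | tuple[float, float]) -> BandSummary:
    """MeanEn and SlopeEn of a profile over one scale band (closed ends).

    ``band`` is a named band from :data:`BANDS` or an explicit ``(lo, hi)``
    pair in seconds.  MeanEn is the unweighted mean of the defined entropy
    values over grid scales inside the band; SlopeEn the OLS slope of entropy
    against log10(scale in seconds).  Fewer than two defined scales yields an
    undefined (NaN) summary.
    """
    if isinstance(band, str):
        name = band
        lo, hi = BANDS[band]
    else:
        lo, hi = band
        name = f"{lo:g}-{hi:g}s"
    mask = (profile.scales_s >= lo) & (profile.scales_s <= hi) & profile.defined()
    n = int(mask.sum())
    if n < 2:
        return BandSummary(name, lo, hi, float("nan"), float("nan"), n, False)
    s = np.log10(profile.scales_s[mask])
    y = profile.sampen[mask]
    slope = float(np.polyfit(s, y, 1)[0])
    return BandSummary(name, lo, hi, float(np.mean(y)), slope, n, True)
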