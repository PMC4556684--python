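import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afmse.mse import (
    BANDS,
    MSEProfile,
    SampEnParams,
    band_summary,
    coarse_grain,
    default_scale_grid,
    mse_profile,
    sample_entropy,
)
from afmse.preprocess import UniformSeries

from conftest import naive_sampen_counts, naive_sampen_counts_loops


class TestCoarseGrain:
    @pytest.mark.parametrize("x, tau, expected", [
        ([1, 2, 3, 4], 2, [1.5, 3.5]),
        ([1, 2, 3, 4, 5], 2, [1.5, 3.5]),      # trailing sample discarded
        ([1, 5, 3], 1, [1, 5, 3]),             # identity
        ([1, 2, 3, 4, 5, 6], 3, [2.0, 5.0]),
    ])
    def test_block_means(self, x, tau, expected):
        np.testing.assert_allclose(coarse_grain(np.array(x, float), tau), expected)

    def test_mean_conserved_when_divisible(self, rng):
        x = rng.normal(size=120)
        for tau in (2, 3, 4, 5, 6):
            assert coarse_grain(x, tau).mean() == pytest.approx(x.mean())

    def test_tau_larger_than_series_raises(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(4.0), 5)


class TestSampleEntropy:
    def test_periodic_series_has_zero_entropy(self):
        x = np.tile([1.0, 2.0], 50)
        res = sample_entropy(x, m=2, r=0.15)
        assert res.defined and res.value == 0.0

    def test_matches_pure_python_oracle_on_tiny_series(self, rng):
        x = rng.normal(size=10)
        tol = 0.3 * np.std(x)
        res = sample_entropy(x, m=2, tolerance=tol)
        a, b = naive_sampen_counts_loops(x, 2, tol)
        assert (res.a_count, res.b_count) == (a, b)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_exact_count_equality_with_naive_oracle(self, m, rng):
        for n in (30, 100, 400):
            x = rng.normal(size=n)
            tol = 0.2 * np.std(x)
            res = sample_entropy(x, m=m, tolerance=tol)
            a, b = naive_sampen_counts(x, m, tol)
            assert (res.a_count, res.b_count) == (a, b)

    def test_gaussian_white_noise_matches_analytic_limit(self, rng):
        # i.i.d. Gaussian: SampEn -> -ln(erf(r/2)); moderate n, generous MC band
        x = rng.standard_normal(20_000)
        res = sample_entropy(x, m=2, r=0.15)
        assert res.value == pytest.approx(-math.log(math.erf(0.075)), abs=0.02)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1),
           st.floats(0.25, 4.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, seed, a, b):
        # x -> a*x + b leaves SampEn unchanged when tolerance tracks the SD
        x = np.random.default_rng(seed).normal(size=300)
        r1 = sample_entropy(x, m=2, r=0.2)
        r2 = sample_entropy(a * x + b, m=2, r=0.2)
        assert (r1.a_count, r1.b_count) == (r2.a_count, r2.b_count)

    def test_no_matches_flagged_undefined_not_infinite(self):
        x = np.arange(20.0) ** 2  # strictly accelerating: no template matches
        res = sample_entropy(x, m=2, tolerance=1e-9)
        assert not res.defined and math.isnan(res.value)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), m=2, tolerance=0.1)

    def test_zero_tolerance_raises(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(50), m=2, tolerance=0.0)


class TestScaleGrid:
    def test_grid_is_strictly_increasing_integer_tau(self):
        grid = default_scale_grid()
        taus = grid * 2.0
        assert np.all(np.diff(grid) > 0)
        np.testing.assert_allclose(taus, np.round(taus))
        assert grid[0] == 2.5 and grid[-1] == 300.0


class TestMseProfile:
    def test_white_noise_profile_decreases_with_scale(self, rng):
        # fixed-tolerance convention: coarse-graining shrinks the SD ~ 1/sqrt(tau)
        u = UniformSeries(values_ms=rng.normal(800, 100, 40_000))
        prof = mse_profile(u, scale_grid_s=default_scale_grid(hi_s=30.0),
                           min_points=100)
        vals = prof.sampen[prof.defined()]
        assert len(vals) >= 5
        assert np.all(np.diff(vals) < 0)

    def test_constant_series_all_scales_flagged(self):
        u = UniformSeries(values_ms=np.full(5000, 800.0))
        prof = mse_profile(u, scale_grid_s=np.array([2.5, 5.0, 10.0]),
                           min_points=50)
        assert prof.undefined_mask.all()

    def test_per_scale_tolerance_keeps_white_noise_flat(self, rng):
        # re-normalizing r to each coarse series removes the 1/sqrt(tau) decay
        u = UniformSeries(values_ms=rng.normal(800, 100, 40_000))
        grid = default_scale_grid(hi_s=15.0)
        per = mse_profile(u, params=SampEnParams(r_reference="per_scale"),
                          scale_grid_s=grid, min_points=100)
        fixed = mse_profile(u, scale_grid_s=grid, min_points=100)
        ok = per.defined() & fixed.defined()
        assert ok.sum() >= 5
        assert np.ptp(per.sampen[ok]) < 0.25 * np.ptp(fixed.sampen[ok])

    def test_deterministic_for_fixed_input(self, rng):
        u = UniformSeries(values_ms=rng.normal(800, 100, 8000))
        p1 = mse_profile(u, min_points=50)
        p2 = mse_profile(u, min_points=50)
        np.testing.assert_array_equal(p1.sampen, p2.sampen)

    def test_empty_grid_raises(self, rng):
        u = UniformSeries(values_ms=rng.normal(size=1000))
        with pytest.raises(ValueError):
            mse_profile(u, scale_grid_s=np.array([]))


class TestBandSummary:
    @staticmethod
    def _profile(scales, values):
        scales = np.asarray(scales, float)
        values = np.asarray(values, float)
        return MSEProfile(scales_s=scales, sampen=values,
                          n_points=np.full(len(scales), 1000),
                          undefined_mask=np.isnan(values))

    def test_constant_profile(self):
        scales = default_scale_grid(lo_s=90, hi_s=300)
        prof = self._profile(scales, np.full(len(scales), 0.7))
        s = band_summary(prof, "VLF2")
        assert s.mean_en == pytest.approx(0.7)
        assert s.slope_en == pytest.approx(0.0, abs=1e-12)

    def test_linear_profile_recovers_slope_exactly(self):
        scales = default_scale_grid()
        vals = 1.3 - 0.42 * np.log10(scales)
        prof = self._profile(scales, vals)
        for band in BANDS:
            s = band_summary(prof, band)
            assert s.slope_en == pytest.approx(-0.42, abs=1e-10)

    def test_band_edges_closed(self):
        prof = self._profile([90.0, 150.0, 300.0], [0.5, 0.6, 0.7])
        s = band_summary(prof, "VLF2")
        assert s.n_scales == 3 and s.mean_en == pytest.approx(0.6)

    def test_undefined_scales_excluded(self):
        prof = self._profile([90.0, 150.0, 300.0], [0.5, np.nan, 0.7])
        s = band_summary(prof, "VLF2")
        assert s.n_scales == 2 and s.mean_en == pytest.approx(0.6)

    def test_fewer_than_two_points_undefined(self):
        prof = self._profile([90.0, 150.0], [0.5, np.nan])
        s = band_summary(prof, "VLF2")
        assert not s.defined and math.isnan(s.mean_en)
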