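"""Band method selection, resampling, asymptotics, Chernoff quantiles."""

import numpy as np
import pytest
from scipy.stats import norm

from corpcal import (
    PairedSample,
    aggregate,
    chernoff_quantile,
    compute_band,
    continuous_asymptotic_band,
    discrete_asymptotic_band,
    resample_band,
    select_method,
)


class TestSelectMethod:
    @pytest.mark.parametrize(
        "n, k, band_type, expected",
        [
            (500, 10, "consistency", "resampling"),
            (1000, 999, "consistency", "resampling"),
            (4000, 100, "consistency", "resampling"),  # n<=5000 and n<=50k
            (10_000, 30, "consistency", "discrete_asymptotic"),  # 8k^2=7200<=n
            (10_000, 300, "consistency", "continuous_asymptotic"),
            (2000, 10, "consistency", "discrete_asymptotic"),
            (10**6, 10**6, "confidence", "resampling"),
            (5, 2, "confidence", "resampling"),
        ],
    )
    def test_default_rules(self, n, k, band_type, expected):
        assert select_method(n, k, band_type) == expected

    def test_unknown_band_type(self):
        with pytest.raises(ValueError):
            select_method(10, 2, "prediction")


class TestResampleBand:
    def test_reproducible_and_ordered(self, rng):
        x = rng.random(80)
        y = (rng.random(80) < x).astype(float)
        s = PairedSample(x=x, y=y)
        b1 = resample_band(s, "consistency", level=0.9, n_resamples=200, seed=11)
        b2 = resample_band(s, "consistency", level=0.9, n_resamples=200, seed=11)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)
        assert np.all(b1.lower <= b1.upper)
        # quantiles of isotonic curves stay isotonic pointwise
        assert np.all(np.diff(b1.lower) >= -1e-12)
        assert np.all(np.diff(b1.upper) >= -1e-12)

    def test_monotone_nesting_in_level(self, rng):
        x = rng.random(60)
        s = PairedSample(x=x, y=(rng.random(60) < x).astype(float))
        narrow = resample_band(s, "confidence", level=0.5, n_resamples=300, seed=5)
        wide = resample_band(s, "confidence", level=0.95, n_resamples=300, seed=5)
        assert np.all(wide.lower <= narrow.lower + 1e-12)
        assert np.all(narrow.upper <= wide.upper + 1e-12)

    def test_extreme_level_gives_min_max_envelope(self, toy_sample):
        band = resample_band(toy_sample, "consistency", level=1 - 1e-12,
                             n_resamples=50, seed=2)
        assert np.all(band.lower <= band.upper)
        assert band.lower.min() >= 0.0 and band.upper.max() <= 1.0

    def test_degenerate_zero_forecasts(self):
        s = PairedSample(x=np.zeros(20), y=np.zeros(20))
        band = resample_band(s, "consistency", level=0.9, n_resamples=100, seed=1)
        assert np.array_equal(band.lower, [0.0])
        assert np.array_equal(band.upper, [0.0])

    @pytest.mark.parametrize("level, n_resamples", [(0.0, 100), (1.2, 100), (0.9, 0)])
    def test_invalid_parameters(self, toy_sample, level, n_resamples):
        with pytest.raises(ValueError):
            resample_band(toy_sample, "consistency", level=level,
                          n_resamples=n_resamples, seed=0)


class TestDiscreteAsymptoticBand:
    def test_halfwidth_is_normal_times_binomial_se(self):
        s = PairedSample(x=np.full(100, 0.5), y=np.r_[np.ones(50), np.zeros(50)])
        band = discrete_asymptotic_band(aggregate(s), level=0.9)
        hw = norm.ppf(0.95) * np.sqrt(0.25 / 100)
        assert band.upper[0] - band.lower[0] == pytest.approx(2 * hw)
        assert hw == pytest.approx(0.0822, abs=5e-4)

    def test_degenerate_endpoints_zero_width(self):
        s = PairedSample(x=np.repeat([0.0, 1.0], 10), y=np.repeat([0.0, 1.0], 10))
        band = discrete_asymptotic_band(aggregate(s), level=0.9)
        assert np.array_equal(band.lower, band.upper)

    def test_consistency_only(self, toy_sample):
        with pytest.raises(ValueError, match="consistency"):
            discrete_asymptotic_band(aggregate(toy_sample), band_type="confidence")


class TestContinuousAsymptoticBand:
    @staticmethod
    def _uniformish(n, rng):
        x = rng.random(n)
        return PairedSample(x=x, y=(rng.random(n) < x).astype(float))

    def test_width_shrinks_at_cube_root_rate(self, rng):
        # replicating each case 8-fold leaves unique values and density
        # in place but multiplies n by 8: half-widths should halve
        s = self._uniformish(400, rng)
        big = PairedSample(x=np.repeat(s.x, 8), y=np.repeat(s.y, 8))
        b1 = continuous_asymptotic_band(s, level=0.9)
        b8 = continuous_asymptotic_band(big, level=0.9)
        interior = (b1.z > 0.2) & (b1.z < 0.8)
        ratio = np.nanmedian(
            ((b8.upper - b8.lower) / (b1.upper - b1.lower))[interior]
        )
        assert ratio == pytest.approx(0.5, abs=0.1)

    def test_symmetric_marginal_gives_symmetric_widths(self):
        base = np.linspace(0.001, 0.499, 300)
        x = np.sort(np.concatenate([base, 1.0 - base]))
        y = np.zeros_like(x)
        band = continuous_asymptotic_band(PairedSample(x=x, y=y), level=0.9)
        widths = band.upper - band.lower
        # exact up to histogram granularity: bins anchor at 0, so the
        # density estimate is not perfectly mirror-symmetric
        assert np.allclose(widths, widths[::-1], atol=1e-3)

    def test_band_centred_on_diagonal(self, rng):
        s = self._uniformish(500, rng)
        band = continuous_asymptotic_band(s, level=0.9)
        ok = ~np.isnan(band.lower)
        inner = ok & (band.z > 0.15) & (band.z < 0.85)
        assert np.allclose(
            (band.lower + band.upper)[inner] / 2, band.z[inner], atol=1e-9
        )


class TestChernoffQuantile:
    def test_symmetry(self):
        assert chernoff_quantile(0.5) == pytest.approx(0.0, abs=1e-12)
        assert chernoff_quantile(0.9) == pytest.approx(-chernoff_quantile(0.1), abs=1e-12)

    def test_matches_published_upper_quantile(self):
        # Groeneboom & Wellner report the 97.5% point of the argmax of
        # W(t) - t^2 as 0.998
        assert chernoff_quantile(0.975) == pytest.approx(0.998, abs=0.02)

    def test_two_discretisations_agree(self):
        coarse = chernoff_quantile(0.95)
        fine = chernoff_quantile(0.95, n_paths=150_000, dt=0.005, seed=77)
        assert coarse == pytest.approx(fine, abs=0.01)

    def test_domain(self):
        with pytest.raises(ValueError):
            chernoff_quantile(0.0)


def test_row_pav_kernels_agree(rng):
    # the accelerated row-wise kernel must match the reference pass
    from corpcal.bands import _pav_rows, _pav_rows_py

    freqs = rng.random((50, 37))
    weights = rng.integers(1, 9, size=37).astype(float)
    assert np.allclose(_pav_rows(freqs, weights), _pav_rows_py(freqs, weights),
                       atol=1e-12)


class TestComputeBand:
    def test_auto_dispatch_records_method(self, rng):
        x = np.repeat(np.arange(0.05, 1.0, 0.1), 300)  # n=3000, k=10
        y = (rng.random(x.size) < x).astype(float)
        band = compute_band(PairedSample(x=x, y=y), band_type="consistency")
        assert band.method == "discrete_asymptotic"

    def test_unknown_method(self, toy_sample):
        with pytest.raises(ValueError):
            compute_band(toy_sample, method="jackknife")
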