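"""Aggregation and the pool-adjacent-violators fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corpcal import PairedSample, aggregate, calibrate, mean_score, pav_fit
from corpcal.pav import AggregatedSample

from conftest import brute_force_isotonic, random_paired_sample


class TestAggregate:
    def test_counts_events_and_order_invariance(self):
        s = PairedSample(x=np.array([0.3, 0.3, 0.7]), y=np.array([1.0, 0.0, 1.0]))
        agg = aggregate(s)
        assert agg.z.tolist() == [0.3, 0.7]
        assert agg.counts.tolist() == [2, 1]
        assert agg.events.tolist() == [1, 1]

        perm = PairedSample(x=np.array([0.7, 0.3, 0.3]), y=np.array([1.0, 0.0, 1.0]))
        agg2 = aggregate(perm)
        assert np.array_equal(agg.z, agg2.z)
        assert np.array_equal(agg.counts, agg2.counts)
        assert np.array_equal(agg.events, agg2.events)

    def test_singleton(self):
        agg = aggregate(PairedSample(x=np.array([0.5]), y=np.array([0.0])))
        assert agg.z.tolist() == [0.5] and agg.counts.tolist() == [1]
        assert agg.events.tolist() == [0]

    @pytest.mark.parametrize(
        "x, y, msg",
        [
            ([], [], "empty"),
            ([0.5, 1.2], [0, 0], "index 1"),
            ([0.5, 0.5], [0, 2], "index 1"),
            ([0.1, 0.2], [0], "mismatch"),
        ],
    )
    def test_validation_names_offender(self, x, y, msg):
        with pytest.raises(ValueError, match=msg):
            PairedSample(x=np.asarray(x, float), y=np.asarray(y, float))

    @given(st.lists(st.tuples(st.sampled_from([0.1, 0.3, 0.5, 0.9]),
                              st.sampled_from([0.0, 1.0])),
                    min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, pairs, pyrandom):
        shuffled = pairs.copy()
        pyrandom.shuffle(shuffled)
        a1 = aggregate(PairedSample(*map(np.array, zip(*pairs))))
        a2 = aggregate(PairedSample(*map(np.array, zip(*shuffled))))
        assert np.array_equal(a1.z, a2.z)
        assert np.array_equal(a1.counts, a2.counts)
        assert np.array_equal(a1.events, a2.events)


class TestPavFit:
    def test_single_violator_pools_to_half(self):
        agg = AggregatedSample(z=[0.1, 0.2, 0.3], counts=[1, 1, 1], events=[1, 0, 1])
        fit = pav_fit(agg)
        assert np.allclose(fit.cep_hat, [0.5, 0.5, 1.0])

    def test_isotonic_input_is_fixed_point(self):
        agg = AggregatedSample(z=[0.1, 0.5, 0.9], counts=[2, 2, 2], events=[0, 1, 2])
        assert np.allclose(pav_fit(agg).cep_hat, [0.0, 0.5, 1.0])

    def test_fully_reversed_input_pools_to_grand_mean(self):
        agg = AggregatedSample(z=[0.1, 0.2, 0.3, 0.4], counts=[1, 1, 1, 1],
                               events=[1, 1, 0, 0])
        fit = pav_fit(agg)
        assert np.allclose(fit.cep_hat, 0.5)
        assert len(fit.blocks) == 1

    def test_block_values_are_block_event_frequencies(self, rng):
        for _ in range(100):
            s = random_paired_sample(rng)
            agg = aggregate(s)
            fit = pav_fit(agg)
            for b in fit.blocks:
                o = agg.events[b.start : b.stop].sum()
                n = agg.counts[b.start : b.stop].sum()
                assert b.value == pytest.approx(o / n, abs=1e-12)
                assert b.weight == pytest.approx(n)
            assert np.all(np.diff(fit.cep_hat) >= -1e-12)

    def test_matches_sklearn_isotonic(self, rng):
        IsotonicRegression = pytest.importorskip(
            "sklearn.isotonic"
        ).IsotonicRegression
        for _ in range(50):
            s = random_paired_sample(rng, n=60, discrete_prob=0.7)
            agg = aggregate(s)
            ours = pav_fit(agg).cep_hat
            ref = IsotonicRegression().fit_transform(
                agg.z, agg.frequencies, sample_weight=agg.counts
            )
            assert np.allclose(ours, ref, atol=1e-9)


class TestCalibrate:
    def test_toy_example(self, toy_sample):
        assert np.allclose(calibrate(toy_sample), [0.0, 0.5, 0.5, 1.0])

    def test_calibrated_input_unchanged(self):
        s = PairedSample(x=np.array([0.0, 1.0]), y=np.array([0.0, 1.0]))
        assert np.allclose(calibrate(s), s.x)

    def test_constant_forecast_maps_to_event_rate(self):
        s = PairedSample(x=np.full(10, 0.3), y=np.array([1.0] * 4 + [0.0] * 6))
        assert np.allclose(calibrate(s), 0.4)

    def test_idempotent(self, rng):
        for _ in range(50):
            s = random_paired_sample(rng)
            x_hat = calibrate(s)
            again = calibrate(PairedSample(x=x_hat, y=s.y))
            assert np.allclose(again, x_hat, atol=1e-12)

    def test_monotone_in_forecast(self, rng):
        for _ in range(50):
            s = random_paired_sample(rng)
            x_hat = calibrate(s)
            order = np.argsort(s.x, kind="stable")
            assert np.all(np.diff(x_hat[order]) >= -1e-12)


class TestOptimality:
    def test_brute_force_oracle_small_instances(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 9))
            counts = rng.integers(1, 6, size=k)
            events = rng.binomial(counts, rng.random(k))
            z = np.sort(rng.choice(np.linspace(0.01, 0.99, 200), size=k, replace=False))
            agg = AggregatedSample(z=z, counts=counts, events=events)
            oracle = brute_force_isotonic(agg.frequencies, counts)
            assert np.allclose(pav_fit(agg).cep_hat, oracle, atol=1e-9)

    def test_brier_beats_every_isotonic_candidate(self, rng):
        # the PAV recalibration is Brier-optimal among all nondecreasing
        # recalibrations of the unique forecast values
        grid = np.linspace(0.0, 1.0, 21)
        for _ in range(25):
            s = random_paired_sample(rng, n=20, discrete_prob=1.0)
            agg = aggregate(s)
            z, inv = np.unique(s.x, return_inverse=True)
            pav_score = mean_score(s, calibrate(s), "brier")
            for _ in range(40):
                cand = np.sort(rng.choice(grid, size=agg.k))
                assert pav_score <= mean_score(s, cand[inv], "brier") + 1e-12
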