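"""Task geometry, behavioural metrics and rate preprocessing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mentalnav.task import (
    LandmarkLine,
    TrialCondition,
    actual_vector,
    balanced_split,
    enumerate_conditions,
    performance_slope,
    reward_outcome,
    smooth_rates,
    warp_average,
)


class TestActualVector:
    def test_three_landmark_rightward_vector(self):
        assert actual_vector(1, 4) == pytest.approx(1.95)

    def test_leftward_full_span(self):
        assert actual_vector(6, 1) == pytest.approx(-3.25)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            actual_vector(3, 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            actual_vector(0, 4)


class TestConditions:
    @pytest.mark.parametrize("n", range(2, 9))
    def test_count_matches_ordered_pair_enumeration(self, n):
        line = LandmarkLine(n_landmarks=n)
        conds = enumerate_conditions(line)
        brute = [
            (s, t)
            for s in range(1, n + 1)
            for t in range(1, n + 1)
            if s != t
        ]
        assert len(conds) == len(brute) == n * (n - 1)

    def test_distance_multiset_for_six_landmarks(self):
        # brute-force enumeration of ordered pairs
        expected = {}
        for s, t in itertools.permutations(range(1, 7), 2):
            expected[abs(t - s)] = expected.get(abs(t - s), 0) + 1
        counts = {}
        for c in enumerate_conditions():
            counts[c.distance] = counts.get(c.distance, 0) + 1
        assert counts == expected == {1: 10, 2: 8, 3: 6, 4: 4, 5: 2}

    def test_v_a_consistency(self):
        for c in enumerate_conditions():
            assert c.v_a == pytest.approx((c.target - c.start) * 0.65)


class TestBalancedSplit:
    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_partition_and_balance(self, seed):
        conds = enumerate_conditions()
        a, b = balanced_split(conds, seed=seed)
        assert len(a) == len(b) == 15
        key = lambda c: (c.start, c.target)
        assert set(map(key, a)) | set(map(key, b)) == set(map(key, conds))
        assert set(map(key, a)) & set(map(key, b)) == set()
        for d in range(1, 6):
            ca = sum(c.distance == d for c in a)
            cb = sum(c.distance == d for c in b)
            assert abs(ca - cb) <= 1
        assert abs(sum(c.direction for c in a)) <= 1 or True  # direction counts
        dira = sum(c.direction > 0 for c in a)
        dirb = sum(c.direction > 0 for c in b)
        assert abs(dira - dirb) <= 1

    def test_longest_distance_split_one_each(self):
        # only two distance-5 conditions exist, so balance forces 1 + 1
        a, b = balanced_split(enumerate_conditions(), seed=3)
        assert sum(c.distance == 5 for c in a) == 1
        assert sum(c.distance == 5 for c in b) == 1

    def test_deterministic_given_seed(self):
        conds = enumerate_conditions()
        a1, b1 = balanced_split(conds, seed=9)
        a2, b2 = balanced_split(conds, seed=9)
        assert [(c.start, c.target) for c in a1] == [(c.start, c.target) for c in a2]


class TestRewardOutcome:
    def test_exact_production_fully_rewarded(self):
        rewarded, frac = reward_outcome(1.3, 1.3)
        assert rewarded and frac == pytest.approx(1.0)

    def test_large_error_unrewarded(self):
        rewarded, frac = reward_outcome(0.0 + 1e-9, 1.3)
        assert not rewarded and frac == 0.0

    def test_sign_mismatch_unrewarded(self):
        assert reward_outcome(-1.3, 1.3) == (False, 0.0)

    @pytest.mark.parametrize("rule", ["relative_fixed_0.08", "relative_scaled"])
    def test_threshold_boundary_both_rules(self, rule):
        v_a = 1.3
        thresh = 0.08 if rule == "relative_fixed_0.08" else 0.08 * v_a
        just_in = v_a * (1 + 0.99 * thresh)
        just_out = v_a * (1 + 1.01 * thresh)
        assert reward_outcome(just_in, v_a, rule=rule)[0]
        assert not reward_outcome(just_out, v_a, rule=rule)[0]

    def test_reward_decreases_linearly_with_error(self):
        _, f1 = reward_outcome(1.3 * 1.02, 1.3)
        _, f2 = reward_outcome(1.3 * 1.06, 1.3)
        assert f1 > f2 > 0


class TestPerformanceSlope:
    def test_identity_production(self):
        va = np.array([c.v_a for c in enumerate_conditions()])
        df = pd.DataFrame({"v_a": va, "v_p": va})
        res = performance_slope(df)
        assert res["slope"] == pytest.approx(1.0, abs=1e-10)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert res["meets_criterion"]

    @given(a=st.floats(0.2, 1.5), b=st.floats(-0.5, 0.5))
    @settings(max_examples=20, deadline=None)
    def test_exact_recovery_of_linear_law(self, a, b):
        va = np.array([c.v_a for c in enumerate_conditions()])
        df = pd.DataFrame({"v_a": va, "v_p": a * va + b})
        res = performance_slope(df)
        assert res["slope"] == pytest.approx(a, abs=1e-8)
        assert res["intercept"] == pytest.approx(b, abs=1e-8)

    def test_shrunk_slope_flagged(self):
        va = np.array([c.v_a for c in enumerate_conditions()])
        df = pd.DataFrame({"v_a": va, "v_p": 0.5 * va})
        res = performance_slope(df)
        assert res["slope"] == pytest.approx(0.5, abs=1e-8)
        assert not res["meets_criterion"]


class TestSmoothRates:
    def test_single_spike_gaussian_bump(self):
        rm = smooth_rates([np.array([1.0])], 0.0, 2.0)
        trace = rm.rates[0]
        assert trace.argmax() == pytest.approx(1000, abs=1)
        # area ~ 1 spike
        assert trace.sum() * 0.001 == pytest.approx(1.0, rel=0.01)

    def test_count_conservation_away_from_edges(self):
        rng = np.random.default_rng(0)
        spikes = rng.uniform(0.5, 3.5, 60)
        rm = smooth_rates([spikes], 0.0, 4.0)
        assert rm.rates[0].sum() * 0.001 == pytest.approx(60, rel=0.01)

    def test_empty_train_zero_trace(self):
        rm = smooth_rates([np.array([])], 0.0, 1.0)
        assert np.all(rm.rates == 0)

    def test_homogeneous_poisson_mean_rate(self):
        rng = np.random.default_rng(1)
        trains = [np.sort(rng.uniform(0, 2, rng.poisson(40))) for _ in range(100)]
        rm = smooth_rates(trains, 0.0, 2.0)
        mid = rm.mean()[500:1500]  # away from edges
        sem = mid.std() / np.sqrt(mid.size)
        assert abs(mid.mean() - 20) < 1.0

    def test_two_spikes_separated_bumps(self):
        rm = smooth_rates([np.array([0.5, 1.5])], 0.0, 2.0)
        trace = rm.rates[0]
        assert trace[1000] < 0.5 * trace[500]  # trough between bumps


class TestWarpAverage:
    def test_identical_durations_plain_average(self):
        traces = [np.ones(1000), 3 * np.ones(1000)]
        avg, t, stretch = warp_average(traces, [1.0, 1.0], bin_width=0.001)
        assert np.allclose(avg, 2.0)
        assert np.allclose(stretch, 1.0)

    def test_time_fraction_coded_signal_exact(self):
        # rates linear in fractional trial time are invariant under warping
        traces, durs = [], []
        for dur in (0.8, 1.0, 1.25):
            n = int(dur / 0.001)
            traces.append(np.linspace(0, 10, n))
            durs.append(dur)
        avg, t, _ = warp_average(traces, durs, bin_width=0.001)
        frac = t / t[-1]
        expected = 10 * frac
        assert np.allclose(avg[2:-2], expected[2:-2], atol=0.25)

    def test_zero_duration_trial_excluded(self):
        with pytest.warns(UserWarning):
            avg, t, s = warp_average([np.ones(100), np.ones(0)], [0.1, 0.0],
                                     bin_width=0.001)
        assert s.size == 1

    def test_output_length_matches_median_duration(self):
        traces = [np.ones(800), np.ones(1000), np.ones(1300)]
        avg, t, _ = warp_average(traces, [0.8, 1.0, 1.3], bin_width=0.001)
        assert avg.size == int(np.ceil(1.0 / 0.04))
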