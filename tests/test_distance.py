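"""Distance coding: single-unit regression, cross-validated R^2, TDR, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ranksums

from mentalnav.distance import (
    anova4,
    cross_validated_r2,
    cv_distance_r2,
    single_neuron_distance_regression,
    tdr_axis,
    window_rates,
)
from mentalnav.observer import ObserverParams
from mentalnav.synthetic import gen_behavior_session
from mentalnav.task import NeuronSession


@pytest.fixture(scope="module")
def coding_trials():
    obs = ObserverParams(w_m=0.05, w_p=0.05, model_kind="subscalar")
    return gen_behavior_session(obs, n_trials=400, seed=1)


def _offset_coding_neuron(trials, gain, rng, baseline=8.0, window=0.6):
    """Poisson unit whose pre-offset rate scales with ordinal distance."""
    dist = (trials["target"] - trials["start"]).abs().to_numpy()
    spikes = []
    for (_, r), d in zip(trials.iterrows(), dist):
        t_on, t_off = r["t_on"], r["t_off"]
        n_base = rng.poisson(baseline * (t_off - t_on + 1.0))
        s = rng.uniform(t_on - 0.5, t_off + 0.5, n_base)
        n_extra = rng.poisson(gain * d * window)
        s2 = rng.uniform(t_off - window, t_off, n_extra)
        spikes.append(np.concatenate([s, s2]))
    return NeuronSession(f"g{gain:.2f}", np.concatenate(spikes), trials)


@pytest.fixture(scope="module")
def offset_population(coding_trials):
    rng = np.random.default_rng(0)
    return [
        _offset_coding_neuron(coding_trials, float(g), rng)
        for g in rng.uniform(1.0, 4.0, 15)
    ]


class TestCrossValidatedR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert cross_validated_r2(y, y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert cross_validated_r2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_anti_predictive_negative(self):
        y = np.array([1.0, 2.0, 3.0])
        assert cross_validated_r2(y, y[::-1]) < 0

    def test_zero_test_variance_undefined(self):
        assert np.isnan(cross_validated_r2(np.ones(4), np.ones(4)))

    def test_equals_in_sample_r2_when_train_is_test(self):
        rng = np.random.default_rng(1)
        x = np.repeat(np.arange(1.0, 6.0), 20)
        y = 2 * x + rng.standard_normal(x.size)
        beta, b0 = np.polyfit(x, y, 1)
        pred = beta * x + b0
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert cross_validated_r2(y, pred) == pytest.approx(1 - ss_res / ss_tot)

    def test_shuffled_regressor_null_centred_at_or_below_zero(self):
        rng = np.random.default_rng(2)
        dist = np.repeat(np.arange(1.0, 6.0), 30)
        rates = 5 + 2 * dist + rng.standard_normal(dist.size)
        null = []
        for _ in range(100):
            null.append(cv_distance_r2(rates, rng.permutation(dist),
                                       n_repeats=3, seed=0))
        assert np.nanmean(null) <= 0.05


class TestWindowRates:
    def test_exact_window_boundaries(self):
        trials = pd.DataFrame({
            "session_id": "s", "start": 1, "target": 4, "v_a": 1.95,
            "v_p": [1.95], "t_go": 0.5, "t_on": 1.0, "t_off": 2.95,
            "n_attempts": 1, "rewarded": True,
        })
        # spikes at offset-0.099 and offset-0.101: only the first is inside
        # a [-0.1, 0) pre-offset window (half-open)
        spikes = np.array([2.95 - 0.101, 2.95 - 0.099, 2.95])
        s = NeuronSession("n", spikes, trials)
        r = window_rates(s, "offset", (-0.1, 0.0))
        assert r[0] == pytest.approx(1 / 0.1)


class TestSingleNeuron:
    def test_untuned_unit_classified_none(self, coding_trials):
        rng = np.random.default_rng(3)
        s = _offset_coding_neuron(coding_trials, 0.0, rng)
        res = single_neuron_distance_regression(s, seed=0)
        assert res.klass == "none"
        assert abs(res.cv_r2_offset) < 0.15

    def test_offset_coding_detected_with_slope(self, coding_trials):
        rng = np.random.default_rng(4)
        s = _offset_coding_neuron(coding_trials, 3.0, rng)
        res = single_neuron_distance_regression(s, seed=0)
        assert res.klass == "offset"
        # gain is per ordinal distance; |v_p| = 0.65 * distance, so the
        # slope against |v_p| is gain / 0.65
        assert res.slope_offset == pytest.approx(3.0 / 0.65, rel=0.3)

    def test_offset_coding_robust_to_excluding_distance_one(self, coding_trials):
        rng = np.random.default_rng(5)
        s = _offset_coding_neuron(coding_trials, 3.0, rng)
        res = single_neuron_distance_regression(s, exclude_distance_1=True, seed=0)
        assert res.klass == "offset"


class TestTDR:
    def test_offset_axis_beats_onset_axis(self, offset_population):
        res = tdr_axis(offset_population, seed=3)
        stat = ranksums(res.r2_offset, res.r2_onset, alternative="greater")
        assert stat.pvalue < 1e-4

    def test_projections_ordered_by_distance(self, offset_population):
        res = tdr_axis(offset_population, seed=3)
        means = [np.mean(res.proj_offset[d]) for d in sorted(res.proj_offset)]
        assert np.all(np.diff(means) > 0)

    def test_axis_aligned_with_planted_gains(self, coding_trials):
        rng = np.random.default_rng(7)
        gains = rng.uniform(0.5, 4.0, 20)
        pop = [_offset_coding_neuron(coding_trials, float(g), rng) for g in gains]
        res = tdr_axis(pop, seed=1)
        cos = res.axis_offset @ gains / np.linalg.norm(gains)
        assert cos > 0.9

    def test_shuffled_distances_kill_both_axes(self, coding_trials, offset_population):
        rng = np.random.default_rng(8)
        shuffled = rng.permutation(
            (coding_trials["target"] - coding_trials["start"]).abs().to_numpy(float)
        )
        res = tdr_axis(offset_population, distances=shuffled, seed=2)
        assert np.nanmean(res.r2_offset) < 0.1

    def test_small_population_rejected(self, offset_population):
        with pytest.raises(ValueError):
            tdr_axis(offset_population[:5])


class TestAnova:
    def test_distance_coding_dominates_landmark_identity(self, offset_population):
        out = anova4(offset_population[:8])
        assert out["distance_vs_start"]["mean_diff"] > 0
        assert out["distance_vs_start"]["p"] < 0.05

    def test_target_coding_generator_flips_dominance(self, coding_trials):
        # alternative generator: rate keyed to target landmark identity
        rng = np.random.default_rng(9)
        target = coding_trials["target"].to_numpy()
        pop = []
        for j in range(8):
            pref = rng.integers(1, 7)
            spikes = []
            for (_, r), tg in zip(coding_trials.iterrows(), target):
                lam = 8.0 + 18.0 * (tg == pref)
                n = rng.poisson(lam * (r["t_off"] - r["t_on"] + 1.0))
                spikes.append(rng.uniform(r["t_on"] - 0.5, r["t_off"] + 0.5, n))
            pop.append(NeuronSession(f"t{j}", np.concatenate(spikes), coding_trials))
        out = anova4(pop)
        assert out["distance_vs_target"]["mean_diff"] < 0

    def test_pure_noise_f_near_one(self, coding_trials):
        rng = np.random.default_rng(10)
        pop = [_offset_coding_neuron(coding_trials, 0.0, rng) for _ in range(6)]
        out = anova4(pop)
        assert out["table"]["F_distance"].mean() < 3.0
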