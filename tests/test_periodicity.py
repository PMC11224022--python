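"""ACG/PI pipeline, surrogate null, ramping, epoch comparisons, Fano."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mentalnav.periodicity import (
    ACG_DT,
    PIResult,
    _peak_lag,
    acg_of_trace,
    classify_periodic,
    compute_acg,
    epoch_outcome_comparison,
    fano_periodicity,
    fano_time_course,
    periodicity_index,
    ramping_test,
    shifted_acg_correlation,
)
from mentalnav.synthetic import (
    NeuronSpec,
    PopulationSpec,
    gen_spike_session,
    make_class_spec,
)
from mentalnav.task import NeuronSession


class TestPeriodicityIndex:
    @pytest.mark.parametrize("period", [0.35, 0.5, 0.65, 0.9, 1.2])
    def test_peak_at_true_period_of_cosine_acg(self, period):
        lags = np.arange(0, int(2.4 / ACG_DT) + 1) * ACG_DT
        acg = np.cos(2 * np.pi * lags / period)
        pi, pl = periodicity_index(acg)
        assert _peak_lag(pi, pl) == pytest.approx(period, abs=0.011)

    def test_damped_cosine_peak(self):
        lags = np.arange(0, int(2.4 / ACG_DT) + 1) * ACG_DT
        acg = np.exp(-lags / 1.2) * np.cos(2 * np.pi * lags / 0.65)
        pi, pl = periodicity_index(acg)
        assert _peak_lag(pi, pl) == pytest.approx(0.65, abs=0.011)

    def test_white_noise_acg_gives_near_zero_pi(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(30):
            acg = rng.standard_normal(int(2.4 / ACG_DT) + 1) * 0.05
            acg[0] = 1.0
            pi, _ = periodicity_index(acg)
            vals.append(np.nanmean(pi[20:]))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 0.05

    def test_shifted_correlation_identity_at_zero_lag(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        c = shifted_acg_correlation(x)
        assert c[0] == pytest.approx(1.0)

    def test_shifted_correlation_matches_direct_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        c = shifted_acg_correlation(x)
        for tau in (5, 50, 120):
            direct = np.corrcoef(x[:-tau], x[tau:])[0, 1]
            assert c[tau] == pytest.approx(direct, abs=1e-10)


class TestComputeACG:
    def test_periodic_neuron_side_lobe_near_t_o(self, periodic_neuron):
        acg, lags, n = compute_acg(periodic_neuron)
        assert n > 15
        pi, pl = periodicity_index(acg)
        assert _peak_lag(pi, pl) == pytest.approx(0.65, abs=0.05)

    def test_acg_normalized_at_zero(self, periodic_neuron):
        acg, lags, _ = compute_acg(periodic_neuron)
        assert acg[0] == pytest.approx(1.0, abs=1e-9)

    def test_no_qualifying_trials_flagged(self, periodic_neuron):
        acg, lags, n = compute_acg(periodic_neuron, min_distance=99)
        assert n == 0 and np.all(np.isnan(acg))


class TestClassifyPeriodic:
    def test_strong_periodic_neuron_detected(self, periodic_neuron):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = classify_periodic(periodic_neuron, n_null=100, seed=0)
        assert res.significant
        assert res.peak_lag == pytest.approx(0.65, abs=0.05)

    def test_untuned_neuron_not_detected(self, untuned_neuron):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = classify_periodic(untuned_neuron, n_null=100, seed=1)
        assert not res.significant

    def test_trial_count_rule(self, periodic_neuron):
        # restrict to 10 trials: periodicity may be present but the unit
        # must not be classified significant
        mask = np.zeros(len(periodic_neuron.trials), bool)
        mask[:10] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = classify_periodic(periodic_neuron, n_null=50, seed=2,
                                    trial_mask=mask)
        assert not res.significant
        assert "trials" in res.reason


class TestRamping:
    def test_linear_ramp_recovered(self, behavior_trials):
        pop = PopulationSpec([make_class_spec("ramping", ramp_slope=5.0,
                                              baseline=10.0)], seed=0)
        s = gen_spike_session(pop, behavior_trials, seed=1)[0]
        res = ramping_test(s)
        assert res["significant"]
        assert res["slope"] == pytest.approx(5.0, rel=0.25)

    def test_flat_rate_not_significant(self, untuned_neuron):
        res = ramping_test(untuned_neuron)
        assert not res["significant"]


class TestEpochOutcome:
    def test_identical_partitions_centred_at_zero(self, periodic_neuron):
        tr = periodic_neuron.trials.copy()
        # alternate trials into two statistically identical halves via the
        # rewarded flag
        tr["rewarded"] = (np.arange(len(tr)) % 2 == 0)
        n2 = NeuronSession(periodic_neuron.neuron_id, periodic_neuron.spike_times,
                          tr, periodic_neuron.group, periodic_neuron.iti_segments)
        out = epoch_outcome_comparison([n2], mode="correct_vs_error", min_trials=5)
        if out["n_units"]:
            assert abs(out["diff"][0]) < 1.0

    def test_tertile_split_detects_period_stretching(self, behavior_trials):
        # units whose bumps are locked to trial time-fractions have a longer
        # bump period on trials with a larger produced vector, so the
        # top-tertile PI peak lag should exceed the bottom-tertile one
        rng = np.random.default_rng(21)
        tr = behavior_trials.copy()
        tr["rewarded"] = True
        neurons = []
        for j in range(4):
            spikes = []
            for _, r in tr.iterrows():
                t_on, t_off = r["t_on"], r["t_off"]
                d = abs(r["target"] - r["start"])
                period = (t_off - t_on) / d  # stretches with |v_p|
                t = np.arange(t_on - 0.5, t_off + 0.5, 0.001)
                rate = np.full(t.size, 6.0)
                c = t_off
                while c > t_on - 0.2:
                    rate += 30.0 * np.exp(-0.5 * ((t - c) / 0.08) ** 2)
                    c -= period
                counts = rng.poisson(rate * 0.001)
                idx = np.repeat(np.arange(t.size), counts)
                spikes.append(t[idx])
            neurons.append(NeuronSession(f"tf{j}", np.concatenate(spikes), tr))
        out = epoch_outcome_comparison(neurons, mode="tertiles", min_trials=5)
        assert out["n_units"] >= 2
        assert np.nanmean(out["diff"]) > 0

    def test_mnav_vs_iti_periodic_only_during_navigation(self, behavior_trials):
        pop = PopulationSpec([make_class_spec("periodic") for _ in range(4)], seed=2)
        neurons = gen_spike_session(pop, behavior_trials, seed=3)
        out = epoch_outcome_comparison(neurons, mode="mnav_vs_iti", min_trials=5)
        assert out["n_units"] >= 2
        # navigation-epoch PI exceeds ITI PI for bump-locked units
        assert np.nanmean(out["diff"]) > 0


@pytest.fixture(scope="module")
def many_trials(long_conditions):
    """Fano estimation needs a large trial count; 120 long-distance trials."""
    from mentalnav.observer import ObserverParams
    from mentalnav.synthetic import gen_behavior_session

    obs = ObserverParams(w_m=0.05, w_p=0.05, model_kind="subscalar")
    return gen_behavior_session(obs, conditions=long_conditions, n_trials=120, seed=13)


class TestFano:
    def test_homogeneous_poisson_fano_near_one(self, behavior_trials):
        pop = PopulationSpec([make_class_spec("untuned", baseline=30.0)], seed=4)
        s = gen_spike_session(pop, behavior_trials, seed=5)[0]
        fano, t, counts = fano_time_course(s)
        assert np.nanmean(fano) == pytest.approx(1.0, abs=0.15)

    def test_jitter_reset_fano_periodic_without_periodic_mean(self, many_trials):
        # the Fano PI peak has ~1-sample (25 ms) resolution per unit, so the
        # period is checked on the median over three generated units
        peaks, n_sig = [], 0
        for seed in (6, 7, 8):
            pop = PopulationSpec([make_class_spec("jitter_reset", baseline=40.0)],
                                 seed=seed)
            s = gen_spike_session(pop, many_trials, seed=seed + 1)[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # a four-period window keeps the ACG support long enough for
                # an unbiased peak estimate
                res = fano_periodicity(s, n_null=50, seed=8, window=(-2.6, 0.0))
            n_sig += res.significant
            peaks.append(res.peak_lag)
        assert n_sig >= 2
        assert np.median(peaks) == pytest.approx(0.65, abs=0.05)
        # dissociation: the unit's mean rate is aperiodic
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rate_res = classify_periodic(s, n_null=100, seed=9)
        assert not rate_res.significant

    def test_doubly_stochastic_gain_fano_above_one_nonperiodic(self, behavior_trials):
        # trial-wise rate gain: overdispersed but with no periodic structure
        rng = np.random.default_rng(10)
        spikes = []
        tr = behavior_trials
        for _, r in tr.iterrows():
            gain = rng.lognormal(0, 0.4)
            lam = 30.0 * gain * (r["t_off"] - r["t_on"] + 1.0)
            n = rng.poisson(lam)
            spikes.append(rng.uniform(r["t_on"] - 0.5, r["t_off"] + 0.5, n))
        s = NeuronSession("ds", np.concatenate(spikes), tr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fano_periodicity(s, n_null=50, seed=11)
        fano, _, _ = fano_time_course(s)
        assert np.nanmean(fano) > 1.3
        assert not res.significant
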