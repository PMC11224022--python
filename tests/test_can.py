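"""Continuous-attractor network: dynamics, learning, navigation, variability."""

import dataclasses
import warnings

import numpy as np
import pytest

from mentalnav.can import (
    CANConfig,
    CANetwork,
    GCModules,
    LMUnit,
    _landmark_period,
    find_training_velocity,
    match_no_landmark_model,
    model_fano,
    run_navigation,
    train_landmark_weights,
    variability_powerlaw,
)


@pytest.fixture(scope="module")
def trained_net():
    net = CANetwork(seed=1)
    v = find_training_velocity(net)
    train_landmark_weights(net, velocity=v, n_pulses=40)
    net.calibrated_velocity = 1.4
    net._train_velocity = v
    return net


def _advance(mods, v, T):
    r = mods.init_state(1)
    ph_prev = mods.phase(r, 0)[0]
    unw = 0.0
    traj = []
    for _ in range(int(T / mods.cfg.dt)):
        r = mods.step(r, np.array([v]))
        ph = mods.phase(r, 0)[0]
        unw += float(np.angle(np.exp(1j * (ph - ph_prev))))
        ph_prev = ph
        traj.append(unw)
    return np.array(traj)


class TestAttractorDynamics:
    def test_pattern_forms_and_is_stationary(self):
        cfg = dataclasses.replace(CANConfig(), gains=(1.0,))
        mods = GCModules(cfg)
        r = mods.init_state(1)
        assert r.max() > 2 * r.mean()  # patterned, not uniform
        traj = _advance(mods, 0.0, 5.0)
        # drift below 1% of an inter-bump spacing (2 pi) per second
        assert abs(traj[-1]) / 5.0 < 0.0628

    def test_phase_advance_linear_in_time(self):
        cfg = dataclasses.replace(CANConfig(), gains=(1.0,))
        mods = GCModules(cfg)
        traj = _advance(mods, 1.0, 1.5)
        t = np.arange(traj.size) * cfg.dt
        r2 = np.corrcoef(t[200:], traj[200:])[0, 1] ** 2
        assert r2 > 0.99

    def test_velocity_doubling_doubles_advance_rate(self):
        cfg = dataclasses.replace(CANConfig(), gains=(1.0,))
        mods = GCModules(cfg)
        a1 = _advance(mods, 0.5, 1.0)[-1]
        a2 = _advance(mods, 1.0, 1.0)[-1]
        assert a2 / a1 == pytest.approx(2.0, rel=0.15)


class TestLandmarkLearning:
    def test_zero_learning_rate_keeps_weights(self):
        net = CANetwork(seed=0)
        w0 = net.lm.W.copy()
        net.lm.eta = 0.0
        train_landmark_weights(net, velocity=0.85, n_pulses=2)
        assert np.allclose(net.lm.W, w0)

    def test_learning_rate_bound_enforced(self):
        with pytest.raises(ValueError):
            LMUnit.init(128, eta=2e-7)

    def test_matched_module_weight_energy_dominates(self, trained_net):
        cfg = trained_net.cfg
        e = np.array([
            np.sum(trained_net.lm.W[m * cfg.n_units:(m + 1) * cfg.n_units] ** 2)
            for m in range(len(cfg.gains))
        ])
        mm = trained_net.matched_module
        others = np.delete(e, mm)
        assert e[mm] / others.max() > 5

    def test_weights_centred_per_module(self, trained_net):
        cfg = trained_net.cfg
        for m in range(len(cfg.gains)):
            seg = trained_net.lm.W[m * cfg.n_units:(m + 1) * cfg.n_units]
            assert abs(seg.mean()) < 1e-10

    def test_internal_drive_alone_reproduces_pulse_train(self, trained_net):
        period = _landmark_period(trained_net, trained_net._train_velocity)
        assert period == pytest.approx(0.65, abs=0.05)


class TestNavigation:
    def test_zero_noise_runs_are_deterministic(self, trained_net):
        cfg = dataclasses.replace(trained_net.cfg, weber=0.0, fast_noise=0.0,
                                  adapt_noise=0.0)
        net = CANetwork(cfg, seed=1)
        net.lm = trained_net.lm
        net.calibrated_velocity = 1.4
        run = run_navigation(net, 1.4, with_landmarks=True, distances=(1, 2),
                             n_sims=5, seed=0, max_factor=6.0)
        assert np.nanstd(run["durations"], axis=1).max() < 1e-6

    def test_landmark_drive_slows_traversal(self, trained_net):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            on = run_navigation(trained_net, 1.4, with_landmarks=True,
                                distances=(3,), n_sims=8, seed=1, max_factor=6.0)
            off = run_navigation(trained_net, 1.4, with_landmarks=False,
                                 distances=(3,), n_sims=8, seed=1, max_factor=6.0)
        assert np.nanmean(on["durations"]) > np.nanmean(off["durations"])

    def test_reset_count_matches_distance(self, trained_net):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_navigation(trained_net, 1.4, with_landmarks=True,
                                 distances=(4,), n_sims=6, seed=2, max_factor=6.0)
        d4 = np.nanmean(run["durations"][0])
        counts = [np.sum(ev <= d4 + 0.1) for ev in run["resets"]]
        assert np.median(counts) == pytest.approx(4, abs=1)

    def test_phase_variance_dips_at_landmarks(self, trained_net):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_navigation(trained_net, 1.4, with_landmarks=True,
                                 distances=(5,), n_sims=30, seed=3, max_factor=6.0)
        var = np.nanvar(run["trajectory"], axis=1)
        t = run["time"]
        sel = (t > 0.8) & (t < 2.8)
        # periodic variance collapse: within the navigation epoch the minimum
        # across-sim phase variance is far below the local maximum
        assert var[sel].min() < 0.4 * var[sel].max()

    def test_matched_velocities_equalize_means(self, trained_net):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = run_navigation(trained_net, 1.4, with_landmarks=True,
                                 distances=(2, 4), n_sims=12, seed=4, max_factor=6.0)
            targets = np.nanmean(ref["durations"], axis=1)
            vels = match_no_landmark_model(trained_net, targets, distances=(2, 4),
                                           n_sims=12, seed=5)
            for v, d, tgt in zip(vels, (2, 4), targets):
                run = run_navigation(trained_net, v, with_landmarks=False,
                                     distances=(d,), n_sims=12, seed=6,
                                     max_factor=8.0)
                assert np.nanmean(run["durations"]) == pytest.approx(tgt, rel=0.1)


class TestPowerLaw:
    def test_linear_sd_gives_exponent_one(self):
        rng = np.random.default_rng(0)
        means = 0.65 * np.arange(1, 6)
        d = np.array([rng.normal(m, 0.1 * m, 4000) for m in means])
        res = variability_powerlaw(d, n_boot=50, seed=1)
        assert res.b == pytest.approx(1.0, abs=0.15)
        assert not res.test_sublinear()["significant"] or res.b > 0.85

    def test_sqrt_sd_gives_exponent_half(self):
        rng = np.random.default_rng(2)
        means = 0.65 * np.arange(1, 6)
        d = np.array([rng.normal(m, 0.1 * np.sqrt(m), 4000) for m in means])
        res = variability_powerlaw(d, n_boot=50, seed=3)
        assert res.b == pytest.approx(0.5, abs=0.15)
        assert res.test_sublinear()["significant"]

    def test_summary_mentions_test(self):
        rng = np.random.default_rng(4)
        means = 0.65 * np.arange(1, 6)
        d = np.array([rng.normal(m, 0.08 * m, 200) for m in means])
        text = variability_powerlaw(d, n_boot=30, seed=5).summary()
        assert "b < 1" in text

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            variability_powerlaw(np.ones((3, 10)))


class TestModelFano:
    def test_requires_recorded_units(self, trained_net):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_navigation(trained_net, 1.4, with_landmarks=True,
                                 distances=(2,), n_sims=4, seed=7, max_factor=6.0)
        with pytest.raises(ValueError):
            model_fano(run)

    def test_reset_model_fano_periodic(self, trained_net):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_navigation(trained_net, 1.4, with_landmarks=True,
                                 distances=(5,), n_sims=30, seed=8,
                                 max_factor=6.0, record_units=True)
        out = model_fano(run)
        peaks = out["peak_lags"]
        med = np.nanmedian(peaks)
        assert med == pytest.approx(0.65, abs=0.08)
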