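# mentalnav

Analysis and modelling toolkit for **landmark-based mental navigation**:
the behaviour of producing a temporal-distance vector between memorized
landmarks, the spike-train signatures expected when a cognitive map is
recalled endogenously, and the circuit model that ties the two together.

The package is aimed at systems/cognitive neurophysiologists working with
interval-production tasks and entorhinal-style periodic activity. It
provides, end to end:

- **Task model** — a line of six landmark images separated by
  t_o = 0.65 s of travel; 30 ordered start–target conditions; signed
  actual/produced vectors `v_a`, `v_p`; reward rules; behavioural
  regression; balanced training/generalization splits.
- **Periodicity analyses** — a lag-domain *periodicity index* (PI), the
  1D analogue of the gridness score: per-trial detrended
  autocorrelograms averaged into an ACG, with
  `PI(τ) = corr(ACG, shift τ) − corr(ACG, shift τ/2)` and significance
  against Gaussian-process surrogate spike trains; ramping tests;
  epoch/outcome/tertile comparisons; Fano-factor periodicity.
- **Bump phases** — recursive detection of pre-offset activity peaks
  (expected near −0.65, −1.30, −1.95 s), with bootstrap uncertainty and a
  calibrated circular-shift null.
- **Distance coding** — single-unit regression with cross-validated R²,
  targeted dimensionality reduction (population coding axes at joystick
  onset and offset), and a four-way ANOVA separating distance from
  landmark identity.
- **Pair structure** — preservation of pairwise correlation structure
  across task epochs, the attractor-network signature.
- **Continuous-attractor network (CAN)** — ring modules that
  path-integrate a velocity input, a landmark unit that learns to fire at
  memorized landmark positions through Oja plasticity, reset dynamics that
  pin the network at endogenous landmarks, and the resulting sub-linear
  (subscalar) growth of timing variability.
- **Bayesian observers** — two generative models of production behaviour
  built on Bayes-least-squares estimation over the task prior: *scalar*
  (σ = w_p·t_e, no resets) vs *subscalar* (σ = w_p·√t_o·√t_e, the
  variance-sum law of an epoch divided into base intervals), with MLE
  fitting (`ObserverModel.fit()` → results object with `summary()`),
  outlier exclusion and model comparison.
- **Synthetic data** — seeded generators for behavioural sessions and
  spike-train populations carrying exactly the structure the analyses
  assume (landmark-locked bumps, ramps, anticipatory bursts, and a
  jitter-reset class whose Fano factor is periodic without a periodic
  mean rate).

`docs/methods.md` documents every model, default and numerical choice.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from mentalnav.observer import ObserverParams, fit_mle
from mentalnav.periodicity import classify_periodic
from mentalnav.synthetic import (PopulationSpec, gen_behavior_session,
                                 gen_spike_session, make_class_spec)
from mentalnav.task import enumerate_conditions, performance_slope

# one session of behaviour from a subscalar observer
obs = ObserverParams(w_m=0.05, w_p=0.08, model_kind="subscalar")
trials = gen_behavior_session(obs, n_trials=200, seed=0)
perf = performance_slope(trials)
print(f"regression of v_p on v_a: slope {perf['slope']:.3f}, "
      f"intercept {perf['intercept']:.3f}")

# which production-noise law explains the session better?
for kind in ("scalar", "subscalar"):
    f = fit_mle(trials, kind)
    print(f"{kind:>9}: w_p = {f.params[1]:.3f}, mean log-lik = {f.mean_llf():.3f}")

# periodicity of a landmark-locked synthetic unit
long_trials = gen_behavior_session(
    obs, conditions=[c for c in enumerate_conditions() if c.distance >= 3],
    n_trials=40, seed=1)
pop = PopulationSpec([make_class_spec("periodic")], seed=2)
unit = gen_spike_session(pop, long_trials, seed=3)[0]
res = classify_periodic(unit, n_null=200, seed=4)
print(f"unit {unit.neuron_id}: significant={res.significant}, "
      f"PI peak at {res.peak_lag:.3f} s "
      f"(max PI {res.max_pi:.2f} vs null {res.null_mean:.2f} +/- {res.null_sd:.2f})")
```

Output:

```
regression of v_p on v_a: slope 1.002, intercept -0.002
   scalar: w_p = 0.068, mean log-lik = 1.040
subscalar: w_p = 0.086, mean log-lik = 1.106
unit n000: significant=True, PI peak at 0.620 s (max PI 1.84 vs null 0.72 +/- 0.41)
```

The behavioural slope near 1 says the produced vectors track the actual
vectors; the subscalar observer's higher mean log-likelihood correctly
identifies the generating noise law; and the unit's PI peak near 0.65 s
recovers the inter-landmark interval planted in its spike trains, well
above the surrogate (Gaussian-process) null.

The CAN lives in `mentalnav.can`: build a `CANetwork`, train the landmark
weights (`train_landmark_weights`), calibrate the drive
(`calibrate_velocity`), then `run_navigation` with and without landmarks
and fit `variability_powerlaw` to the produced durations — the landmark
(reset) model comes out sub-linear (b < 1), the landmark-free model scalar
(b ≈ 1).

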