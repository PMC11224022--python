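# Methods

This note documents the models and procedures implemented in `mentalnav`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## The task and its containers

The task is one-dimensional mental navigation along a line of six
equidistant landmark images. At the fixed display speed, adjacent landmarks
are separated by the base interval t_o = 0.65 s, so a displacement of D
landmarks corresponds to a temporal distance of D × 0.65 s. On each trial a
subject holds a joystick deflected to produce a signed vector v_p that
should match the actual start-to-target vector v_a = (target − start) × t_o;
rightward is positive. There are 6 × 5 = 30 ordered start–target pairs with
distance multiplicities {D=1: 10, 2: 8, 3: 6, 4: 4, 5: 2}; these
multiplicities double as the task prior over distances. Trials with a second
attempt are treated as errors throughout.

Conventions: all within-trial times are seconds relative to joystick onset
or offset; analysis windows are half-open [a, b). The reward rule compares
the relative error |v_p − v_a| / |v_a| with a criterion; whether the
criterion is a fixed 8% window or additionally scaled by |v_a| is a config
switch (`reward_rule`), defaulting to the fixed 8% window, which behaves
sensibly at all distances.

Firing rates are spike counts in 1-ms bins smoothed with a Gaussian kernel
(SD 100 ms). Condition averages across trials of unequal duration use
linear time-warping onto the median-duration base at 40-ms resolution.

## Periodicity index (PI)

The PI is a one-dimensional, lag-domain analogue of the gridness score.
Per unit: pool trials with distance ≥ 3 (long enough to estimate
periodicity), truncate 500 ms before joystick offset (removing the
anticipatory burst), linearly detrend each trial's smoothed rate, compute
each trial's normalized autocorrelation (lags 0–2,400 ms) and average them
into a mean ACG. For candidate lags 0–1,300 ms the ACG is Pearson-correlated
with its lag-shifted copy over the overlapping support, and
PI(τ) = corr(ACG, shift τ) − corr(ACG, shift τ/2). A periodic unit has PI
maximal at the true period.

Numerical choices: the ACG/PI stage runs on a 5-ms lag grid (the 100-ms
smoothing kernel leaves no structure at 1 ms); per-trial autocorrelations
use the biased (zero-padded) estimator normalized to ACG(0) = 1, averaged
with per-lag trial counts so short trials only contribute where they have
support; a minimum overlap of 10 samples is required for each shifted
correlation; PI peaks are local maxima with ties broken toward the smaller
lag. The biased estimator's triangular taper plus Poisson noise biases the
recovered peak by roughly −0.02 to −0.03 s at realistic signal-to-noise —
well inside the ±0.05 s tolerance used throughout.

Significance uses surrogate spike trains from a zero-mean Gaussian process
with squared-exponential covariance (variance 1, length constant 100 ms,
matching the smoothing kernel), mapped to a nonnegative intensity with an
exponential link normalized to the unit's own mean rate, and thinned as an
inhomogeneous Poisson process. Each surrogate repeat regenerates the unit's
full trial set (same count and durations) and passes through the identical
pipeline; the null statistic is the maximal PI. A unit is periodic when its
maximal PI exceeds the surrogate mean by two standard deviations and more
than 15 trials were pooled.

The Fano factor (across-trial variance/mean of spike counts) is computed in
100-ms sliding bins stepped by 25 ms, aligned to joystick offset; its
periodicity uses the same detrend/ACG/PI machinery, with a null from
rate-matched Poisson regenerations of the same trials (for which the Fano
factor is 1 and aperiodic). The default window spans three base intervals
(−1.95 to 0 s); a four-interval window gives a less biased peak estimate
when enough long trials exist.

## Bump phases

Local maxima of the offset-aligned mean rate are detected recursively: the
first peak inside the second before the offset, the second inside the
second before the first, and so on. Peaks need a prominence of ≥5% of the
trace range; a window whose maximum sits on its edge is flagged rather than
trusted. Phase uncertainty comes from 100 bootstrap repeats over 80% trial
subsamples.

The significance test is a split-half consistency test. Comparing the
bootstrap distribution of the mean phase directly against a single
circularly-shifted null realization is not calibrated: a structureless
unit's noise peak is self-consistent within a session, so both
distributions are narrow at different arbitrary locations and the KS test
would always reject. Instead, each repeat splits the trials into disjoint
halves and records the wrapped difference between the halves' peak phases;
the null repeats the same computation with one half circularly shifted.
Landmark-locked units give near-zero differences against a broad null;
units without locking give matched distributions. The KS test between the
two difference distributions is calibrated for both cases.

## Distance coding

Single units: trial rates in a 100-ms window before joystick onset or
offset are sorted into 15 equal-count bins of produced vector length
(equal-count rather than equal-width guarantees occupancy) and the binned
means regressed on the binned lengths; significance by F-test at 95%
confidence, classification into onset/offset/both/none. The
cross-validated R² uses random split halves (20 repeats), a slope fitted on
the training half against the dummy distance regressor 1..5, and
R² = 1 − Σ(y_test − y_pred)² / Σ(y_test − ȳ_test)² on the held-out half
(negative for anti-predictive fits).

Population: targeted dimensionality reduction. Rates are centred per unit
across the two windows (−200 to 0 ms pre-onset; −500 to −300 ms
pre-offset); the per-time regression coefficient of centred rate on ordinal
distance is computed on a random half of trials (balanced over distances);
the time point with the maximal coefficient norm defines the unit-norm
coding axis; held-out trials are projected onto it, and 50 bootstrap
resamples of the projection-vs-distance R² quantify coding strength per
epoch.

The four-way ANOVA (distance, start landmark, target landmark, direction;
main effects only) uses type-II sums of squares because the factors are
inherently correlated (end landmarks participate in the longest distances).
Population contrasts are t-tests on per-unit F-statistic differences over
units with a significant effect of either factor, for both the mean rate
(−500 to −300 ms) and the within-window rate slope (−550 to −250 ms).

## Pair structure

For the top-K most periodic simultaneously recorded units (K = 20 → 190
pairs), the cross-correlogram of smoothed rates (5-ms bins, 100-ms kernel,
lags ±1.3 s) is computed per epoch; the per-pair summary is the zero-lag
Pearson correlation, with the CCG peak lag as the pair's relative phase.
Preservation across two epochs is the Pearson correlation of the per-pair
summaries; display rank order comes from the navigation epoch and is reused
for the comparison epoch. Inter-trial epochs reuse pooled segments of at
least 4 s.

## Continuous-attractor network

Architecture: five ring modules of 128 rate units with
difference-of-Gaussians connectivity whose outgoing centres are shifted in
the direction preferred by each unit (alternating ±); dynamics
τ dr/dt = −r + [W r + I]₊ with τ = 10 ms, integrated at dt = 0.5 ms. The
kernel's dominant spatial mode (k = 3 at the default widths) sets a
repeating-bump pattern; the pattern phase is read out in that Fourier mode,
and one full cycle (2π) is the phase-equivalent of one landmark step.
Velocity enters as a multiplicative modulation of the feedforward drive;
modules carry gains (0.4, 0.7, 1.0, 1.3, 2.1), chosen so that, at the
training speed, the mismatched modules' phases at landmark times are
incommensurate with the landmark sequence (commensurate ratios would leave
spurious structure in the learned weights).

Landmark learning: a landmark unit (LM) receives plastic weights from all
module units, updated at every time step by Oja's rule (η = 5 × 10⁻⁸,
required < 10⁻⁷ for stability) with weights centred at zero per module —
and, additionally, per direction subpopulation within each module, because
the two interleaved populations have different mean rates under strong
velocity drive and a scalar centre would leave that static offset in the
weights. During stage 1 (visually guided navigation) the LM response is
dominated by the external landmark pulses (0.65-s spacing): learning with
the internal drive included is self-amplifying and loses selectivity, so
the teacher signal is the supra-threshold external response. After stage 1,
the internal drive alone reproduces a pulse train at the landmark period
(stage 2), with weight energy concentrated (> 5×) in the module whose cycle
matches the landmark spacing. The LM's normalized output saturates at 1 — a
firing-rate ceiling, without which the feedback loop diverges while pinned.

Reset dynamics: during navigation with landmarks, the active LM pins the
pattern — its feedback through the (positive part of the) learned weights
stabilizes the attractor at the landmark phase, and it gates the velocity
drive (85% suppression at saturating LM activity). The pin releases by
short-term depression of the feedback synapse: the resource depletes with
τ = 0.15 s while the LM is active, recovers with τ = 0.06 s only once the
LM is quiet (so a released pin cannot re-arm while the bump is still inside
the well), and the feedback collapses regeneratively once the resource
crosses 15% — so the hold time is set by the depression clock rather than
by a force balance against the velocity drive. The resource diffuses
(0.6 /√s while engaged), making each release time independently jittered.

Noise model and why it matters. The velocity carries a per-trial Weber gain
(SD = weber × v, weber = 0.1) plus a small fast fluctuation
(Ornstein–Uhlenbeck, SD 0.9 × weber × v, correlation 20 ms). Without
landmarks the per-trial gain makes the produced duration's standard
deviation grow linearly with its mean — the scalar law. A constant
velocity misestimate cannot be corrected by any internal reset (there is no
within-trial time reference), so the landmark model's sub-linear growth
cannot come from the Weber component; it comes from the pinned fraction of
each cycle being insensitive to the velocity error while the stochastic
release contributes independent variability per landmark — the variance sum
law, σ² ∝ D. The depression-noise release is therefore a structural part of
the reset model, not a tuning convenience.

Calibration follows two grid searches: first the drive velocity at which
the operating (pinned) model's landmark period is 0.65 s. The period is
measured as the steady-state interval between reset events (each
simulation's first interval is discarded because starts are synchronized at
a landmark), using 12 simulations and two measurement repeats per grid
point with common random numbers; because the period–velocity curve is
nearly flat in the pinned regime, the target is found by inverting a
quadratic fit to the curve rather than by taking the noisiest grid point.
Second, for the landmark-free comparison, a per-distance velocity
equalizes the mean produced duration with the landmark model (a secant
search exploiting the near-reciprocal duration–velocity relation).
Landmark-free comparison runs share common random numbers across the five
distances — a variance-reduction device that leaves every marginal
distribution unchanged.

Variability scaling is summarized by fitting sd = a·mean^b + c across the
five distances (nonlinear least squares). With only five conditions the
offset trades off against the exponent, so c is restricted to
[0, 0.9 × min(sd)] — a nonnegative noise floor that cannot exceed the
smallest observed sd. The sampling distribution of b comes from 1,000
bootstrap resamples; when every simulation contributes a duration at every
distance, whole simulations are resampled jointly (preserving the
across-distance correlation structure), and a one-tailed t-test evaluates
H1: b < 1 against the scalar null H0: b = 1. The model Fano factor uses the
across-simulation mean and variance of every unit's activity on a 10-ms
grid (50 noisy simulations), pushed through the same ACG/PI procedure; the
dominant periodicity is summarized as the mean of per-unit PI peak lags
inside the central 0.4–0.9 s band, which excludes the harmonic and
subharmonic side modes of the per-unit peak distribution.

Typical desk-scale behaviour (5 × 128 units, 50 simulations): the reset
model's fitted exponent lands around b ≈ 0.6–0.95 and is reliably
sub-linear by the bootstrap test; the matched landmark-free model stays
within b ≈ 0.95–1.1; per-unit Fano periodicity concentrates at 0.63–0.67 s.

## Bayesian observers

Both observers measure the distance magnitude with scalar Gaussian noise
(SD w_m·d — the measurement law is not further specified by the framework,
so the standard scalar form is used and w_m is reported but not
interpreted), combine it with the task prior, and take the posterior mean
t_e (Bayes least squares). Production adds Gaussian noise with
σ = w_p·t_e (scalar observer — no resets) or σ = w_p·√t_o·√t_e
(subscalar observer — the epoch is divided into base-interval segments
whose variances add: σ² = (w_p t_o)²D). An offset b shifts the production
mean. The two observers coincide at D = 1.

Fitting is maximum likelihood: the per-trial density marginalizes the
unobserved measurement on a 501-point grid spanning ±5 measurement SDs
(trapezoidal; checked against a 10× finer grid at < 10⁻⁶ relative error),
optimized by bounded L-BFGS-B from a fixed 27-point multi-start grid, so
results are deterministic. Standard errors come from the observed
information. Outliers are removed first with a per-condition mixture of a
task Gaussian and a uniform lapse on [0, 3|v_a|] (EM; trials with lapse
responsibility > 0.5 dropped; the datum-dependent support [0, 3|v_p|] is
available behind a flag but is improper as a fixed mixture component).
Model comparison fits both observers per session and applies a paired
t-test across sessions on the per-trial mean log-likelihood; a
bias-plus-variance RMSE metric is available as an alternative. Directions
are pooled into one prior over magnitudes.

## Synthetic data: what it emulates, what it does not

Behavioural sessions draw produced vectors from an observer model over the
task prior, lay out go-cue/onset/offset timestamps sequentially, and draw
inter-trial intervals uniformly from 0.5–1.0 s, extended to 4–6 s on ~35%
of trials (mimicking slow fixation re-acquisition) to provide the long
control segments the epoch analyses need.

Spiking units are inhomogeneous-Poisson with a phenomenological rate:
baseline + distance-independent ramp + Gaussian bumps (default width 80 ms,
amplitude 30 Hz on an 8-Hz baseline for the canonical periodic class)
anchored to joystick offset at 0.65-s spacing with per-trial jitter
(SD 20 ms) + an anticipatory half-Gaussian burst peaking at the offset.
The `jitter_reset` class has a flat mean rate but a multiplicative
log-Brownian gain that collapses to zero at each landmark time (with the
exact mean correction, so the expected rate stays flat): across-trial
variance rises within each inter-landmark interval and resets at its
boundary, producing a periodic Fano factor without periodic mean activity —
the dissociation the Fano analysis is designed to detect.

What passing tests on these generators establish: that each analysis
recovers the structure it targets at realistic rates, trial counts and
noise levels, with calibrated false-positive behaviour on matched nulls.
What they do not establish: robustness to non-Poisson firing, to
correlated noise across units beyond the planted structure, to non-Gaussian
bump shapes, or to the behavioural idiosyncrasies of real sessions
(direction errors, motivation drifts, attempts at correction). Bump widths
and amplitudes of real entorhinal units are not constrained by the
implemented analyses; the generator defaults are working values, not claims
about data.

## Problem sizes

Default analysis scales were chosen to make the full suite reproducible on
a single CPU: 50-unit populations with 40 trials per unit and 200 surrogate
repeats for periodicity classification; 100 bootstrap repeats for phases;
20 sessions of 200 trials for observer model recovery (500 trials for
parameter recovery); the 5 × 128-unit network with 50 noisy simulations and
1,000 bootstrap power-law fits. All generators and analyses take explicit
seeds and are bit-reproducible given (configuration, seed).

## Known limitations

- The PI peak inherits a small (−0.02 to −0.03 s) inward bias from the
  biased ACG estimator at realistic noise; tolerances account for it.
- The power-law exponent b is weakly identified from five conditions; its
  bootstrap distribution (not the point estimate alone) carries the
  inference.
- The CAN operates in a strongly pinned regime; the period–velocity curve
  is flat there, so the calibrated velocity is a set-valued choice and the
  reported exponent varies by ±0.15 across noise seeds.
- The split-half phase test trades some power for calibration; weakly
  periodic units may not be retained.
- NWB input is not supported; sessions travel as CSV/JSON.
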