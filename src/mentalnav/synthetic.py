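"""Seeded generators for behavioural sessions and spike-train populations.

These generators produce data with the statistical structure the analysis
modules assume: sessions of trials drawn from the generative observer models
over the landmark-task prior, and inhomogeneous-Poisson spike trains with
landmark-locked activity bumps (0.65 s spacing by default), distance-scaled
ramps, anticipatory pre-offset bursts, and trial-to-trial jitter mechanisms
that induce a periodic Fano factor with or without a periodic mean rate.

Everything is bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .observer import ObserverParams, TaskPrior, simulate_trials
from .task import LandmarkLine, NeuronSession, TrialCondition, enumerate_conditions, reward_outcome

__all__ = [
    "NeuronSpec",
    "PopulationSpec",
    "gen_behavior_session",
    "gen_spike_session",
    "gen_gp_surrogate",
    "gen_paired_population",
]

_DT = 0.001  # spike-generation grid, seconds


@dataclass(frozen=True)
class NeuronSpec:
    """Phenomenological rate model of one unit.

    ``cls`` is one of {"periodic", "ramping", "periodic_ramping",
    "offset_burst", "untuned", "jitter_reset"}.  Bumps are Gaussian in time
    (default width 80 ms), spaced ``bump_spacing`` apart and anchored to
    joystick offset by default; ``phase`` shifts the bump train.  The
    ``jitter_reset`` class has a flat mean rate but a multiplicative gain
    driven by Brownian noise that collapses to zero at every landmark time,
    which produces a periodic Fano factor without periodic mean activity.
    """

    cls: str = "periodic"
    baseline: float = 8.0           # Hz
    bump_amp: float = 25.0          # Hz
    bump_width: float = 0.08        # s (Gaussian SD)
    bump_spacing: float = 0.65      # s, defaults to t_o
    anchor: str = "offset"
    phase: float = 0.0              # s, shift of the bump train
    ramp_slope: float = 0.0         # Hz/s from joystick onset
    burst_amp: float = 0.0          # anticipatory half-Gaussian peak at offset
    burst_width: float = 0.12       # s
    jitter_sd: float = 0.02         # s, per-trial bump-train jitter
    gain_noise: float = 0.0         # Brownian gain noise rate (jitter_reset)
    jitter_reset: bool = False

    def with_(self, **kw) -> "NeuronSpec":
        return replace(self, **kw)


def make_class_spec(cls: str, **kw) -> NeuronSpec:
    """Convenience constructors for the canonical unit classes."""
    presets = {
        "periodic": dict(cls="periodic", bump_amp=30.0),
        "ramping": dict(cls="ramping", bump_amp=0.0, ramp_slope=6.0),
        "periodic_ramping": dict(cls="periodic_ramping", bump_amp=18.0, ramp_slope=5.0),
        "offset_burst": dict(cls="offset_burst", bump_amp=0.0, burst_amp=30.0),
        "untuned": dict(cls="untuned", bump_amp=0.0),
        "jitter_reset": dict(cls="jitter_reset", bump_amp=0.0,
                             gain_noise=1.2, jitter_reset=True),
    }
    if cls not in presets:
        raise ValueError(f"unknown unit class {cls!r}")
    return NeuronSpec(**{**presets[cls], **kw})


@dataclass
class PopulationSpec:
    """A list of unit specs plus shared-phase structure for pair analyses."""

    neurons: list[NeuronSpec]
    seed: int = 0

    @classmethod
    def from_fractions(
        cls, n: int, fractions: dict[str, float], seed: int = 0, **kw
    ) -> "PopulationSpec":
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        rng = np.random.default_rng(seed)
        names = list(fractions)
        counts = np.floor(np.array([fractions[k] for k in names]) * n).astype(int)
        while counts.sum() < n:
            counts[int(rng.integers(len(names)))] += 1
        specs = []
        for name, c in zip(names, counts):
            for _ in range(c):
                phase = float(rng.uniform(0, 0.65))
                specs.append(make_class_spec(name, phase=phase, **kw))
        return cls(specs, seed=seed)


def gen_behavior_session(
    observer: ObserverParams,
    conditions: list[TrialCondition] | None = None,
    n_trials: int = 200,
    seed: int = 0,
    session_id: str = "s0",
    prior: TaskPrior | None = None,
    long_iti_prob: float = 0.35,
) -> pd.DataFrame:
    """One session of trials with event timestamps.

    Produced vectors are drawn from the observer model; timestamps are laid
    out sequentially with a uniform 500-1,000 ms inter-trial interval.  With
    probability ``long_iti_prob`` the ITI is extended to 4-6 s (mimicking
    slow fixation re-acquisition), which provides the long inter-trial
    segments used as the non-navigation control epoch.
    """
    rng = np.random.default_rng(seed)
    prior = prior or TaskPrior()
    if conditions is None:
        conditions = enumerate_conditions(LandmarkLine(t_o=prior.t_o))
    draws = simulate_trials(observer, prior, n=n_trials,
                            seed=int(rng.integers(2**31 - 1)),
                            conditions=conditions)
    t = 1.0
    rows = []
    for _, r in draws.iterrows():
        t_go = t + rng.uniform(0.4, 1.4)       # landmark presentation epoch
        t_on = t_go + rng.uniform(0.25, 0.4)   # reaction time
        t_off = t_on + abs(r["v_p"])
        rewarded, _ = reward_outcome(r["v_p"], r["v_a"])
        rows.append(
            dict(session_id=session_id, start=int(r["start"]), target=int(r["target"]),
                 v_a=r["v_a"], v_p=r["v_p"], t_go=t_go, t_on=t_on, t_off=t_off,
                 n_attempts=1 if rewarded else 2, rewarded=rewarded)
        )
        iti = rng.uniform(4.0, 6.0) if rng.random() < long_iti_prob else rng.uniform(0.5, 1.0)
        t = t_off + iti
    return pd.DataFrame(rows)


def iti_segments_from_trials(trials: pd.DataFrame, min_len: float = 4.0) -> list:
    """Inter-trial (offset -> next go cue) stretches at least ``min_len`` long."""
    segs = []
    t_off = trials["t_off"].to_numpy(float)
    t_go = trials["t_go"].to_numpy(float)
    for a, b in zip(t_off[:-1], t_go[1:]):
        if b - a >= min_len:
            segs.append((a + 0.2, b - 0.2))
    return segs


def _trial_rate(spec: NeuronSpec, t: np.ndarray, t_on: float, t_off: float,
                rng: np.random.Generator) -> np.ndarray:
    """Rate trace (Hz) on absolute-time grid ``t`` covering one trial."""
    rate = np.full(t.size, float(spec.baseline))
    rate += spec.ramp_slope * np.clip(t - t_on, 0, None)
    if spec.bump_amp > 0:
        jit = rng.normal(0, spec.jitter_sd) if spec.jitter_sd > 0 else 0.0
        anchor_t = t_off if spec.anchor == "offset" else t_on
        step = spec.bump_spacing if spec.anchor == "onset" else -spec.bump_spacing
        # bump centres walking away from the anchor across the trial
        k = np.arange(0, int(np.ceil((t_off - t_on) / spec.bump_spacing)) + 2)
        centers = anchor_t + step * k + (spec.phase if spec.anchor == "onset" else -spec.phase) + jit
        centers = centers[(centers > t_on - 0.2) & (centers < t_off + 0.2)]
        for c in centers:
            rate += spec.bump_amp * np.exp(-0.5 * ((t - c) / spec.bump_width) ** 2)
    if spec.burst_amp > 0:
        pre = t <= t_off
        rate[pre] += spec.burst_amp * np.exp(-0.5 * ((t[pre] - t_off) / spec.burst_width) ** 2)
    if spec.jitter_reset and spec.gain_noise > 0:
        # Brownian log-gain that collapses to zero at each landmark time
        # (boundaries anchored to joystick offset); the exact mean correction
        # keeps the expected rate flat while the across-trial variance rises
        # within each inter-landmark interval and resets at its start.
        dt = t[1] - t[0]
        seg_edges = np.arange(t_off, t_on - spec.bump_spacing, -spec.bump_spacing)[::-1]
        seg_id = np.searchsorted(seg_edges, t, side="right")
        dW = rng.normal(0, np.sqrt(dt), size=t.size)
        B = np.cumsum(dW)
        elapsed = np.empty(t.size)
        for s in np.unique(seg_id):
            m = seg_id == s
            i0 = np.argmax(m)
            B[m] -= B[i0]
            elapsed[m] = t[m] - t[i0]
        g = np.exp(spec.gain_noise * B - 0.5 * spec.gain_noise**2 * elapsed)
        rate = rate * g
    return np.clip(rate, 0, None)


def gen_spike_session(
    pop: PopulationSpec,
    trials: pd.DataFrame,
    seed: int = 0,
    pad: float = 0.6,
    group: str = "g0",
) -> list[NeuronSession]:
    """Inhomogeneous-Poisson spike trains for a population over a session.

    Within each trial (plus ``pad`` seconds either side) spikes follow the
    unit's structured rate; elsewhere they are homogeneous at the unit's
    baseline.  Requested rates are rectified at zero.
    """
    rng = np.random.default_rng(seed)
    t_on = trials["t_on"].to_numpy(float)
    t_off = trials["t_off"].to_numpy(float)
    session_end = float(trials["t_off"].iloc[-1] + 2.0)
    itis = iti_segments_from_trials(trials)

    sessions = []
    for j, spec in enumerate(pop.neurons):
        nrng = np.random.default_rng(rng.integers(2**31 - 1))
        spikes = []
        # baseline spiking over the whole session
        n_base = nrng.poisson(spec.baseline * session_end)
        base = np.sort(nrng.uniform(0, session_end, n_base))
        # structured rate within trials: thin/augment relative to baseline by
        # regenerating each trial window from the full rate profile
        for a, b in zip(t_on, t_off):
            lo, hi = a - pad, b + pad
            base = base[(base < lo) | (base >= hi)]
        spikes.append(base)
        for a, b in zip(t_on, t_off):
            lo, hi = a - pad, b + pad
            t = np.arange(lo, hi, _DT)
            rate = _trial_rate(spec, t, a, b, nrng)
            counts = nrng.poisson(rate * _DT)
            idx = np.repeat(np.arange(t.size), counts)
            spikes.append(t[idx] + nrng.uniform(0, _DT, idx.size))
        sessions.append(
            NeuronSession(f"n{j:03d}", np.concatenate(spikes), trials,
                          group=group, iti_segments=itis)
        )
    return sessions


def sample_gp(duration: float, n: int, rng: np.random.Generator,
              length_constant: float = 0.1, max_variance: float = 1.0,
              dt: float = _DT) -> tuple[np.ndarray, np.ndarray]:
    """Samples of a zero-mean squared-exponential GP on a regular grid.

    Realized by convolving white noise with a Gaussian filter of SD
    ``length_constant / sqrt(2)``: the resulting covariance is exactly
    ``max_variance * exp(-tau^2 / (2 * length_constant^2))``.
    """
    from scipy.ndimage import gaussian_filter1d

    m = int(np.round(duration / dt))
    sigma_bins = length_constant / np.sqrt(2) / dt
    pad = int(np.ceil(6 * sigma_bins))
    w = rng.standard_normal((n, m + 2 * pad))
    g = gaussian_filter1d(w, sigma_bins, axis=1, mode="constant")[:, pad:pad + m]
    # unit variance after filtering: ||kernel||_2 for a discrete Gaussian
    norm = 1.0 / np.sqrt(2 * np.sqrt(np.pi) * sigma_bins)
    g = g / norm * np.sqrt(max_variance)
    t = np.arange(m) * dt
    return t, g


def gen_gp_surrogate(
    duration: float,
    n: int = 1,
    seed: int | np.random.Generator = 0,
    length_constant: float = 0.1,
    max_variance: float = 1.0,
    mean_rate: float = 20.0,
) -> list[np.ndarray]:
    """Surrogate spike trains from a GP intensity via a Poisson process.

    The GP sample ``g(t)`` is mapped to a nonnegative intensity with an
    exponential link, ``r(t) = r0 * exp(g(t)) / E[exp(g)]``, so the expected
    rate equals ``mean_rate``; spikes are then drawn as an inhomogeneous
    Poisson process.  The GP's length constant (100 ms default) matches the
    smoothing kernel used on real rates, so surrogates share its smoothness.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, g = sample_gp(duration, n, rng, length_constant, max_variance)
    rate = mean_rate * np.exp(g) / np.exp(max_variance / 2)
    counts = rng.poisson(rate * _DT)
    out = []
    for i in range(n):
        idx = np.repeat(np.arange(t.size), counts[i])
        out.append(t[idx] + rng.uniform(0, _DT, idx.size))
    return out


def gen_paired_population(
    pop: PopulationSpec,
    epochs: tuple[str, ...] = ("MNAV", "ITI", "inference"),
    preserve_phases: bool = True,
    seed: int = 0,
    duration: float = 60.0,
    t_o: float = 0.65,
) -> dict[str, list[np.ndarray]]:
    """The same units simulated across task epochs, for pair analyses.

    Each unit fires Gaussian bumps at period ``t_o`` with a unit-specific
    phase offset.  With ``preserve_phases`` the phase is kept across epochs
    (the attractor regime); otherwise phases are re-drawn per epoch
    (scrambled control).  Returns, per epoch, one continuous spike train per
    unit (duration seconds).
    """
    rng = np.random.default_rng(seed)
    base_phases = np.array([s.phase for s in pop.neurons])
    out = {}
    for e, epoch in enumerate(epochs):
        erng = np.random.default_rng(rng.integers(2**31 - 1))
        phases = base_phases if preserve_phases else erng.uniform(0, t_o, len(pop.neurons))
        trains = []
        t = np.arange(0.0, duration, _DT)
        # common multiplicative drift makes rate correlations well-defined
        from scipy.ndimage import gaussian_filter1d

        drift = gaussian_filter1d(erng.standard_normal(t.size), 500, mode="constant")
        drift = 1.0 + 0.3 * drift / max(drift.std(), 1e-12)
        for spec, ph in zip(pop.neurons, phases):
            frac = ((t - ph) / t_o) % 1.0
            dist = np.minimum(frac, 1 - frac) * t_o
            rate = spec.baseline + spec.bump_amp * np.exp(-0.5 * (dist / spec.bump_width) ** 2)
            rate = np.clip(rate * drift, 0, None)
            counts = erng.poisson(rate * _DT)
            idx = np.repeat(np.arange(t.size), counts)
            trains.append(t[idx] + erng.uniform(0, _DT, idx.size))
        out[epoch] = trains
    return out
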