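"""Task geometry, trial data model, behavioural metrics and rate preprocessing.

The task is one-dimensional mental navigation along a line of ``n_landmarks``
equidistant landmark images.  At a fixed display speed, adjacent landmarks are
separated by a temporal distance ``t_o`` (0.65 s by default).  On each trial
the subject holds a joystick deflected to produce a signed displacement vector
``v_p`` that should match the actual start-to-target vector ``v_a``; rightward
vectors are positive.

All within-trial times are in seconds.  Analysis windows are expressed as
signed offsets relative to joystick onset or offset, with half-open
``[a, b)`` convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "LandmarkLine",
    "TrialCondition",
    "TrialRecord",
    "NeuronSession",
    "RateMatrix",
    "actual_vector",
    "enumerate_conditions",
    "balanced_split",
    "reward_outcome",
    "performance_slope",
    "smooth_rates",
    "warp_average",
    "TRIAL_COLUMNS",
]

#: canonical column order for trial tables on disk
TRIAL_COLUMNS = [
    "session_id", "start", "target", "v_a", "v_p",
    "t_go", "t_on", "t_off", "n_attempts", "rewarded",
]


@dataclass(frozen=True)
class LandmarkLine:
    """Geometry of the landmark line.

    Parameters
    ----------
    n_landmarks : int
        Number of equidistant landmark images (>= 2).
    t_o : float
        Inter-landmark temporal distance in seconds (> 0).
    speed : float
        Display translation speed in display units per second.  Metadata
        only; every analysis works in temporal units.
    """

    n_landmarks: int = 6
    t_o: float = 0.65
    speed: float = 10.0

    def __post_init__(self):
        if self.n_landmarks < 2:
            raise ValueError("a landmark line needs at least 2 landmarks")
        if self.t_o <= 0:
            raise ValueError("inter-landmark interval t_o must be positive")


@dataclass(frozen=True)
class TrialCondition:
    """One start->target pair; ``v_a`` is the signed actual vector."""

    start: int
    target: int
    t_o: float = 0.65

    def __post_init__(self):
        if self.start == self.target:
            raise ValueError("start and target landmarks must differ")

    @property
    def v_a(self) -> float:
        return (self.target - self.start) * self.t_o

    @property
    def direction(self) -> int:
        """+1 for rightward (target right of start), -1 for leftward."""
        return 1 if self.target > self.start else -1

    @property
    def distance(self) -> int:
        """Ordinal distance ``D`` = number of inter-landmark steps."""
        return abs(self.target - self.start)


@dataclass
class TrialRecord:
    """One behavioural trial.

    ``t_go``, ``t_on`` and ``t_off`` are session timestamps of the go cue and
    joystick onset/offset.  Trials with ``n_attempts > 1`` are treated as
    error trials throughout.
    """

    condition: TrialCondition
    v_p: float
    t_go: float
    t_on: float
    t_off: float
    n_attempts: int = 1
    rewarded: bool = True
    session_id: str = "s0"

    def __post_init__(self):
        if self.t_off <= self.t_on:
            raise ValueError("joystick offset must follow onset")

    @property
    def is_error(self) -> bool:
        return self.n_attempts > 1

    @property
    def produced_duration(self) -> float:
        return self.t_off - self.t_on


@dataclass
class NeuronSession:
    """Spike times of one unit across a behavioural session.

    ``spike_times`` are absolute session timestamps (seconds); ``trials`` is
    a trial table carrying at least ``t_on``/``t_off`` (joystick onset and
    offset) plus condition columns.  ``group`` identifies simultaneously
    recorded units for pair analyses; ``iti_segments`` are pooled inter-trial
    stretches (start, stop) usable as a non-navigation control epoch.
    """

    neuron_id: str
    spike_times: np.ndarray
    trials: pd.DataFrame
    group: str = "g0"
    iti_segments: list = field(default_factory=list)

    def __post_init__(self):
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))

    def select(self, mask) -> "NeuronSession":
        """Same unit restricted to a subset of trials."""
        return NeuronSession(
            self.neuron_id, self.spike_times,
            self.trials[np.asarray(mask)].reset_index(drop=True),
            self.group, self.iti_segments,
        )

    def aligned_spikes(
        self, align: str = "onset", window: tuple[float, float] = (0.0, None)
    ) -> list[np.ndarray]:
        """Per-trial spike times relative to the alignment event.

        ``window=(a, b)`` is relative to the event, half-open ``[a, b)``.
        ``b=None`` extends to the other joystick event (onset <-> offset).
        """
        ev = self.trials["t_on"] if align == "onset" else self.trials["t_off"]
        other = self.trials["t_off"] if align == "onset" else self.trials["t_on"]
        out = []
        for e, o in zip(ev.to_numpy(float), other.to_numpy(float)):
            a, b = window
            lo = e + a
            hi = o if b is None else e + b
            sel = self.spike_times[(self.spike_times >= lo) & (self.spike_times < hi)]
            out.append(sel - e)
        return out


@dataclass
class RateMatrix:
    """Per-trial firing-rate traces on a common time base.

    ``rates`` has shape (n_trials, n_bins); ``time`` gives the left edge of
    each bin relative to the alignment event.  ``stretch`` records the
    per-trial time-warp factor applied (1.0 when no warping).
    """

    rates: np.ndarray
    time: np.ndarray
    bin_width: float
    align: str = "onset"
    stretch: np.ndarray | None = None

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.rates.ndim == 1:
            self.rates = self.rates[None, :]
        if self.stretch is None:
            self.stretch = np.ones(self.rates.shape[0])

    def mean(self) -> np.ndarray:
        return self.rates.mean(axis=0)


def actual_vector(start: int, target: int, line: LandmarkLine | None = None) -> float:
    """Signed actual vector ``v_a`` (seconds) between two landmarks.

    Positive values are rightward.  A zero vector (start == target) is not a
    task condition and is rejected.
    """
    line = line or LandmarkLine()
    for name, k in (("start", start), ("target", target)):
        if not 1 <= k <= line.n_landmarks:
            raise ValueError(f"{name} landmark {k} outside 1..{line.n_landmarks}")
    if start == target:
        raise ValueError("start and target landmarks must differ")
    return (target - start) * line.t_o


def enumerate_conditions(line: LandmarkLine | None = None) -> list[TrialCondition]:
    """All ordered pairs of distinct landmarks: ``n * (n - 1)`` conditions."""
    line = line or LandmarkLine()
    return [
        TrialCondition(s, t, line.t_o)
        for s, t in itertools.permutations(range(1, line.n_landmarks + 1), 2)
    ]


def balanced_split(
    conditions: Sequence[TrialCondition],
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[list[TrialCondition], list[TrialCondition]]:
    """Split conditions into two disjoint halves balanced in direction and distance.

    Seeded rejection sampling over random partitions: a candidate split is
    accepted when, for every ordinal distance and for each direction, the two
    halves differ by at most one condition.  Mirrors the training/held-out
    generalization design (15 + 15 for the 6-landmark line).
    """
    conditions = list(conditions)
    n = len(conditions)
    half = n // 2
    rng = np.random.default_rng(seed)

    def counts(subset):
        dist = {}
        ndir = {1: 0, -1: 0}
        for c in subset:
            dist[c.distance] = dist.get(c.distance, 0) + 1
            ndir[c.direction] += 1
        return dist, ndir

    for _ in range(max_tries):
        idx = rng.permutation(n)
        a = [conditions[i] for i in idx[:half]]
        b = [conditions[i] for i in idx[half:]]
        da, na = counts(a)
        db, nb = counts(b)
        dists = set(da) | set(db)
        if any(abs(da.get(d, 0) - db.get(d, 0)) > 1 for d in dists):
            continue
        if any(abs(na[s] - nb[s]) > 1 for s in (1, -1)):
            continue
        return a, b
    raise RuntimeError(
        f"no balanced split found in {max_tries} tries; constraints may be infeasible"
    )


def reward_outcome(
    v_p: float,
    v_a: float,
    criterion: float = 0.08,
    rule: str = "relative_fixed_0.08",
) -> tuple[bool, float]:
    """Reward flag and graded reward fraction for a produced vector.

    Relative error is ``|v_p - v_a| / |v_a|``.  Under ``relative_fixed_0.08``
    the trial is rewarded when the relative error is below ``criterion`` (an
    8% window); under ``relative_scaled`` the threshold is additionally
    scaled by ``|v_a|`` (criterion * |v_a|), the literal reading of the
    stated rule.  Reward decreases linearly with relative error within the
    window.  A direction (sign) mismatch is never rewarded.
    """
    if v_a == 0:
        raise ValueError("v_a must be nonzero")
    if np.sign(v_p) != np.sign(v_a):
        return False, 0.0
    rel_err = abs(v_p - v_a) / abs(v_a)
    if rule == "relative_fixed_0.08":
        thresh = criterion
    elif rule == "relative_scaled":
        thresh = criterion * abs(v_a)
    else:
        raise ValueError(f"unknown reward rule {rule!r}")
    rewarded = rel_err < thresh
    fraction = float(np.clip(1.0 - rel_err / thresh, 0.0, 1.0)) if rewarded else 0.0
    return rewarded, fraction


def performance_slope(
    trials: pd.DataFrame | Iterable[TrialRecord],
    criterion: float = 0.8,
) -> dict:
    """OLS regression of produced on actual vectors.

    Returns slope, intercept, the 95% CI on the slope, and whether the slope
    meets the training criterion (0.8).  Accepts a trial DataFrame with
    ``v_a``/``v_p`` columns or an iterable of :class:`TrialRecord`.
    """
    import statsmodels.api as sm

    if isinstance(trials, pd.DataFrame):
        v_a = trials["v_a"].to_numpy(float)
        v_p = trials["v_p"].to_numpy(float)
    else:
        trials = list(trials)
        v_a = np.array([t.condition.v_a for t in trials])
        v_p = np.array([t.v_p for t in trials])
    if np.unique(v_a).size < 2:
        raise ValueError("need at least two distinct v_a values for a slope")
    res = sm.OLS(v_p, sm.add_constant(v_a)).fit()
    ci = res.conf_int(alpha=0.05)
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "slope_ci": (float(ci[1][0]), float(ci[1][1])),
        "meets_criterion": bool(res.params[1] >= criterion),
        "r2": float(res.rsquared),
    }


def smooth_rates(
    spike_trains: Sequence[np.ndarray],
    t_start: float,
    t_stop: float,
    bin_width: float = 0.001,
    kernel_sd: float = 0.1,
) -> RateMatrix:
    """Smoothed firing rates from spike times.

    Spike counts in ``bin_width`` bins (1 ms default) are convolved with a
    Gaussian kernel (SD 100 ms default) and scaled to Hz.  Empty trains give
    a zero trace.  Times are relative to the trial's alignment event; the
    time base covers ``[t_start, t_stop)``.
    """
    edges = np.arange(t_start, t_stop + bin_width / 2, bin_width)
    time = edges[:-1]
    traces = np.zeros((len(spike_trains), time.size))
    for i, st in enumerate(spike_trains):
        st = np.asarray(st, dtype=float)
        if st.size:
            traces[i], _ = np.histogram(st, bins=edges)
    sigma_bins = kernel_sd / bin_width
    traces = gaussian_filter1d(traces, sigma_bins, axis=1, mode="constant")
    return RateMatrix(traces / bin_width, time, bin_width)


def warp_average(
    rates: Sequence[np.ndarray],
    durations: Sequence[float],
    bin_width: float,
    target_bin: float = 0.040,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-warped condition average of per-trial rate traces.

    Each trial's trace (sampled at ``bin_width``, spanning that trial's
    produced duration) is linearly rescaled to the condition's median
    duration, rebinned at ``target_bin`` (40 ms default), then averaged.
    Zero-duration trials are excluded.

    Returns (average trace, time base of the median-duration trial,
    per-trial stretch factors).
    """
    durations = np.asarray(durations, dtype=float)
    keep = durations > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding {int((~keep).sum())} zero-duration trial(s)")
    rates = [r for r, k in zip(rates, keep) if k]
    durations = durations[keep]
    if len(rates) == 0:
        raise ValueError("no usable trials")

    med = float(np.median(durations))
    n_out = int(np.ceil(med / target_bin))
    t_out = (np.arange(n_out) + 0.5) * target_bin  # bin centres on median base
    stretch = durations / med

    warped = np.empty((len(rates), n_out))
    for i, (trace, dur) in enumerate(zip(rates, durations)):
        trace = np.asarray(trace, dtype=float)
        t_trial = (np.arange(trace.size) + 0.5) * bin_width
        # map median-base time -> this trial's own time axis
        warped[i] = np.interp(t_out * stretch[i], t_trial, trace)
    return warped.mean(axis=0), t_out, stretch
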