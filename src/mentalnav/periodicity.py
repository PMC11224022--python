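"""Autocorrelogram periodicity index, surrogate nulls, ramping and Fano analyses.

The periodicity index (PI) is a one-dimensional, lag-domain analogue of the
gridness score.  Pipeline per unit:

1. pool trials requiring navigation over at least three landmarks;
2. truncate each trial 500 ms before joystick offset (removes the large
   anticipatory response);
3. linearly detrend each trial's smoothed firing rate (so ramps do not mask
   periodicity);
4. average the per-trial normalized autocorrelation functions over lags
   0-2,400 ms into a mean ACG (ACG(0) = 1);
5. for candidate lags 0-1,300 ms, correlate the ACG with its lag-shifted
   copy over the overlapping support, and define
   ``PI(tau) = corr(ACG, shift(tau)) - corr(ACG, shift(tau / 2))``.

A periodic unit has PI maximal at the true period (positive correlation at a
full period, negative at the half period).  Significance is assessed against
surrogate spike trains drawn from a squared-exponential Gaussian-process
intensity (length constant equal to the 100-ms smoothing kernel, mean rate
matched to the unit) passed through an inhomogeneous Poisson process: a unit
is periodic when its maximal PI exceeds the surrogate mean by two standard
deviations and more than 15 trials were pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .synthetic import gen_gp_surrogate
from .task import NeuronSession, smooth_rates

__all__ = [
    "PIResult",
    "FanoResult",
    "compute_acg",
    "periodicity_index",
    "shifted_acg_correlation",
    "classify_periodic",
    "ramping_test",
    "epoch_outcome_comparison",
    "fano_periodicity",
]

_DT = 0.001        # spike-rate grid for smoothing, s
ACG_DT = 0.005     # ACG/PI lag grid, s (the 100-ms kernel makes 1 ms redundant)
ACG_MAX_LAG = 2.4
PI_MAX_LAG = 1.3
MIN_OVERLAP = 10


@dataclass
class PIResult:
    """Periodicity analysis of one unit."""

    acg: np.ndarray
    acg_lags: np.ndarray
    pi_curve: np.ndarray
    pi_lags: np.ndarray
    n_trials: int
    null_mean: float = np.nan
    null_sd: float = np.nan
    significant: bool = False
    peak_lag: float = np.nan
    reason: str = ""

    @property
    def max_pi(self) -> float:
        if np.all(np.isnan(self.pi_curve)):
            return np.nan
        return float(np.nanmax(self.pi_curve))


@dataclass
class FanoResult:
    """Fano-factor time course and its periodicity."""

    fano: np.ndarray
    time: np.ndarray
    pi: PIResult | None
    null_mean: float = np.nan
    null_sd: float = np.nan
    significant: bool = False
    peak_lag: float = np.nan


# ---------------------------------------------------------------------------
# ACG

def _trial_acgs(traces: list[np.ndarray], dt: float, max_lag: float) -> np.ndarray:
    """Per-trial normalized autocorrelations (rows), NaN beyond each trial's
    support.  Each trace is linearly detrended first."""
    n_lag = int(round(max_lag / dt)) + 1
    out = np.full((len(traces), n_lag), np.nan)
    for i, x in enumerate(traces):
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            continue
        x = signal.detrend(x, type="linear")
        denom = float(x @ x)
        if denom <= 0:
            out[i, : min(n_lag, x.size)] = 0.0
            out[i, 0] = 1.0
            continue
        m = min(n_lag, x.size)
        # zero-padded FFT autocorrelation == sum_i x_i x_{i+tau}
        nfft = int(2 ** np.ceil(np.log2(2 * x.size)))
        f = np.fft.rfft(x, nfft)
        ac = np.fft.irfft(f * np.conj(f), nfft)[:m]
        out[i, :m] = ac / denom
    return out


def compute_acg(
    neuron: NeuronSession,
    min_distance: int = 3,
    truncate_pre_offset: float = 0.5,
    kernel_sd: float = 0.1,
    max_lag: float = ACG_MAX_LAG,
    trial_mask=None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Trial-averaged ACG of detrended smoothed firing rate.

    Pools trials with ordinal distance >= ``min_distance``, truncated
    ``truncate_pre_offset`` seconds before joystick offset.  Returns
    (mean ACG, lags in seconds, number of pooled trials); the mean at each
    lag averages the trials whose truncated duration supports that lag.
    """
    tr = neuron.trials
    dist = (tr["target"] - tr["start"]).abs() if "target" in tr else tr["distance"]
    mask = (dist >= min_distance).to_numpy()
    if trial_mask is not None:
        mask &= np.asarray(trial_mask)
    durations = (tr["t_off"] - tr["t_on"]).to_numpy(float) - truncate_pre_offset
    mask &= durations > 0.2
    n_trials = int(mask.sum())
    lags = np.arange(0, int(round(max_lag / ACG_DT)) + 1) * ACG_DT
    if n_trials == 0:
        return np.full(lags.size, np.nan), lags, 0

    sub = neuron.select(mask)
    step = int(round(ACG_DT / _DT))
    traces = []
    for spikes, dur in zip(sub.aligned_spikes("onset"), durations[mask]):
        rm = smooth_rates([spikes[spikes < dur]], 0.0, dur, kernel_sd=kernel_sd)
        traces.append(rm.rates[0][::step])
    acgs = _trial_acgs(traces, ACG_DT, max_lag)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_acg = np.nanmean(acgs, axis=0)
    return mean_acg, lags, n_trials


def acg_of_trace(x: np.ndarray, dt: float = ACG_DT, max_lag: float = ACG_MAX_LAG) -> tuple[np.ndarray, np.ndarray]:
    """Detrended normalized autocorrelation of a single time course."""
    acgs = _trial_acgs([np.asarray(x, dtype=float)], dt, max_lag)
    lags = np.arange(acgs.shape[1]) * dt
    return acgs[0], lags


# ---------------------------------------------------------------------------
# periodicity index

def shifted_acg_correlation(acg: np.ndarray) -> np.ndarray:
    """Pearson correlation of a trace with its tau-shifted copy, all shifts.

    ``C[tau] = corr(x[:L-tau], x[tau:])`` over the overlapping support, for
    ``tau = 0..L-1``, vectorized with running sums.  Entries with overlap
    below ``MIN_OVERLAP`` samples or degenerate variance are NaN.
    Accepts a 1D trace or a (batch, L) array.
    """
    x = np.atleast_2d(np.asarray(acg, dtype=float))
    B, L = x.shape
    valid_len = np.full(B, L)
    # NaN tails (variable trial support): truncate at first NaN per row
    for i in range(B):
        bad = np.flatnonzero(np.isnan(x[i]))
        if bad.size:
            valid_len[i] = bad[0]
    out = np.full((B, L), np.nan)
    for i in range(B):
        xi = x[i, : valid_len[i]]
        Li = xi.size
        if Li < MIN_OVERLAP:
            continue
        nfft = int(2 ** np.ceil(np.log2(2 * Li)))
        f = np.fft.rfft(xi, nfft)
        sxy = np.fft.irfft(f * np.conj(f), nfft)[:Li]
        c1 = np.concatenate(([0.0], np.cumsum(xi)))
        c2 = np.concatenate(([0.0], np.cumsum(xi**2)))
        tau = np.arange(Li)
        n = Li - tau
        s_head = c1[Li - tau] - c1[0]          # sum of first n samples
        s_tail = c1[Li] - c1[tau]              # sum of last n samples
        q_head = c2[Li - tau] - c2[0]
        q_tail = c2[Li] - c2[tau]
        cov = sxy - s_head * s_tail / n
        v1 = q_head - s_head**2 / n
        v2 = q_tail - s_tail**2 / n
        with np.errstate(invalid="ignore", divide="ignore"):
            c = cov / np.sqrt(v1 * v2)
        c[n < MIN_OVERLAP] = np.nan
        out[i, :Li] = c
    return out[0] if np.asarray(acg).ndim == 1 else out


def periodicity_index(
    acg: np.ndarray,
    dt: float = ACG_DT,
    max_lag: float = PI_MAX_LAG,
) -> tuple[np.ndarray, np.ndarray]:
    """PI curve: shifted-ACG correlation at each lag minus at half that lag."""
    single = np.asarray(acg).ndim == 1
    C = np.atleast_2d(shifted_acg_correlation(acg))
    n_pi = min(int(round(max_lag / dt)) + 1, C.shape[1])
    tau = np.arange(n_pi)
    half = tau // 2
    pi = C[:, tau] - C[:, half]
    lags = tau * dt
    return (pi[0], lags) if single else (pi, lags)


def _peak_lag(pi: np.ndarray, lags: np.ndarray) -> float:
    """Lag of the maximal PI, preferring local maxima (ties -> smaller lag).

    The discrete peak is refined by parabolic interpolation through its two
    neighbours, removing the lag-grid quantization bias.
    """
    ok = ~np.isnan(pi)
    if not ok.any():
        return np.nan
    x = np.where(ok, pi, -np.inf)
    interior = (x[1:-1] >= x[:-2]) & (x[1:-1] >= x[2:])
    cand = np.flatnonzero(interior) + 1
    if cand.size == 0:
        cand = np.arange(x.size)
    vals = x[cand]
    top = vals.max()
    p = int(cand[vals >= top - 1e-9][0])  # ties broken toward the smaller lag
    if 0 < p < x.size - 1 and np.isfinite(x[p - 1]) and np.isfinite(x[p + 1]):
        denom = x[p - 1] - 2 * x[p] + x[p + 1]
        if denom < -1e-12:
            delta = 0.5 * (x[p - 1] - x[p + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return float(lags[p] + delta * (lags[1] - lags[0]))
    return float(lags[p])


def _null_max_pis(
    durations: np.ndarray,
    mean_rate: float,
    n_null: int,
    kernel_sd: float,
    rng: np.random.Generator,
    length_constant: float = 0.1,
) -> np.ndarray:
    """Max-PI null distribution from GP-surrogate trials, fully vectorized.

    For each of ``n_null`` repeats a matched set of surrogate trials (same
    trial count, durations and mean rate as the analyzed unit) is generated
    from the squared-exponential GP intensity, smoothed, detrended,
    autocorrelated and reduced to the maximal PI, exactly as the real data.
    """
    durations = np.asarray(durations, dtype=float)
    n_tr = durations.size
    lens = np.round(durations / ACG_DT).astype(int)
    l_max = int(lens.max())
    B = n_null * n_tr
    lens_b = np.tile(lens, n_null)

    def fft_gauss(arr, sigma_bins):
        # batched Gaussian convolution via FFT (zero boundary)
        half = int(np.ceil(4 * sigma_bins))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_bins) ** 2)
        k /= k.sum()
        nfft = int(2 ** np.ceil(np.log2(arr.shape[1] + 2 * half + 1)))
        fa = np.fft.rfft(arr, nfft, axis=1)
        fk = np.fft.rfft(np.roll(np.pad(k, (0, nfft - k.size)), -half))
        return np.fft.irfft(fa * fk[None, :], nfft, axis=1)[:, : arr.shape[1]]

    # GP sample: white noise filtered to the squared-exponential covariance
    sigma_bins = length_constant / np.sqrt(2) / ACG_DT
    pad = int(np.ceil(5 * sigma_bins))
    g = rng.standard_normal((B, l_max + 2 * pad))
    g = fft_gauss(g, sigma_bins)[:, pad:pad + l_max]
    g = g / np.sqrt(1.0 / (2 * np.sqrt(np.pi) * sigma_bins))
    rate = mean_rate * np.exp(g - 0.5)
    counts = rng.poisson(rate * ACG_DT).astype(float)

    mask = np.arange(l_max)[None, :] < lens_b[:, None]
    counts *= mask
    traces = fft_gauss(counts, kernel_sd / ACG_DT)
    traces *= mask

    # masked per-row linear detrend
    t = np.arange(l_max, dtype=float)
    n = lens_b.astype(float)
    st = np.where(mask, t, 0.0).sum(axis=1)
    stt = np.where(mask, t * t, 0.0).sum(axis=1)
    sx = traces.sum(axis=1)
    sxt = (traces * t).sum(axis=1)
    denom = n * stt - st**2
    slope = np.where(denom > 0, (n * sxt - st * sx) / denom, 0.0)
    icept = (sx - slope * st) / n
    traces = (traces - (slope[:, None] * t[None, :] + icept[:, None])) * mask

    # batched zero-padded FFT autocorrelation
    n_lag = int(round(ACG_MAX_LAG / ACG_DT)) + 1
    nfft = int(2 ** np.ceil(np.log2(l_max + n_lag)))
    f = np.fft.rfft(traces, nfft, axis=1)
    ac = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n_lag]
    denom_ac = ac[:, 0].copy()
    denom_ac[denom_ac <= 0] = np.inf
    ac = ac / denom_ac[:, None]
    valid = np.arange(n_lag)[None, :] < lens_b[:, None]
    ac[~valid] = np.nan

    out = np.empty(n_null)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(n_null):
            macg = np.nanmean(ac[b * n_tr:(b + 1) * n_tr], axis=0)
            pi, _ = periodicity_index(macg)
            out[b] = np.nanmax(pi)
    return out


def classify_periodic(
    neuron: NeuronSession,
    n_null: int = 1000,
    z_threshold: float = 2.0,
    min_trials: int = 15,
    min_distance: int = 3,
    kernel_sd: float = 0.1,
    seed: int = 0,
    trial_mask=None,
) -> PIResult:
    """Full periodicity classification of one unit with a GP-surrogate null.

    For each of ``n_null`` repeats, surrogate spike trains matched in trial
    count, duration and mean rate are generated from the GP intensity model
    and pushed through the identical ACG/PI pipeline; the null statistic is
    the maximal PI.  The unit is significant when its own maximal PI exceeds
    ``null_mean + z_threshold * null_sd`` and more than ``min_trials``
    trials were pooled.
    """
    acg, lags, n_trials = compute_acg(
        neuron, min_distance=min_distance, kernel_sd=kernel_sd, trial_mask=trial_mask
    )
    if n_trials == 0:
        return PIResult(acg, lags, np.full(0, np.nan), np.zeros(0), 0,
                        reason="no qualifying trials")
    pi, pi_lags = periodicity_index(acg)
    res = PIResult(acg, lags, pi, pi_lags, n_trials)

    tr = neuron.trials
    dist = (tr["target"] - tr["start"]).abs() if "target" in tr else tr["distance"]
    mask = (dist >= min_distance).to_numpy()
    if trial_mask is not None:
        mask &= np.asarray(trial_mask)
    durations = (tr["t_off"] - tr["t_on"]).to_numpy(float) - 0.5
    mask &= durations > 0.2
    durations = durations[mask]
    # rate matched to the analyzed epochs
    total_spikes = sum(
        np.sum(s < d) for s, d in zip(neuron.select(mask).aligned_spikes("onset"), durations)
    )
    mean_rate = max(total_spikes / durations.sum(), 0.5)

    rng = np.random.default_rng(seed)
    null_max = _null_max_pis(durations, mean_rate, n_null, kernel_sd, rng)
    res.null_mean = float(null_max.mean())
    res.null_sd = float(null_max.std(ddof=1))

    if n_trials <= min_trials:
        res.reason = f"only {n_trials} trials (need > {min_trials})"
        return res
    if res.max_pi > res.null_mean + z_threshold * res.null_sd:
        res.significant = True
        res.peak_lag = _peak_lag(pi, pi_lags)
    return res


# ---------------------------------------------------------------------------
# ramping

def ramping_test(
    neuron: NeuronSession,
    min_distance: int = 3,
    bin_width: float = 0.1,
    alpha: float = 0.001,
    truncate_pre_offset: float = 0.5,
) -> dict:
    """Linear-vs-constant test on the trial-averaged rate of long trials.

    The mean rate is computed in coarse (100 ms) bins of raw counts so that
    adjacent samples are effectively independent; an F-test compares the
    linear model against a constant at ``alpha`` (0.001).
    """
    import statsmodels.api as sm

    tr = neuron.trials
    dist = (tr["target"] - tr["start"]).abs() if "target" in tr else tr["distance"]
    mask = (dist >= min_distance).to_numpy()
    durations = (tr["t_off"] - tr["t_on"]).to_numpy(float) - truncate_pre_offset
    mask &= durations > 3 * bin_width
    if not mask.any():
        return {"slope": np.nan, "F": np.nan, "p": np.nan, "significant": False}
    # pool out to the 75th-percentile duration; each bin averages the trials
    # that cover it (>= 25% of pooled trials)
    horizon = float(np.quantile(durations[mask], 0.75))
    edges = np.arange(0.0, horizon + 1e-9, bin_width)
    counts = np.zeros(edges.size - 1)
    cover = np.zeros(edges.size - 1)
    sub = neuron.select(mask)
    for spikes, dur in zip(sub.aligned_spikes("onset"), durations[mask]):
        c, _ = np.histogram(spikes[spikes < dur], bins=edges)
        counts += c
        cover += edges[1:] <= dur + 1e-9
    keep = cover >= max(0.25 * mask.sum(), 2)
    mean_rate = counts[keep] / cover[keep] / bin_width
    t = (edges[:-1] + bin_width / 2)[keep]
    fit = sm.OLS(mean_rate, sm.add_constant(t)).fit()
    return {
        "slope": float(fit.params[1]),
        "F": float(fit.fvalue),
        "p": float(fit.f_pvalue),
        "significant": bool(fit.f_pvalue < alpha),
    }


# ---------------------------------------------------------------------------
# epoch / outcome / tertile comparisons

def _pi_at(pi: np.ndarray, lags: np.ndarray, period: float, half_window: float) -> float:
    sel = (lags >= period - half_window) & (lags <= period + half_window)
    if not sel.any() or np.all(np.isnan(pi[sel])):
        return np.nan
    return float(np.nanmax(pi[sel]))


def _iti_pseudo_session(neuron: NeuronSession, chunk: float = 2.5) -> NeuronSession | None:
    """Chop pooled >=4-s ITI segments into pseudo-trials for the PI pipeline."""
    import pandas as pd

    rows = []
    for a, b in neuron.iti_segments:
        t = a
        while t + chunk <= b:
            # distance 3 marker so the pseudo-trials pass the pooling rule;
            # truncation removes the final 0.5 s of each chunk
            rows.append(dict(start=1, target=4, v_a=chunk, v_p=chunk,
                             t_go=t, t_on=t, t_off=t + chunk,
                             n_attempts=1, rewarded=True, session_id="iti"))
            t += chunk
    if not rows:
        return None
    return NeuronSession(neuron.neuron_id, neuron.spike_times, pd.DataFrame(rows),
                         neuron.group, [])


def epoch_outcome_comparison(
    neurons: list[NeuronSession],
    mode: str,
    period: float = 0.65,
    half_window: float = 0.05,
    min_trials: int = 8,
    seed: int = 0,
    n_null: int = 0,
) -> dict:
    """Paired per-unit PI comparison across epochs, outcomes, or v_p tertiles.

    ``mode``:
      - ``mnav_vs_iti``: PI near the landmark period during navigation
        trials vs pooled inter-trial segments.
      - ``correct_vs_error``: rewarded vs error (multi-attempt) trials.
      - ``tertiles``: rewarded trials pooled per condition and split by
        produced-vector magnitude; compares the PI *peak lag* (period) of
        the top vs bottom tertile.

    Returns per-unit paired values and a paired t-test; units lacking a
    partition with at least ``min_trials`` qualifying trials are skipped.
    """
    a_vals, b_vals, skipped = [], [], 0

    for neuron in neurons:
        tr = neuron.trials
        if mode == "mnav_vs_iti":
            acg, lags, n = compute_acg(neuron)
            iti = _iti_pseudo_session(neuron)
            if n < min_trials or iti is None or len(iti.trials) < min_trials:
                skipped += 1
                continue
            pi, pl = periodicity_index(acg)
            acg_i, _, _ = compute_acg(iti)
            pi_i, _ = periodicity_index(acg_i)
            a_vals.append(_pi_at(pi, pl, period, half_window))
            b_vals.append(_pi_at(pi_i, pl, period, half_window))
        elif mode == "correct_vs_error":
            ok = tr["rewarded"].astype(bool).to_numpy()
            masks = (ok, ~ok)
            vals = []
            for m in masks:
                acg, lags, n = compute_acg(neuron, trial_mask=m)
                if n < min_trials:
                    vals = None
                    break
                pi, pl = periodicity_index(acg)
                vals.append(_pi_at(pi, pl, period, half_window))
            if vals is None:
                skipped += 1
                continue
            a_vals.append(vals[0])
            b_vals.append(vals[1])
        elif mode == "tertiles":
            ok = tr["rewarded"].astype(bool).to_numpy()
            vp = tr["v_p"].abs().to_numpy(float)
            top = np.zeros(len(tr), bool)
            bot = np.zeros(len(tr), bool)
            for _, grp in tr[ok].groupby("v_a"):
                pos = tr.index.get_indexer(grp.index)
                v = vp[pos]
                lo, hi = np.quantile(v, [1 / 3, 2 / 3])
                bot[pos] = v <= lo
                top[pos] = v >= hi
            vals = []
            for m in (top, bot):
                acg, lags, n = compute_acg(neuron, trial_mask=m)
                if n < min_trials:
                    vals = None
                    break
                pi, pl = periodicity_index(acg)
                vals.append(_peak_lag(pi, pl))
            if vals is None:
                skipped += 1
                continue
            a_vals.append(vals[0])
            b_vals.append(vals[1])
        else:
            raise ValueError(f"unknown mode {mode!r}")

    a = np.asarray(a_vals)
    b = np.asarray(b_vals)
    out = {"a": a, "b": b, "diff": a - b, "n_units": a.size, "n_skipped": skipped}
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() >= 2 and np.ptp((a - b)[ok]) > 0:
        t, p = stats.ttest_rel(a[ok], b[ok])
        out.update({"t": float(t), "p": float(p)})
    else:
        out.update({"t": np.nan, "p": np.nan})
    return out


# ---------------------------------------------------------------------------
# Fano factor

def fano_time_course(
    neuron: NeuronSession,
    window: tuple[float, float] = (-1.95, 0.0),
    align: str = "offset",
    bin_width: float = 0.1,
    step: float = 0.025,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-trial Fano factor (variance/mean of spike counts) in sliding bins.

    Only trials long enough to cover ``window`` contribute.  Bins with zero
    mean count are masked (NaN).  Returns (fano, bin centres, counts matrix).
    """
    durations = (neuron.trials["t_off"] - neuron.trials["t_on"]).to_numpy(float)
    need = -window[0] if align == "offset" else window[1]
    mask = durations >= need
    sub = neuron.select(mask)
    trains = sub.aligned_spikes(align, window=(window[0] - bin_width, bin_width))
    starts = np.arange(window[0], window[1] - bin_width + 1e-9, step)
    centers = starts + bin_width / 2
    counts = np.zeros((len(trains), starts.size))
    for i, st in enumerate(trains):
        for j, s in enumerate(starts):
            counts[i, j] = np.sum((st >= s) & (st < s + bin_width))
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
    return fano, centers, counts


def fano_periodicity(
    neuron: NeuronSession,
    window: tuple[float, float] = (-1.95, 0.0),
    bin_width: float = 0.1,
    step: float = 0.025,
    n_null: int = 100,
    z_threshold: float = 2.0,
    min_trials: int = 20,
    peak_window: tuple[float, float] = (0.5, 0.8),
    seed: int = 0,
) -> FanoResult:
    """Periodicity of the Fano-factor time course with a Poisson-matched null.

    The Fano trace is pushed through the same detrend/ACG/PI procedure as
    firing rates.  The null regenerates the same trials as inhomogeneous
    Poisson processes from the unit's trial-averaged rate (for which the
    Fano factor is 1 and aperiodic) and recomputes the maximal PI inside
    ``peak_window``.  Significance: observed windowed max PI above null mean
    + 2 SD, with the PI peak inside the window.
    """
    fano, centers, counts = fano_time_course(neuron, window, "offset", bin_width, step)
    n_trials = counts.shape[0]
    if n_trials < min_trials:
        return FanoResult(fano, centers, None)
    filled = np.where(np.isnan(fano), np.nanmean(fano), fano)
    acg, lags = acg_of_trace(filled, step)
    pi, pl = periodicity_index(acg, dt=step)
    res_pi = PIResult(acg, lags, pi, pl, n_trials)

    mean_count = counts.mean(axis=0)  # per sliding bin; overlapping, but the
    # null only needs the mean rate profile on a fine grid:
    rng = np.random.default_rng(seed)
    grid = np.arange(window[0], window[1], _DT)
    rate = np.interp(grid, centers, mean_count / bin_width)
    null_max = np.empty(n_null)
    sel = (pl >= peak_window[0]) & (pl <= peak_window[1])
    for b in range(n_null):
        c = rng.poisson(np.tile(rate * _DT, (n_trials, 1)))
        # rebin the Poisson draws into the sliding windows
        csum = np.concatenate([np.zeros((n_trials, 1)), np.cumsum(c, axis=1)], axis=1)
        idx0 = np.searchsorted(grid, np.arange(window[0], window[1] - bin_width + 1e-9, step))
        idx1 = np.clip(idx0 + int(round(bin_width / _DT)), 0, grid.size)
        k = csum[:, idx1] - csum[:, idx0]
        m = k.mean(axis=0)
        v = k.var(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(m > 0, v / m, np.nan)
        f = np.where(np.isnan(f), np.nanmean(f), f)
        nacg, _ = acg_of_trace(f, step)
        npi, _ = periodicity_index(nacg, dt=step)
        null_max[b] = np.nanmax(npi[sel]) if sel.any() else np.nan
    null_mean = float(np.nanmean(null_max))
    null_sd = float(np.nanstd(null_max, ddof=1))

    peak = _peak_lag(pi, pl)
    obs = np.nanmax(pi[sel]) if sel.any() else np.nan
    significant = bool(
        np.isfinite(obs)
        and obs > null_mean + z_threshold * null_sd
        and peak_window[0] <= peak <= peak_window[1]
    )
    return FanoResult(fano, centers, res_pi, null_mean, null_sd, significant,
                      peak if significant else _peak_lag(pi, pl))
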