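"""Temporal-distance coding at joystick onset and offset.

Single-unit analysis: firing rates in a 100-ms window before joystick onset
or offset are regressed on the produced vector length (15 equal-count bins),
with significance by F-test at 95% confidence and a cross-validated R^2
(random split-half, slope fitted on training trials against dummy distances
1..5).  Population analysis: targeted dimensionality reduction finds the
axis of regression coefficients relating centred rates to ordinal distance,
picks the time point where the coefficient norm peaks, and evaluates
held-out projections; a four-way main-effects ANOVA separates distance
coding from start/target landmark identity and direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import NeuronSession

__all__ = [
    "DistanceCodingResult",
    "TDRResult",
    "window_rates",
    "single_neuron_distance_regression",
    "cross_validated_r2",
    "cv_distance_r2",
    "tdr_axis",
    "anova4",
]


@dataclass
class DistanceCodingResult:
    neuron_id: str
    slope_onset: float
    slope_offset: float
    F_onset: float
    F_offset: float
    p_onset: float
    p_offset: float
    cv_r2_onset: float
    cv_r2_offset: float
    klass: str   # 'onset' | 'offset' | 'both' | 'none'


@dataclass
class TDRResult:
    axis_onset: np.ndarray
    axis_offset: np.ndarray
    t_onset: float
    t_offset: float
    beta_onset: np.ndarray        # (neurons, time)
    beta_offset: np.ndarray
    proj_onset: dict              # distance -> held-out projections
    proj_offset: dict
    r2_onset: np.ndarray          # bootstrap distribution
    r2_offset: np.ndarray


def window_rates(
    neuron: NeuronSession, align: str, window: tuple[float, float]
) -> np.ndarray:
    """Per-trial firing rate (Hz) from raw counts in an exact window.

    ``window`` is relative to the alignment event, half-open [a, b).
    """
    trains = neuron.aligned_spikes(align, window=window)
    width = window[1] - window[0]
    return np.array([
        np.sum((st >= window[0]) & (st < window[1])) / width for st in trains
    ])


def _binned_regression(vp: np.ndarray, rates: np.ndarray, n_bins: int = 15):
    """Slope/F of binned mean rate on binned mean |v_p| (equal-count bins)."""
    import statsmodels.api as sm

    order = np.argsort(vp)
    splits = np.array_split(order, n_bins)
    splits = [s for s in splits if s.size > 0]
    if len(splits) < 5:
        return np.nan, np.nan, np.nan, 0
    x = np.array([vp[s].mean() for s in splits])
    y = np.array([rates[s].mean() for s in splits])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.fvalue), float(fit.f_pvalue), len(splits)


def cross_validated_r2(y_test: np.ndarray, y_pred: np.ndarray) -> float:
    """Variance of held-out data accounted for by the prediction.

    ``R^2 = 1 - sum((y_test - y_pred)^2) / sum((y_test - mean(y_test))^2)``.
    May be negative for anti-predictive fits; undefined (NaN) when the test
    data have zero variance.
    """
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    denom = float(np.sum((y_test - y_test.mean()) ** 2))
    if denom == 0:
        return np.nan
    return 1.0 - float(np.sum((y_test - y_pred) ** 2)) / denom


def cv_distance_r2(
    rates: np.ndarray,
    distances: np.ndarray,
    n_repeats: int = 20,
    seed: int = 0,
) -> float:
    """Split-half cross-validated R^2 of a rate-on-distance regression.

    Trials are split 50/50 at random; a slope (with intercept) is fitted on
    the training half against the dummy distance regressor and evaluated on
    the held-out half.  Averaged over ``n_repeats`` random splits.
    """
    rng = np.random.default_rng(seed)
    n = rates.size
    vals = []
    for _ in range(n_repeats):
        idx = rng.permutation(n)
        tr, te = idx[: n // 2], idx[n // 2:]
        x_tr, y_tr = distances[tr], rates[tr]
        if np.ptp(x_tr) == 0:
            continue
        beta, b0 = np.polyfit(x_tr, y_tr, 1)
        y_pred = beta * distances[te] + b0
        r2 = cross_validated_r2(rates[te], y_pred)
        if np.isfinite(r2):
            vals.append(r2)
    return float(np.mean(vals)) if vals else np.nan


def single_neuron_distance_regression(
    neuron: NeuronSession,
    window_pre: float = 0.1,
    n_bins: int = 15,
    alpha: float = 0.05,
    exclude_distance_1: bool = False,
    trial_level: bool = False,
    seed: int = 0,
) -> DistanceCodingResult | None:
    """Onset/offset distance coding of one unit.

    Returns None when fewer than 5 of the ``n_bins`` produced-vector bins
    are occupied.  ``exclude_distance_1`` reruns the analysis without the
    shortest distance (control against the shortest distance inflating the
    linear readout); ``trial_level`` regresses trial rates directly instead
    of binned means.
    """
    tr = neuron.trials
    vp = tr["v_p"].abs().to_numpy(float)
    dist = (tr["target"] - tr["start"]).abs().to_numpy() if "target" in tr \
        else tr["distance"].to_numpy()
    keep = np.ones(len(tr), bool)
    if exclude_distance_1:
        keep &= dist > 1
    vp = vp[keep]
    dist = dist[keep]
    sub = neuron.select(keep)

    out = {}
    for align, win in (("onset", (-window_pre, 0.0)), ("offset", (-window_pre, 0.0))):
        rates = window_rates(sub, align, win)
        if trial_level:
            import statsmodels.api as sm

            fit = sm.OLS(rates, sm.add_constant(vp)).fit()
            slope, F, p = float(fit.params[1]), float(fit.fvalue), float(fit.f_pvalue)
            nb = n_bins
        else:
            slope, F, p, nb = _binned_regression(vp, rates, n_bins)
        if nb < 5:
            return None
        r2 = cv_distance_r2(rates, dist.astype(float), seed=seed)
        out[align] = (slope, F, p, r2)

    sig_on = out["onset"][2] < alpha
    sig_off = out["offset"][2] < alpha
    klass = {(True, True): "both", (True, False): "onset",
             (False, True): "offset", (False, False): "none"}[(sig_on, sig_off)]
    return DistanceCodingResult(
        neuron.neuron_id,
        out["onset"][0], out["offset"][0],
        out["onset"][1], out["offset"][1],
        out["onset"][2], out["offset"][2],
        out["onset"][3], out["offset"][3],
        klass,
    )


# ---------------------------------------------------------------------------
# targeted dimensionality reduction

def _rate_tensor(neurons, align, window, bin_width):
    """(n_neurons, n_bins, n_trials) spike-count rates on a common grid."""
    edges = np.arange(window[0], window[1] + 1e-9, bin_width)
    n_bins = edges.size - 1
    n_trials = len(neurons[0].trials)
    R = np.zeros((len(neurons), n_bins, n_trials))
    for i, nrn in enumerate(neurons):
        trains = nrn.aligned_spikes(align, window=window)
        for k, st in enumerate(trains):
            c, _ = np.histogram(st, bins=edges)
            R[i, :, k] = c / bin_width
    return R, edges[:-1] + bin_width / 2


def tdr_axis(
    neurons: list[NeuronSession],
    distances: np.ndarray | None = None,
    window_onset: tuple[float, float] = (-0.2, 0.0),
    window_offset: tuple[float, float] = (-0.5, -0.3),
    bin_width: float = 0.04,
    n_boot: int = 50,
    seed: int = 0,
    ridge: float = 0.0,
) -> TDRResult:
    """Population distance-coding axes at joystick onset and offset.

    All units must share one simultaneously recorded trial table.  Rates
    are centred per unit by subtracting its mean across both windows; the
    per-time regression coefficient of centred rate on ordinal distance is
    computed, the time of maximal coefficient norm picked, and the
    coefficient vector there (unit norm) is the coding axis.  Held-out
    trials (random half per distance) are projected onto the axis; the
    bootstrap distribution (``n_boot`` resamples) of the projection R^2
    against the dummy distance regressor quantifies coding strength.
    """
    if len(neurons) < 10:
        raise ValueError("need at least 10 simultaneously recorded units")
    rng = np.random.default_rng(seed)
    tr = neurons[0].trials
    if distances is None:
        distances = (tr["target"] - tr["start"]).abs().to_numpy(float)
    n_trials = len(tr)

    R_on, t_on = _rate_tensor(neurons, "onset", window_onset, bin_width)
    R_off, t_off = _rate_tensor(neurons, "offset", window_offset, bin_width)
    # centre each unit across both windows
    grand = np.concatenate([R_on, R_off], axis=1).mean(axis=(1, 2))
    R_on = R_on - grand[:, None, None]
    R_off = R_off - grand[:, None, None]

    # train/test split balanced over distances
    test = np.zeros(n_trials, bool)
    for d in np.unique(distances):
        idx = np.flatnonzero(distances == d)
        test[rng.permutation(idx)[: idx.size // 2]] = True
    train = ~test

    def fit_axis(R):
        d = distances[train]
        denom = float(d @ d) + ridge
        beta = np.tensordot(R[:, :, train], d, axes=([2], [0])) / denom
        norms = np.linalg.norm(beta, axis=0)
        t_star = int(np.argmax(norms))
        axis = beta[:, t_star]
        axis = axis / max(np.linalg.norm(axis), 1e-12)
        return beta, t_star, axis

    beta_on, i_on, ax_on = fit_axis(R_on)
    beta_off, i_off, ax_off = fit_axis(R_off)

    def held_out(R, axis):
        # average over the window, project held-out trials
        proj = axis @ R[:, :, :].mean(axis=1)
        by_d = {int(d): proj[test & (distances == d)] for d in np.unique(distances)}
        return proj, by_d

    proj_on, by_on = held_out(R_on, ax_on)
    proj_off, by_off = held_out(R_off, ax_off)

    def boot_r2(proj):
        te = np.flatnonzero(test)
        out = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(te, size=te.size, replace=True)
            x, y = distances[idx], proj[idx]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                out[b] = np.nan
                continue
            out[b] = stats.pearsonr(x, y)[0] ** 2
        return out

    return TDRResult(
        ax_on, ax_off, float(t_on[i_on]), float(t_off[i_off]),
        beta_on, beta_off, by_on, by_off,
        boot_r2(proj_on), boot_r2(proj_off),
    )


# ---------------------------------------------------------------------------
# four-way ANOVA

def _window_slope(neuron, window, bin_width=0.02):
    """Per-trial slope of the rate within a window (OLS on binned counts)."""
    edges = np.arange(window[0], window[1] + 1e-9, bin_width)
    centers = edges[:-1] + bin_width / 2
    trains = neuron.aligned_spikes("offset", window=window)
    slopes = np.empty(len(trains))
    for k, st in enumerate(trains):
        c, _ = np.histogram(st, bins=edges)
        slopes[k] = np.polyfit(centers, c / bin_width, 1)[0]
    return slopes


def anova4(
    neurons: list[NeuronSession],
    dependent: str = "rate",
    window_rate: tuple[float, float] = (-0.5, -0.3),
    window_slope: tuple[float, float] = (-0.55, -0.25),
    alpha: float = 0.05,
) -> dict:
    """Four-way main-effects ANOVA per unit plus population contrasts.

    Factors: ordinal distance, start landmark, target landmark, direction;
    the dependent variable is either the mean rate in the window before
    joystick offset or the within-window rate slope.  Type-II sums of
    squares accommodate the unbalanced (correlated) factor design.  The
    population contrast compares F(distance) against F(start) and
    F(target) with a t-test on per-unit F differences over units with a
    significant effect of either factor.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    for nrn in neurons:
        tr = nrn.trials
        if dependent == "rate":
            y = window_rates(nrn, "offset", window_rate)
        else:
            y = _window_slope(nrn, window_slope)
        df = pd.DataFrame({
            "y": y,
            "distance": (tr["target"] - tr["start"]).abs().to_numpy(),
            "start": tr["start"].to_numpy(),
            "target": tr["target"].to_numpy(),
            "direction": np.sign(tr["v_a"].to_numpy()),
        })
        try:
            fit = ols("y ~ C(distance) + C(start) + C(target) + C(direction)", df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
        except Exception:
            continue
        rec = {"neuron_id": nrn.neuron_id}
        for fac in ("distance", "start", "target", "direction"):
            rec[f"F_{fac}"] = float(tab.loc[f"C({fac})", "F"])
            rec[f"p_{fac}"] = float(tab.loc[f"C({fac})", "PR(>F)"])
        rows.append(rec)
    table = pd.DataFrame(rows)
    out = {"table": table}
    for other in ("start", "target"):
        sel = (table["p_distance"] < alpha) | (table[f"p_{other}"] < alpha)
        diffs = (table["F_distance"] - table[f"F_{other}"])[sel].to_numpy()
        if diffs.size >= 2 and np.ptp(diffs) > 0:
            t, p = stats.ttest_1samp(diffs, 0.0)
            out[f"distance_vs_{other}"] = {"t": float(t), "p": float(p),
                                           "mean_diff": float(diffs.mean()),
                                           "n": int(diffs.size)}
        else:
            out[f"distance_vs_{other}"] = {"t": np.nan, "p": np.nan,
                                           "mean_diff": np.nan, "n": int(diffs.size)}
    return out
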