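"""Generative Bayesian observer models of vector-production behaviour.

Two observers are implemented.  Both measure the actual temporal distance
with scalar Gaussian noise (SD ``w_m * d``), combine the measurement with the
task prior over distances, and take the posterior mean ``t_e`` (Bayes least
squares).  They differ in how production noise scales with the estimate:

``scalar``
    sigma = w_p * t_e — the classical scalar property of interval timing
    (no intermediate resets during the navigation epoch).

``subscalar``
    the navigation epoch is divided into multiples of the base interval
    ``t_o``; by the variance sum law sigma^2 = (w_p * t_o)^2 * D, i.e.
    sigma = w_p * sqrt(t_o) * sqrt(t_e) — sub-linear growth, the signature
    of intermediate resets at endogenous landmarks.

An overall production bias ``b`` shifts the mean of the produced interval.
``ObserverModel`` is a statsmodels-style model object: build it from a trial
table, call :meth:`ObserverModel.fit`, and inspect the returned
:class:`ObserverResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task import LandmarkLine, TrialCondition, enumerate_conditions

__all__ = [
    "ObserverParams",
    "TaskPrior",
    "bls_estimate",
    "production_sd",
    "simulate_trials",
    "exclude_outliers",
    "ObserverModel",
    "ObserverResults",
    "fit_mle",
    "compare_models",
]

_WP_BOUNDS = (1e-3, 1.0)
_WM_BOUNDS = (1e-4, 1.0)
_B_BOUNDS = (-1.0, 1.0)


@dataclass(frozen=True)
class ObserverParams:
    """Observer parameters: measurement/production Weber fractions and bias."""

    w_m: float
    w_p: float
    offset_b: float = 0.0
    model_kind: str = "scalar"
    t_o: float = 0.65

    def __post_init__(self):
        if self.w_m < 0:
            raise ValueError("w_m must be >= 0")
        if self.w_p <= 0:
            raise ValueError("w_p must be > 0")
        if self.model_kind not in ("scalar", "subscalar"):
            raise ValueError("model_kind must be 'scalar' or 'subscalar'")

    @property
    def w_pc(self) -> float:
        """Composite production Weber fraction w_p * sqrt(t_o) (subscalar)."""
        return self.w_p * np.sqrt(self.t_o)


class TaskPrior:
    """Prior over temporal-distance magnitudes implied by the condition set.

    For an ``n``-landmark line the ordered-pair multiplicity of ordinal
    distance ``D`` is ``2 (n - D)``; for n = 6 the distances 1..5 have
    multiplicities {10, 8, 6, 4, 2}.  Directions are pooled: the prior lives
    on magnitudes ``D * t_o``.
    """

    def __init__(self, line: LandmarkLine | None = None):
        line = line or LandmarkLine()
        self.t_o = line.t_o
        n = line.n_landmarks
        d = np.arange(1, n)
        mult = 2 * (n - d)
        self.distances = d
        self.support = d * line.t_o
        self.probs = mult / mult.sum()

    @classmethod
    def from_atoms(cls, support, probs, t_o=0.65):
        obj = cls.__new__(cls)
        obj.support = np.asarray(support, dtype=float)
        obj.probs = np.asarray(probs, dtype=float) / np.sum(probs)
        obj.distances = np.round(obj.support / t_o).astype(int)
        obj.t_o = t_o
        return obj

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)


def bls_estimate(m, prior: TaskPrior, w_m: float):
    """Bayes-least-squares (posterior mean) estimate of the distance.

    The likelihood of a measurement ``m`` given true magnitude ``d`` is
    Gaussian with SD ``w_m * d``.  With ``w_m = 0`` the likelihood is
    degenerate and the estimate snaps to the nearest prior atom.
    The estimate always lies within the prior support.
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))
    s, p = prior.support, prior.probs
    if w_m == 0:
        idx = np.argmin(np.abs(m[:, None] - s[None, :]), axis=1)
        out = s[idx]
    else:
        sd = w_m * s
        lik = np.exp(-0.5 * ((m[:, None] - s[None, :]) / sd) ** 2) / sd
        w = lik * p
        out = (w @ s) / w.sum(axis=1)
    return out if out.size > 1 else float(out[0])


def production_sd(t_e, params: ObserverParams):
    """Production noise SD for an estimate ``t_e`` under the observer's law."""
    t_e = np.asarray(t_e, dtype=float)
    if params.model_kind == "scalar":
        sd = params.w_p * t_e
    else:
        sd = params.w_p * np.sqrt(params.t_o) * np.sqrt(t_e)
    return sd if sd.ndim else float(sd)


def simulate_trials(
    params: ObserverParams,
    prior: TaskPrior | None = None,
    n: int = 500,
    seed: int = 0,
    conditions: list[TrialCondition] | None = None,
) -> pd.DataFrame:
    """Simulate produced vectors from an observer.

    Per trial: a condition is drawn (its distance follows the task prior when
    drawn from the full condition set), the magnitude is measured with noise
    ``w_m * d``, mapped through the BLS estimator, and the produced magnitude
    is drawn from ``Normal(t_e + b, production_sd)``.  Direction is copied
    from the condition.  Negative produced magnitudes are resampled (counted
    and warned at >1% of draws).
    """
    rng = np.random.default_rng(seed)
    prior = prior or TaskPrior()
    if conditions is None:
        conditions = enumerate_conditions(LandmarkLine(t_o=prior.t_o))
    cond_idx = rng.integers(0, len(conditions), size=n)
    d_mag = np.array([conditions[i].v_a for i in cond_idx])
    sign = np.sign(d_mag)
    d = np.abs(d_mag)

    m = rng.normal(d, params.w_m * d) if params.w_m > 0 else d.copy()
    t_e = np.atleast_1d(bls_estimate(m, prior, params.w_m))
    mu = t_e + params.offset_b
    sd = np.atleast_1d(production_sd(t_e, params))

    v_mag = rng.normal(mu, sd) if params.w_p > 0 else mu.copy()
    n_resampled = 0
    bad = v_mag <= 0
    while bad.any():
        n_resampled += int(bad.sum())
        v_mag[bad] = rng.normal(mu[bad], sd[bad])
        bad = v_mag <= 0
    if n_resampled > 0.01 * n:
        warnings.warn(f"resampled {n_resampled} negative produced vectors")

    return pd.DataFrame(
        {
            "start": [conditions[i].start for i in cond_idx],
            "target": [conditions[i].target for i in cond_idx],
            "v_a": d_mag,
            "v_p": sign * v_mag,
            "distance": np.round(d / prior.t_o).astype(int),
        }
    )


def exclude_outliers(
    trials: pd.DataFrame,
    max_iter: int = 200,
    lapse_on_vp: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Remove lapse trials with a per-condition Gaussian + uniform mixture.

    For each condition the produced magnitudes are modelled as a mixture of a
    task Gaussian and a uniform lapse distribution on ``[0, 3 |v_a|]``
    (``lapse_on_vp=True`` uses the trial's own ``3 |v_p|`` instead, which
    makes the lapse density datum-dependent).  EM estimates the mixture;
    trials whose lapse responsibility exceeds 0.5 are dropped.

    Returns (kept trials, number removed).
    """
    keep_mask = np.ones(len(trials), dtype=bool)
    for _, grp in trials.groupby("v_a"):
        y = np.abs(grp["v_p"].to_numpy(float))
        va = abs(float(grp["v_a"].iloc[0]))
        if len(y) < 3:
            continue
        hi = 3.0 * np.abs(y) if lapse_on_vp else 3.0 * va
        u_dens = np.where((y >= 0) & (y <= hi), 1.0 / np.maximum(hi, 1e-12), 1e-12)
        mu, sd, lam = np.median(y), max(1.4826 * np.median(np.abs(y - np.median(y))), 1e-3), 0.05
        ok = True
        for _ in range(max_iter):
            g = stats.norm.pdf(y, mu, sd)
            r = lam * u_dens / (lam * u_dens + (1 - lam) * g + 1e-300)
            w = 1 - r
            if w.sum() < 2:
                ok = False
                break
            mu_new = float((w * y).sum() / w.sum())
            sd_new = float(np.sqrt((w * (y - mu_new) ** 2).sum() / w.sum()))
            lam_new = float(np.clip(r.mean(), 1e-4, 0.5))
            if abs(mu_new - mu) < 1e-10 and abs(sd_new - sd) < 1e-10:
                mu, sd, lam = mu_new, max(sd_new, 1e-4), lam_new
                break
            mu, sd, lam = mu_new, max(sd_new, 1e-4), lam_new
        else:
            ok = False
        if not ok:
            warnings.warn("mixture fit did not converge; no exclusion for condition")
            continue
        g = stats.norm.pdf(y, mu, sd)
        resp = lam * u_dens / (lam * u_dens + (1 - lam) * g + 1e-300)
        keep_mask[trials.index.get_indexer(grp.index)] &= resp <= 0.5
    kept = trials[keep_mask]
    return kept, int((~keep_mask).sum())


class ObserverModel:
    """Maximum-likelihood observer model for one session of trials.

    The per-trial likelihood marginalizes the unobserved measurement ``m``
    on a numerical grid (501 points spanning the measurement mean +/- 5 SD,
    trapezoidal rule):

        p(v_p | d) = ∫ N(m; d, w_m d) N(|v_p|; t_e(m) + b, sigma(t_e(m))) dm

    Parameters are ``(w_m, w_p, b)``; ``model_kind`` selects the production
    noise law.  Fitting uses bounded L-BFGS-B from a fixed multi-start grid,
    so results are deterministic.
    """

    param_names = ("w_m", "w_p", "offset_b")

    def __init__(
        self,
        trials: pd.DataFrame,
        model_kind: str = "scalar",
        prior: TaskPrior | None = None,
        n_grid: int = 501,
    ):
        self.prior = prior or TaskPrior()
        self.model_kind = model_kind
        self.n_grid = n_grid
        self.trials = trials
        self._d = np.abs(trials["v_a"].to_numpy(float))
        self._y = np.abs(trials["v_p"].to_numpy(float))
        self._uniq_d = np.unique(self._d)

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, **kw) -> "ObserverModel":
        return cls(trials, **kw)

    @property
    def nobs(self) -> int:
        return self._y.size

    def _trial_density(self, theta) -> np.ndarray:
        w_m, w_p, b = theta
        params = ObserverParams(w_m=max(w_m, 0.0), w_p=w_p, offset_b=b,
                                model_kind=self.model_kind, t_o=self.prior.t_o)
        dens = np.empty_like(self._y)
        for d in self._uniq_d:
            sel = self._d == d
            y = self._y[sel]
            if w_m < 1e-6:
                t_e = np.atleast_1d(bls_estimate(np.array([d]), self.prior, 0.0))
                sd = np.atleast_1d(production_sd(t_e, params))
                dens[sel] = stats.norm.pdf(y, t_e[0] + b, sd[0])
                continue
            sd_m = w_m * d
            m_grid = np.linspace(d - 5 * sd_m, d + 5 * sd_m, self.n_grid)
            lik_m = stats.norm.pdf(m_grid, d, sd_m)
            t_e = np.atleast_1d(bls_estimate(m_grid, self.prior, w_m))
            sd_p = np.atleast_1d(production_sd(t_e, params))
            # (n_trials, n_grid) production density, marginalized over m
            pdens = stats.norm.pdf(y[:, None], t_e[None, :] + b, sd_p[None, :])
            dens[sel] = np.trapezoid(pdens * lik_m[None, :], m_grid, axis=1)
        return dens

    def loglike(self, theta) -> float:
        dens = self._trial_density(theta)
        return float(np.log(np.maximum(dens, 1e-300)).sum())

    def fit(self, starts: np.ndarray | None = None) -> "ObserverResults":
        if starts is None:
            wm0 = [0.02, 0.08, 0.2]
            wp0 = [0.05, 0.1, 0.25]
            b0 = [-0.1, 0.0, 0.1]
            starts = np.array([(a, c, d) for a in wm0 for c in wp0 for d in b0])
        bounds = [_WM_BOUNDS, _WP_BOUNDS, _B_BOUNDS]
        neg = lambda th: -self.loglike(th)
        coarse = sorted(starts, key=neg)[:3]
        best = None
        for x0 in coarse:
            res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        at_bound = any(
            np.isclose(v, b[0]) or np.isclose(v, b[1])
            for v, b in zip(best.x, bounds)
        )
        return ObserverResults(self, best.x, -best.fun, at_bound)


class ObserverResults:
    """Fit results: parameter estimates, SEs, and a summary table."""

    def __init__(self, model: ObserverModel, params, llf, at_bound=False,
                 n_outliers_removed: int = 0):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.at_bound = bool(at_bound)
        self.n_outliers_removed = n_outliers_removed

    @property
    def observer(self) -> ObserverParams:
        return ObserverParams(
            w_m=self.params[0], w_p=self.params[1], offset_b=self.params[2],
            model_kind=self.model.model_kind, t_o=self.model.prior.t_o,
        )

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def aic(self) -> float:
        return 2 * len(self.params) - 2 * self.llf

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the observed information (numerical Hessian)."""
        from statsmodels.tools.numdiff import approx_hess

        h = approx_hess(self.params, self.model.loglike)
        with np.errstate(invalid="ignore"):
            cov = np.linalg.pinv(-h)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return se

    def mean_llf(self) -> float:
        return self.llf / self.nobs

    def predicted_bias_variance(self) -> pd.DataFrame:
        """Model-predicted mean and SD of |v_p| per distance (Monte Carlo free).

        Computed on the measurement grid: E[v_p|d] = E[t_e] + b and
        Var[v_p|d] = E[sigma^2] + Var[t_e].
        """
        p = self.observer
        rows = []
        for d in self.model._uniq_d:
            if p.w_m < 1e-6:
                t_e = np.array([bls_estimate(np.array([d]), self.model.prior, 0.0)])
                w = np.array([1.0])
            else:
                sd_m = p.w_m * d
                g = np.linspace(d - 5 * sd_m, d + 5 * sd_m, self.model.n_grid)
                w = stats.norm.pdf(g, d, sd_m)
                w = w / np.trapezoid(w, g)
                t_e = np.atleast_1d(bls_estimate(g, self.model.prior, p.w_m))
            if w.size == 1:
                e_te, v_te = float(t_e[0]), 0.0
                e_s2 = float(production_sd(t_e, p) ** 2)
            else:
                e_te = float(np.trapezoid(w * t_e, g))
                v_te = float(np.trapezoid(w * (t_e - e_te) ** 2, g))
                e_s2 = float(np.trapezoid(w * production_sd(t_e, p) ** 2, g))
            rows.append({"d": d, "mean": e_te + p.offset_b,
                         "sd": np.sqrt(e_s2 + v_te)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Bayesian observer model fit",
            "=" * 46,
            f"model kind:     {self.model.model_kind}",
            f"n trials:       {self.nobs}",
            f"log-likelihood: {self.llf:.2f}   AIC: {self.aic:.2f}",
            f"at bound:       {self.at_bound}",
            "-" * 46,
            f"{'param':>10} {'estimate':>10} {'std err':>10}",
        ]
        for name, v, s in zip(self.model.param_names, self.params, se):
            lines.append(f"{name:>10} {v:>10.4f} {s:>10.4f}")
        return "\n".join(lines)


def fit_mle(
    trials: pd.DataFrame,
    model_kind: str,
    prior: TaskPrior | None = None,
    remove_outliers: bool = True,
) -> ObserverResults:
    """Outlier exclusion followed by maximum-likelihood observer fitting."""
    n_removed = 0
    if remove_outliers:
        trials, n_removed = exclude_outliers(trials)
    res = ObserverModel(trials, model_kind=model_kind, prior=prior).fit()
    res.n_outliers_removed = n_removed
    return res


def compare_models(
    sessions: list[pd.DataFrame],
    prior: TaskPrior | None = None,
    metric: str = "mean_llf",
) -> dict:
    """Fit both observer kinds to each session and compare them.

    ``metric`` is the per-session goodness of fit: ``mean_llf`` (default) or
    ``bias_var_rmse`` (RMSE of the predicted per-distance mean and SD against
    the empirical ones; lower is better, so its sign is flipped before the
    paired test).  With >= 2 sessions a paired t-test of
    (subscalar - scalar) is reported; fewer sessions give descriptive output.
    """
    rows = []
    for i, s in enumerate(sessions):
        fits = {k: fit_mle(s, k, prior=prior) for k in ("scalar", "subscalar")}
        rec = {"session": i}
        for k, f in fits.items():
            rec[f"llf_{k}"] = f.mean_llf()
            if metric == "bias_var_rmse":
                pred = f.predicted_bias_variance()
                emp = (
                    s.assign(y=np.abs(s["v_p"]), d=np.abs(s["v_a"]))
                    .groupby("d")["y"].agg(["mean", "std"]).reset_index()
                )
                merged = pred.merge(emp, on="d")
                rec[f"rmse_{k}"] = float(
                    np.sqrt(
                        np.mean(
                            (merged["mean_x"] - merged["mean_y"]) ** 2
                            + (merged["sd"] - merged["std"]) ** 2
                        )
                    )
                )
        rows.append(rec)
    table = pd.DataFrame(rows)
    if metric == "mean_llf":
        delta = table["llf_subscalar"] - table["llf_scalar"]
    else:
        delta = table["rmse_scalar"] - table["rmse_subscalar"]
    out = {
        "table": table,
        "delta": delta.to_numpy(),
        "winner": "subscalar" if delta.mean() > 0 else "scalar",
    }
    if len(sessions) >= 2:
        # paired t-test == one-sample t-test on the per-session differences
        t, p = stats.ttest_1samp(out["delta"], 0.0)
        out.update({"t": float(t), "p": float(p)})
    return out
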