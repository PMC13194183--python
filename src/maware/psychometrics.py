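"""Motor-awareness proportions and psychometric threshold estimation.

The self-attribution probability is modelled as a descending cumulative
Gaussian of the absolute deviation d:

    P(yes | d) = lambda_low + (1 - lambda_low - lambda_high)
                 * (1 - Phi((d - mu) / sigma))

mu is the threshold (point of subjective equality, PSE) and 1/sigma the
sensitivity (slope) as conventionally reported. Parameters are estimated
by Bernoulli maximum likelihood with multi-start local optimization; the
upper lapse (ceiling below 1) is fitted by default because veridical
trials are self-attributed at only ~90%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

DESIGN_LEVELS = (0.0, 7.5, 15.0, 22.5, 30.0)

_EPS = 1e-12


class DegenerateDataError(ValueError):
    """Raised when the responses carry no threshold information."""


def _psi(d, mu, sigma, lapse_low, lapse_high):
    core = sps.norm.sf((np.asarray(d, dtype=float) - mu) / sigma)
    return lapse_low + (1.0 - lapse_low - lapse_high) * core


def _nll(params, d, n_yes, n_trials, lapse_low, lapse_high, fit_lapse):
    mu, sigma = params[0], params[1]
    lh = params[2] if fit_lapse else lapse_high
    p = np.clip(_psi(d, mu, sigma, lapse_low, lh), _EPS, 1.0 - _EPS)
    return -np.sum(n_yes * np.log(p) + (n_trials - n_yes) * np.log1p(-p))


class PsychometricCurve(BaseEstimator):
    """Cumulative-Gaussian yes/no psychometric model (descending in d).

    scikit-learn style estimator. `fit` accepts trial-level data
    (X = absolute deviation per trial, y = 0/1 response) or, via
    `fit_counts`, aggregated per-level counts.

    Parameters
    ----------
    lapse_low : float
        Fixed floor of the yes rate at large deviations.
    fit_lapse_high : bool
        Fit the ceiling lapse (bounded by `lapse_high_max`); otherwise it
        is fixed at `lapse_high`.
    lapse_high, lapse_high_max : float
        Fixed value / upper bound of the ceiling lapse.
    mu_bounds, sigma_bounds : tuple
        Box constraints of the optimizer, degrees. The default sigma
        floor of 2 reflects identifiability: spreads well below the
        7.5-degree spacing of the deviation levels cannot be resolved.
    n_starts : int
        The optimizer restarts from an `n_starts x n_starts` grid of
        (mu, sigma) values spanning the bounds; ties in log-likelihood
        are broken toward the smallest sigma.
    tol : float
        Log-likelihood convergence tolerance.

    Attributes
    ----------
    mu_, sigma_, slope_ : float
        Threshold (PSE), spread, and reported sensitivity 1/sigma.
    lapse_high_ : float
    loglik_ : float
    se_mu_ : float
        Standard error of mu from the observed information.
    converged_ : bool
    degenerate_ : bool
        True when the responses carry no threshold information
        (identical yes rate at every level).
    boundary_ : bool
        True when the optimum sits on the mu or sigma box boundary -
        typically observers whose threshold lies beyond the largest
        tested deviation, where the spread is unidentifiable and the
        likelihood favors a step at the last level. Boundary fits are
        excluded from group summaries.
    """

    def __init__(
        self,
        lapse_low: float = 0.0,
        fit_lapse_high: bool = True,
        lapse_high: float = 0.0,
        lapse_high_max: float = 0.15,
        mu_bounds: tuple[float, float] = (0.5, 60.0),
        sigma_bounds: tuple[float, float] = (2.0, 60.0),
        n_starts: int = 5,
        tol: float = 1e-8,
    ):
        self.lapse_low = lapse_low
        self.fit_lapse_high = fit_lapse_high
        self.lapse_high = lapse_high
        self.lapse_high_max = lapse_high_max
        self.mu_bounds = mu_bounds
        self.sigma_bounds = sigma_bounds
        self.n_starts = n_starts
        self.tol = tol

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        """Fit from trial-level data: X = |deviation| (deg), y = 0/1."""
        d = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(d) != len(y):
            raise ValueError("X and y must have equal length")
        levels, inv = np.unique(d, return_inverse=True)
        n_yes = np.bincount(inv, weights=y)
        n_trials = np.bincount(inv).astype(float)
        return self.fit_counts(levels, n_yes, n_trials)

    def fit_counts(self, levels, n_yes, n_trials):
        """Fit from aggregated counts per |deviation| level."""
        levels = np.asarray(levels, dtype=float)
        n_yes = np.asarray(n_yes, dtype=float)
        n_trials = np.asarray(n_trials, dtype=float)
        keep = n_trials > 0
        levels, n_yes, n_trials = levels[keep], n_yes[keep], n_trials[keep]
        if len(levels) < 3:
            raise ValueError("need trials at >= 3 deviation levels")
        props = n_yes / n_trials
        self.degenerate_ = bool(np.ptp(props) < 1e-9)
        if self.degenerate_:
            self.mu_ = self.sigma_ = self.slope_ = np.nan
            self.lapse_high_ = np.nan
            self.loglik_ = np.nan
            self.se_mu_ = np.nan
            self.converged_ = False
            self.boundary_ = False
            return self

        args = (levels, n_yes, n_trials, self.lapse_low, self.lapse_high,
                self.fit_lapse_high)
        bounds = [self.mu_bounds, self.sigma_bounds]
        if self.fit_lapse_high:
            bounds.append((0.0, self.lapse_high_max))
        mu_starts = np.linspace(*self.mu_bounds, self.n_starts + 2)[1:-1]
        sigma_starts = np.geomspace(*self.sigma_bounds, self.n_starts + 2)[1:-1]
        best = None
        for mu0 in mu_starts:
            for s0 in sigma_starts:
                x0 = [mu0, s0] + ([0.05] if self.fit_lapse_high else [])
                res = optimize.minimize(
                    _nll, x0, args=args, method="L-BFGS-B", bounds=bounds,
                    options={"ftol": self.tol, "maxiter": 500},
                )
                if best is None or res.fun < best.fun - 1e-10 or (
                    abs(res.fun - best.fun) <= 1e-10 and res.x[1] < best.x[1]
                ):
                    best = res
        self.mu_ = float(best.x[0])
        self.sigma_ = float(best.x[1])
        self.slope_ = 1.0 / self.sigma_
        self.lapse_high_ = float(best.x[2]) if self.fit_lapse_high else self.lapse_high
        self.loglik_ = -float(best.fun)
        self.converged_ = bool(best.success)
        eps = 1e-6
        self.boundary_ = bool(
            self.mu_ <= self.mu_bounds[0] + eps
            or self.mu_ >= self.mu_bounds[1] - eps
            or self.sigma_ <= self.sigma_bounds[0] + eps
            or self.sigma_ >= self.sigma_bounds[1] - eps
        )
        self.se_mu_ = self._se_mu(best.x, args)
        self.n_levels_ = len(levels)
        return self

    def _se_mu(self, x, args) -> float:
        """SE of mu from a central-difference observed information matrix."""
        k = len(x)
        h = np.maximum(1e-4, 1e-4 * np.abs(x))
        hess = np.zeros((k, k))
        f0 = _nll(x, *args)
        for i in range(k):
            for j in range(i, k):
                xi, xj = np.zeros(k), np.zeros(k)
                xi[i], xj[j] = h[i], h[j]
                fpp = _nll(x + xi + xj, *args)
                fpm = _nll(x + xi - xj, *args)
                fmp = _nll(x - xi + xj, *args)
                fmm = _nll(x - xi - xj, *args)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(hess)
            var = cov[0, 0]
            return float(np.sqrt(var)) if var > 0 else float("nan")
        except np.linalg.LinAlgError:
            return float("nan")

    # -- prediction --------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """P(yes) at the given absolute deviations."""
        check_is_fitted(self, "mu_")
        if self.degenerate_:
            raise DegenerateDataError("no fitted curve for degenerate data")
        return _psi(X, self.mu_, self.sigma_, self.lapse_low, self.lapse_high_)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    @property
    def slope_at_pse_(self) -> float:
        """Derivative of the fitted curve at the PSE (per degree)."""
        check_is_fitted(self, "mu_")
        return float(
            (1.0 - self.lapse_low - self.lapse_high_)
            / (self.sigma_ * np.sqrt(2 * np.pi))
        )


def fit_psychometric(levels, n_yes, n_trials, **kwargs) -> PsychometricCurve:
    """Functional wrapper over :class:`PsychometricCurve`."""
    return PsychometricCurve(**kwargs).fit_counts(levels, n_yes, n_trials)


def grid_search_loglik(
    levels,
    n_yes,
    n_trials,
    mu_grid=None,
    sigma_grid=None,
    lapse_grid=None,
    lapse_low: float = 0.0,
) -> float:
    """Best Bernoulli log-likelihood over an exhaustive parameter grid.

    Independent check of the MLE: a correct optimizer can never do worse
    than the best point of this (mu, sigma, lapse_high) grid. Defaults:
    21 x 21 (mu, sigma) by 16 lapse values.
    """
    mu = np.asarray(mu_grid if mu_grid is not None else np.linspace(0.5, 60, 21))
    sg = np.asarray(sigma_grid if sigma_grid is not None else np.geomspace(2.0, 60, 21))
    lh = np.asarray(lapse_grid if lapse_grid is not None else np.linspace(0, 0.15, 16))
    d = np.asarray(levels, dtype=float)
    n_yes = np.asarray(n_yes, dtype=float)
    n_trials = np.asarray(n_trials, dtype=float)
    core = sps.norm.sf(
        (d[None, None, :] - mu[:, None, None]) / sg[None, :, None]
    )  # (mu, sigma, level)
    p = lapse_low + (1.0 - lapse_low - lh[:, None, None, None]) * core[None]
    p = np.clip(p, _EPS, 1 - _EPS)
    ll = np.sum(n_yes * np.log(p) + (n_trials - n_yes) * np.log1p(-p), axis=-1)
    return float(ll.max())


# ---------------------------------------------------------------------------
# tabulation, exclusion, group summaries


def ma_proportions(trials: pd.DataFrame, by_mode: bool = True) -> pd.DataFrame:
    """Tabulate yes counts per condition cell.

    One row per (participant, effector, task, mode, |deviation|) with
    n_trials, n_yes and the yes proportion. Control trials keep their own
    mode; deviated trials are grouped by mode (converging/diverging)
    without collapsing across target side before mode assignment. With
    `by_mode=False`, modes are pooled within |deviation| (the grouping
    used for the threshold fits).
    """
    df = trials.copy()
    df["abs_deviation"] = df["deviation_deg"].abs()
    keys = ["participant", "effector", "task"]
    keys += ["mode"] if by_mode else []
    keys += ["abs_deviation"]
    grouped = (
        df.groupby(keys, as_index=False)
        .agg(n_trials=("response_yes", "size"), n_yes=("response_yes", "sum"))
    )
    grouped["proportion_yes"] = grouped["n_yes"] / grouped["n_trials"]
    return grouped


def control_yes_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant control-trial yes rate per effector (tasks pooled)."""
    ctrl = trials[trials["deviation_deg"] == 0]
    out = (
        ctrl.groupby(["participant", "effector"], as_index=False)
        .agg(n_trials=("response_yes", "size"), n_yes=("response_yes", "sum"))
    )
    out["proportion_yes"] = out["n_yes"] / out["n_trials"]
    return out


def exclusion_check(
    proportions: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Participant-level exclusion rule.

    A participant is dropped when the yes proportion is below 50% at
    every deviation level *including* control trials (the fitted curve
    never rises above the point of subjective equality). Exactly 50% at
    control keeps the participant (strict inequality). Returns one row
    per participant with keep flag and reason.
    """
    rows = []
    for pid, sub in proportions.groupby("participant"):
        per_level = sub.groupby("abs_deviation")["n_yes"].sum() / sub.groupby(
            "abs_deviation"
        )["n_trials"].sum()
        drop = bool((per_level < threshold).all())
        rows.append(
            {
                "participant": pid,
                "keep": not drop,
                "reason": (
                    "yes rate below 0.5 at every level including control"
                    if drop
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def group_ci(mean: float, sd: float, n: int, ndigits: int | None = None):
    """t-based 95% confidence interval mean +/- t(0.975, n-1) sd/sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    lo, hi = mean - half, mean + half
    if ndigits is not None:
        lo, hi = round(lo, ndigits), round(hi, ndigits)
    return float(lo), float(hi)


@dataclass(frozen=True)
class GroupSummary:
    effector: str
    task: str
    quantity: str  # "threshold" or "slope"
    mean: float
    sd: float
    n: int
    ci95: tuple[float, float]


def fit_cohort(
    trials: pd.DataFrame,
    include_control: bool = True,
    per_mode: bool = False,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one psychometric curve per participant x effector x task
    (x mode when `per_mode`). Returns a tidy frame of fits."""
    props = ma_proportions(trials, by_mode=per_mode)
    if not include_control:
        props = props[props["abs_deviation"] > 0]
    keys = ["participant", "effector", "task"] + (["mode"] if per_mode else [])
    rows = []
    for key, sub in props.groupby(keys):
        model = PsychometricCurve(**fit_kwargs).fit_counts(
            sub["abs_deviation"].to_numpy(),
            sub["n_yes"].to_numpy(),
            sub["n_trials"].to_numpy(),
        )
        rec = dict(zip(keys, key))
        rec.update(
            mu=model.mu_,
            sigma=model.sigma_,
            slope=model.slope_,
            lapse_low=model.lapse_low,
            lapse_high=model.lapse_high_,
            loglik=model.loglik_,
            se_mu=model.se_mu_,
            converged=model.converged_,
            degenerate=model.degenerate_,
            boundary=model.boundary_,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_table1(fits: pd.DataFrame, round_output: bool = True) -> pd.DataFrame:
    """Group summary of thresholds and slopes per effector x task.

    Mean +/- SD and the t-based 95% CI over participants, excluding
    non-converged, degenerate, and boundary fits; thresholds reported at
    2 decimals and slopes at 3 (the conventional rounding for these
    quantities).
    """
    ok = fits[fits["converged"] & ~fits["degenerate"] & ~fits["boundary"]]
    rows = []
    for (eff, task), sub in ok.groupby(["effector", "task"]):
        for qty, col, nd in (("threshold", "mu", 2), ("slope", "slope", 3)):
            vals = sub[col].to_numpy()
            mean, sd, n = float(vals.mean()), float(vals.std(ddof=1)), len(vals)
            nd_out = nd if round_output else None
            ci = group_ci(mean, sd, n, ndigits=nd_out)
            rows.append(
                {
                    "effector": eff,
                    "task": task,
                    "quantity": qty,
                    "mean": round(mean, nd) if round_output else mean,
                    "sd": round(sd, nd) if round_output else sd,
                    "n": n,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                }
            )
    return pd.DataFrame(rows)


def export_tidy(trials: pd.DataFrame, kinematics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format trial table for external mixed-model fitting.

    One row per analyzed trial with the six independent variables
    (Deviation, Deviation Side, Target Side, Task, Mode, Effector), the
    response, response time, and - when available - the kinematic metrics.
    """
    out = trials.copy()
    out["deviation"] = out["deviation_deg"].abs()
    out["deviation_side"] = np.sign(out["deviation_deg"]).map(
        {1.0: "clockwise", -1.0: "counterclockwise", 0.0: "none"}
    )
    cols = [
        "participant",
        "effector",
        "task",
        "trial_index",
        "deviation",
        "deviation_side",
        "target_side",
        "mode",
        "response_yes",
        "response_time_s",
    ]
    out = out[cols]
    if kinematics is not None:
        out = out.merge(
            kinematics,
            on=["participant", "effector", "task", "trial_index"],
            how="left",
        )
    return out
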