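"""Survival-analysis primitives: Kaplan–Meier, log-rank, Cox partial likelihood.

These are implemented directly (rather than delegated) because downstream
modules need fine control: the score test at ``beta = 0`` (whose statistic for
a binary covariate reproduces the log-rank chi-square when event times are
untied), an Efron/Breslow tie-handling switch, and explicit monotone-likelihood
flagging so permutation replicates never return a silently wrong estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "KaplanMeierCurve",
    "km_estimate",
    "censoring_km",
    "logrank_test",
    "CoxFit",
    "fit_cox",
]

MONOTONE_BETA_BOUND = 20.0


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit estimate as a right-continuous step function.

    ``times`` holds the strictly increasing grid of jump times (times where at
    least one "event", in the sense of the estimated distribution, occurred);
    ``surv[k]`` is S(times[k]).  S(t) before the first jump is 1.
    """

    times: np.ndarray
    surv: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("grid times must be strictly increasing")
        if np.any(self.surv < -1e-12) or np.any(self.surv > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival curve must be non-increasing")

    def evaluate(self, t: float | np.ndarray) -> np.ndarray | float:
        """S(t): value at the largest jump time <= t (right-continuous)."""
        if self.times.size == 0:
            vals = np.ones_like(np.asarray(t, dtype=float))
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            vals = np.where(idx < 0, 1.0, self.surv[np.clip(idx, 0, None)])
        return float(vals) if np.isscalar(t) else vals

    def evaluate_left(self, t: float | np.ndarray) -> np.ndarray | float:
        """S(t-): left limit, value just before t."""
        if self.times.size == 0:
            vals = np.ones_like(np.asarray(t, dtype=float))
        else:
            idx = np.searchsorted(self.times, t, side="left") - 1
            vals = np.where(idx < 0, 1.0, self.surv[np.clip(idx, 0, None)])
        return float(vals) if np.isscalar(t) else vals


def _check_surv_input(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times: np.ndarray, events: np.ndarray) -> KaplanMeierCurve:
    """Kaplan–Meier product-limit estimator.

    At a tied time point deaths are processed before censorings, i.e. a
    subject censored at t is still at risk for the death at t.
    """
    times, events = _check_surv_input(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = t_sorted.size

    grid: list[float] = []
    surv: list[float] = []
    at_risk: list[int] = []
    deaths: list[int] = []
    s = 1.0
    i = 0
    while i < n:
        t = t_sorted[i]
        j = i
        d = 0
        while j < n and t_sorted[j] == t:
            d += int(e_sorted[j])
            j += 1
        risk = n - i
        if d > 0:
            s *= 1.0 - d / risk
            grid.append(t)
            surv.append(s)
            at_risk.append(risk)
            deaths.append(d)
        i = j
    return KaplanMeierCurve(
        times=np.array(grid), surv=np.array(surv),
        n_at_risk=np.array(at_risk, dtype=int), n_events=np.array(deaths, dtype=int),
    )


def censoring_km(times: np.ndarray, events: np.ndarray) -> KaplanMeierCurve:
    """Kaplan–Meier of the censoring distribution, G-hat.

    The roles of death and censoring are swapped (indicator ``1 - event``);
    used as the inverse-probability-of-censoring weight in the Brier score,
    evaluated at the left limit G(t-) for subjects with an observed event.
    """
    times, events = _check_surv_input(times, events)
    return km_estimate(times, 1 - events)


def _logrank_moments(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Sum over event times of (O1 - E1) and the hypergeometric variance."""
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_total = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d1 = int((dying & (group == 1)).sum())
        obs_minus_exp += d1 - d * n1 / n_total
        if n_total > 1:
            var += d * (n1 / n_total) * (1 - n1 / n_total) * (n_total - d) / (n_total - 1)
    return obs_minus_exp, var


def logrank_test(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 degree of freedom."""
    times, events = _check_surv_input(times, events)
    group = np.asarray(group, dtype=int)
    if len(np.unique(group)) < 2:
        raise ValueError("degenerate grouping: only one group present")
    if events.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    o_minus_e, var = _logrank_moments(times, events, group)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxFit:
    """Result of maximizing the Cox partial likelihood.

    ``score_chi2``/``score_p`` hold the global score test of all coefficients
    being zero, evaluated at beta = 0 (the log-rank statistic for a single
    binary covariate on untied data).
    """

    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik_null: float
    loglik_full: float
    converged: bool
    monotone: bool
    n_iter: int
    ties_method: str
    score_chi2: float
    score_p: float
    names: list[str] = field(default_factory=list)

    @property
    def lr_statistic(self) -> float:
        """Likelihood-ratio statistic 2*(l(beta-hat) - l(0))."""
        return 2.0 * (self.loglik_full - self.loglik_null)

    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z()))


def _cox_quantities(beta: np.ndarray, x: np.ndarray, first: np.ndarray, death_blocks: list[np.ndarray],
                    ties: str) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and information at beta.

    ``x`` is sorted by ascending time; ``first[k]`` is the row index where the
    risk set of the k-th distinct event time starts; ``death_blocks[k]`` the
    row indices of the deaths at that time.
    """
    n, p = x.shape
    eta = x @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]
    # suffix sums over the risk set (rows i..n-1)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for k, dk in enumerate(death_blocks):
        f = first[k]
        m = len(dk)
        ll += float(eta[dk].sum())
        grad += x[dk].sum(axis=0)
        r0, r1, r2 = s0[f], s1[f], s2[f]
        if ties == "breslow" or m == 1:
            ll -= m * np.log(r0)
            grad -= m * r1 / r0
            info += m * (r2 / r0 - np.outer(r1, r1) / r0**2)
        else:  # efron
            d0 = w[dk].sum()
            d1 = wx[dk].sum(axis=0)
            d2 = wxx[dk].sum(axis=0)
            for ell in range(m):
                phi = ell / m
                q0 = r0 - phi * d0
                q1 = r1 - phi * d1
                q2 = r2 - phi * d2
                ll -= np.log(q0)
                grad -= q1 / q0
                info += q2 / q0 - np.outer(q1, q1) / q0**2
    return ll, grad, info


def fit_cox(covariates: np.ndarray, times: np.ndarray, events: np.ndarray, *,
            ties: str = "efron", names: list[str] | None = None,
            max_iter: int = 50, score_tol: float = 1e-9, loglik_tol: float = 1e-12) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Starts at beta = 0 with step-halving on likelihood decrease.  Declares
    monotone likelihood (the partial analogue of perfect separation) when any
    coefficient wanders past ``MONOTONE_BETA_BOUND`` during iteration, and
    returns ``converged = False`` rather than an unflagged wrong answer.

    Parameters
    ----------
    covariates : (n, p) design matrix, no constant column.
    ties : ``"efron"`` (default) or ``"breslow"``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    times, events = _check_surv_input(times, events)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.ndim != 2 or x.shape[0] != times.size:
        x = x.reshape(times.size, -1)
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if events.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    if p < 1:
        raise ValueError("need at least one covariate")
    const = np.all(x == x[0, :], axis=0)
    if const.any():
        which = names[int(np.argmax(const))] if names else f"column {int(np.argmax(const))}"
        raise ValueError(f"constant covariate: {which}")

    order = np.argsort(times, kind="stable")
    xs = x[order]
    ts = times[order]
    es = events[order]
    event_times = np.unique(ts[es == 1])
    first = np.searchsorted(ts, event_times, side="left")
    death_blocks = [np.flatnonzero((ts == t) & (es == 1)) for t in event_times]

    beta = np.zeros(p)
    ll0, grad0, info0 = _cox_quantities(beta, xs, first, death_blocks, ties)
    # global score test at beta = 0
    try:
        score_chi2 = float(grad0 @ np.linalg.solve(info0, grad0))
    except np.linalg.LinAlgError:
        score_chi2 = float("nan")
    score_p = float(stats.chi2.sf(score_chi2, df=p)) if np.isfinite(score_chi2) else float("nan")

    ll, grad, info = ll0, grad0, info0
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < score_tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_quantities(new_beta, xs, first, death_blocks, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_quantities(new_beta, xs, first, death_blocks, ties)
            halvings += 1
        if np.max(np.abs(new_beta)) > MONOTONE_BETA_BOUND:
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
            monotone = True
            break
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(grad)) < score_tol or rel_change < loglik_tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
    if monotone:
        converged = False
    return CoxFit(
        coef=beta, se=se, cov=cov,
        loglik_null=float(ll0), loglik_full=float(ll),
        converged=converged, monotone=monotone, n_iter=it,
        ties_method=ties, score_chi2=score_chi2, score_p=score_p,
        names=list(names) if names else [f"x{j}" for j in range(p)],
    )
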