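"""Performance metrics for predicted survival risk scores.

The suite mirrors the standard battery for prognostic models: Somers' D_xy
rank correlation (a censoring-adjusted concordance), the simple hazard ratio
with a likelihood-ratio R-squared ("Cox Model I"), the two-group hazard ratio
after dichotomizing at the training-score median ("Cox Model II") with an
integrated Brier score, the log-rank test on the same dichotomy, and the
time-dependent ROC curve/AUC at fixed survival thresholds.

Sign convention: D_xy is the rank correlation between risk score and survival
time, so a well-performing model (high risk <-> short survival) produces a
NEGATIVE D_xy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import SurvivalDataset
from .models import FittedModel, RiskScores, predict_risk
from .survival import censoring_km, fit_cox, km_estimate, logrank_test

__all__ = [
    "MetricReport",
    "RocCurve",
    "ThresholdScan",
    "somers_dxy",
    "cox_model_one",
    "cox_model_two",
    "integrated_brier_two_group",
    "roc_auc_at",
    "logrank_threshold_scan",
    "evaluate_all",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


def _scores_array(scores: RiskScores | np.ndarray) -> np.ndarray:
    if isinstance(scores, RiskScores):
        return scores.values
    return np.asarray(scores, dtype=float)


def somers_dxy(scores: RiskScores | np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Somers' D_xy = 2c - 1, with c the score-vs-time concordance over usable pairs.

    A pair is usable when the subject with the shorter observed time had the
    event (a censored subject tied in time with an event counts as the longer
    survivor).  A usable pair is concordant when the longer-surviving subject
    also has the higher score; score ties contribute 1/2.  Perfect risk
    prediction therefore yields D_xy = -1.
    """
    s = _scores_array(scores)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    # vectorized pair enumeration: i is the earlier event
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    ej = e[None, :]
    usable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    si, sj = s[:, None], s[None, :]
    conc = np.where(si < sj, 1.0, np.where(si == sj, 0.5, 0.0))
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no comparable pairs")
    c = float(conc[usable].sum()) / n_usable
    return 2.0 * c - 1.0


def _hr_block(fit, index: int = 0) -> dict:
    beta = float(fit.coef[index])
    se = float(fit.se[index])
    return {
        "hr": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - Z_95 * se)),
        "ci_high": float(np.exp(beta + Z_95 * se)),
        "p": float(fit.wald_p()[index]),
    }


def cox_model_one(scores: RiskScores | np.ndarray, times: np.ndarray, events: np.ndarray, *,
                  ties: str = "efron") -> dict:
    """Cox fit with the risk score as the single covariate.

    Returns hazard ratio per unit score with Wald 95% CI and p, plus the
    likelihood-ratio R-squared ``1 - exp(-LR/n)``.
    """
    s = _scores_array(scores)
    if np.all(s == s[0]):
        raise ValueError("constant risk scores")
    fit = fit_cox(s[:, None], times, events, ties=ties, names=["score"])
    if not fit.converged:
        return {"hr": None, "ci_low": None, "ci_high": None, "p": None, "r2": None,
                "converged": False, "monotone": fit.monotone}
    out = _hr_block(fit)
    out["r2"] = float(1.0 - np.exp(-fit.lr_statistic / s.size))
    out["converged"] = True
    return out


def two_group_indicator(train_scores: RiskScores | np.ndarray, test_scores: RiskScores | np.ndarray) -> np.ndarray:
    """High-risk indicator: test score strictly above the training median.

    Scores exactly equal to the median fall in the low-risk group.
    """
    if isinstance(train_scores, RiskScores):
        median = float(np.median(train_scores.values))
    else:
        median = float(np.median(np.asarray(train_scores, dtype=float)))
    ts = _scores_array(test_scores)
    return (ts > median).astype(int)


def cox_model_two(train_scores: RiskScores | np.ndarray, test_scores: RiskScores | np.ndarray,
                  times: np.ndarray, events: np.ndarray, *, ties: str = "efron") -> dict:
    """Two-group hazard ratio: Cox fit on the high-vs-low-risk indicator."""
    group = two_group_indicator(train_scores, test_scores)
    n_high = int(group.sum())
    n_low = int(group.size - n_high)
    if n_high == 0 or n_low == 0:
        raise ValueError("degenerate dichotomy: all test scores on one side of the training median")
    fit = fit_cox(group[:, None].astype(float), times, events, ties=ties, names=["high_risk"])
    if not fit.converged:
        return {"hr": None, "ci_low": None, "ci_high": None, "p": None,
                "n_high": n_high, "n_low": n_low, "converged": False, "monotone": fit.monotone}
    out = _hr_block(fit)
    out.update(n_high=n_high, n_low=n_low, converged=True)
    return out


def integrated_brier_two_group(group: np.ndarray, times: np.ndarray, events: np.ndarray,
                               tau: float | None = None) -> float:
    """Integrated Brier score of the two-group Kaplan–Meier prediction.

    Each subject's predicted event-free probability is the KM curve of their
    own group, so no baseline hazard is estimated.  Censoring is handled by
    inverse-probability weights from the pooled censoring KM G-hat (Graf):

    * ``T_i <= t``, event:   S_g(t)^2 / G(T_i-)
    * ``T_i > t``:           (1 - S_g(t))^2 / G(t)
    * censored before t:     0

    The integral (1/tau) * int_0^tau BS(t) dt is evaluated exactly over the
    step-function segments; ``tau`` defaults to the largest observed time.
    If G-hat reaches 0 before tau the integration is truncated there.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group, dtype=int)
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be non-empty")
    if tau is None:
        tau = float(t.max())
    if tau <= 0:
        raise ValueError("tau must be positive")

    km_by_group = {lvl: km_estimate(t[g == lvl], e[g == lvl]) for lvl in np.unique(g)}
    ghat = censoring_km(t, e)

    # truncate where the censoring survival hits zero (weights undefined beyond)
    zero = ghat.surv <= 0
    tau_eff = min(tau, float(ghat.times[zero][0])) if zero.any() else tau

    breaks = np.unique(np.concatenate([[0.0], t[t < tau_eff], [tau_eff]]))
    integral = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        integral += _brier_at(a, t, e, g, km_by_group, ghat) * (b - a)
    return float(integral / tau_eff)


def _brier_at(t0: float, t: np.ndarray, e: np.ndarray, g: np.ndarray,
              km_by_group: dict, ghat) -> float:
    """BS(t0): mean weighted squared error of event-free status vs prediction."""
    n = t.size
    total = 0.0
    for lvl, km in km_by_group.items():
        s_pred = float(km.evaluate(t0))
        members = g == lvl
        # events by t0: contribute S(t0)^2 weighted by 1/G(T_i-)
        had_event = members & (t <= t0) & (e == 1)
        if had_event.any():
            w = ghat.evaluate_left(t[had_event])
            w = np.asarray(w, dtype=float)
            ok = w > 0
            total += float(np.sum(s_pred**2 / w[ok]))
        # still at risk past t0: contribute (1 - S(t0))^2 weighted by 1/G(t0)
        n_alive = int((members & (t > t0)).sum())
        if n_alive:
            g_t0 = float(ghat.evaluate(t0))
            if g_t0 > 0:
                total += n_alive * (1.0 - s_pred) ** 2 / g_t0
    return total / n


@dataclass
class RocCurve:
    """Empirical time-dependent ROC at survival threshold t.

    Cases are subjects with an observed event by t; controls survive past t;
    subjects censored before t are excluded (their 5-year-style status is
    unknown) and counted in ``n_excluded``.
    """

    t: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_cases: int
    n_controls: int
    n_excluded: int

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity


def roc_auc_at(scores: RiskScores | np.ndarray, times: np.ndarray, events: np.ndarray,
               t: float) -> tuple[RocCurve, float]:
    """ROC curve and AUC for classifying events by time t with score cutoffs.

    Every unique score is a cutoff (score strictly greater => predicted case);
    the trapezoid AUC equals the tie-corrected Mann–Whitney statistic over
    case/control score pairs.
    """
    s = _scores_array(scores)
    tv = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    case = (tv <= t) & (e == 1)
    control = tv > t
    excluded = (tv <= t) & (e == 0)
    n_cases, n_controls = int(case.sum()), int(control.sum())
    if n_cases == 0:
        raise ValueError(f"no cases (events by t={t})")
    if n_controls == 0:
        raise ValueError(f"no controls (survivors past t={t})")

    cutoffs = np.unique(s[case | control])  # ascending
    sens = np.empty(cutoffs.size + 1)
    spec = np.empty(cutoffs.size + 1)
    s_case = s[case]
    s_control = s[control]
    for i, c in enumerate(cutoffs):
        sens[i] = np.mean(s_case > c)
        spec[i] = np.mean(s_control <= c)
    # virtual cutoff below the minimum: everything predicted a case -> (1,1)
    sens[-1] = 1.0
    spec[-1] = 0.0
    order = np.lexsort((sens, 1.0 - spec))  # monotone staircase: fpr, then tpr
    fpr = (1.0 - spec)[order]
    tpr = sens[order]
    auc = float(np.trapezoid(tpr, fpr))
    curve = RocCurve(t=float(t), cutoffs=cutoffs, sensitivity=sens[:-1], specificity=spec[:-1],
                     n_cases=n_cases, n_controls=n_controls, n_excluded=int(excluded.sum()))
    return curve, auc


@dataclass
class ThresholdScan:
    """Log-rank p-value for every possible low-risk group size.

    Entry k (1-based) puts the k smallest risk scores in the low-risk group.
    Cut points falling inside a run of tied scores are flagged: they are not
    realizable as a score threshold.
    """

    k: np.ndarray
    n_low: np.ndarray
    n_high: np.ndarray
    pvalues: np.ndarray
    tied_cutoff: np.ndarray
    degenerate: np.ndarray


def logrank_threshold_scan(scores: RiskScores | np.ndarray, times: np.ndarray,
                           events: np.ndarray) -> ThresholdScan:
    """Scan all n-1 cut points between score order statistics."""
    s = _scores_array(scores)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    ks = np.arange(1, n)
    pvals = np.ones(n - 1)
    tied = np.zeros(n - 1, dtype=bool)
    degen = np.zeros(n - 1, dtype=bool)
    for i, k in enumerate(ks):
        group = np.ones(n, dtype=int)
        group[order[:k]] = 0  # low-risk = k smallest scores
        tied[i] = s_sorted[k - 1] == s_sorted[k]
        try:
            _, pvals[i] = logrank_test(t, e, group)
        except ValueError:
            degen[i] = True
            pvals[i] = 1.0
    return ThresholdScan(k=ks, n_low=ks, n_high=n - ks, pvalues=pvals,
                         tied_cutoff=tied, degenerate=degen)


@dataclass
class MetricReport:
    """Full metric battery for one model on one test cohort."""

    model_id: str
    dxy: float | None
    cox1: dict | None
    cox2: dict | None
    ibs: float | None
    logrank_chi2: float | None
    logrank_p: float | None
    auc_by_time: dict[float, float]
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        """Flatten to one table row (hazard-ratio table layout)."""
        row: dict = {"model": self.model_id, "dxy": self.dxy}
        c1 = self.cox1 or {}
        row.update(r2=c1.get("r2"), hr_1=c1.get("hr"), ci_low_1=c1.get("ci_low"),
                   ci_high_1=c1.get("ci_high"), p_1=c1.get("p"))
        c2 = self.cox2 or {}
        row.update(hr_2=c2.get("hr"), ci_low_2=c2.get("ci_low"), ci_high_2=c2.get("ci_high"),
                   p_2=c2.get("p"), ibs=self.ibs, logrank_p=self.logrank_p)
        for t, auc in sorted(self.auc_by_time.items()):
            row[f"auc_{t:g}"] = auc
        row["flags"] = ";".join(self.flags)
        return row


def evaluate_all(model: FittedModel, train: SurvivalDataset, test: SurvivalDataset,
                 t_list: list[float] = ()) -> MetricReport:
    """Score the test cohort and compute the whole metric battery.

    Partial failures (degenerate dichotomy, constant scores, non-convergence)
    are recorded in ``flags`` rather than raised, so a batch evaluation never
    dies on one pathological model.
    """
    test_scores = predict_risk(model, test)
    flags = list(model.warnings)
    dxy = cox1 = cox2 = ibs = None
    lr_chi2 = lr_p = None
    auc_by_time: dict[float, float] = {}

    try:
        dxy = somers_dxy(test_scores, test.time, test.event)
    except ValueError as exc:
        flags.append(f"dxy: {exc}")
    try:
        cox1 = cox_model_one(test_scores, test.time, test.event, ties=model.spec.ties)
        if not cox1.get("converged", True):
            flags.append("cox1: non-convergence")
    except ValueError as exc:
        flags.append(f"cox1: {exc}")
    try:
        cox2 = cox_model_two(model.training_scores, test_scores, test.time, test.event,
                             ties=model.spec.ties)
        if not cox2.get("converged", True):
            flags.append("cox2: non-convergence")
        group = two_group_indicator(model.training_scores, test_scores)
        ibs = integrated_brier_two_group(group, test.time, test.event)
        lr_chi2, lr_p = logrank_test(test.time, test.event, group)
    except ValueError as exc:
        flags.append(f"two-group: {exc}")
    for t in t_list:
        try:
            _, auc_by_time[float(t)] = roc_auc_at(test_scores, test.time, test.event, t)
        except ValueError as exc:
            flags.append(f"auc(t={t}): {exc}")
    return MetricReport(model_id=model.spec.model_id, dxy=dxy, cox1=cox1, cox2=cox2,
                        ibs=ibs, logrank_chi2=lr_chi2, logrank_p=lr_p,
                        auc_by_time=auc_by_time, flags=flags)
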