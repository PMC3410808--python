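"""Permutation significance for prediction metrics.

The null hypothesis is that the training outcomes carry no information about
the test outcomes through the fitted signature.  Null datasets are generated
by jointly permuting the (time, event) pairs of the training cohort across
subjects; covariates stay fixed, so each replicate conserves the outcome
multiset exactly.  Two null constructions are offered:

* **M1** (conditional): the gene selection and PCA loadings derived from the
  observed training data are kept; only the Cox coefficients are refit on the
  permuted outcomes.
* **M2** (unconditional): screening, ranking and PCA are re-derived from
  scratch on each permuted dataset.

For a purely clinical model the two coincide replicate-by-replicate.

The permutation p-value is the proportion of null replicates whose metric is
at least as extreme as the observed one, extremeness pointing in the
direction of better-than-null prediction: more negative D_xy, smaller Cox
p-value, larger R-squared, larger AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import SurvivalDataset
from .models import FittedModel, ModelSpec, RiskScores, build_model, predict_risk
from .survival import fit_cox
from .metrics import cox_model_one, roc_auc_at, somers_dxy

__all__ = [
    "RandTestConfig",
    "RandTestResult",
    "permute_training",
    "randomization_test",
]

METRICS = ("dxy", "cox1_p", "r2", "auc")

# direction in which a null value counts as "at least as extreme as observed"
_LOWER_IS_EXTREME = {"dxy": True, "cox1_p": True, "r2": False, "auc": False}


@dataclass(frozen=True)
class RandTestConfig:
    """Settings for one randomization test run.

    ``n_perm`` defaults to 10,000 (the resolution used for the reference
    analyses); scale it down for quick checks — the p-value granularity is
    1/n_perm.  ``plus_one`` switches on the (r+1)/(n+1) smoothing that keeps
    p-values away from exactly zero (off by default).
    """

    model_spec: ModelSpec
    n_perm: int = 10_000
    mode: str = "M1"
    metrics: tuple[str, ...] = ("dxy", "cox1_p", "r2")
    t_list: tuple[float, ...] = ()
    seed: int = 0
    plus_one: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.mode not in ("M1", "M2"):
            raise ValueError(f"mode must be M1 or M2, got {self.mode!r}")
        bad = set(self.metrics) - set(METRICS)
        if bad:
            raise ValueError(f"unknown metrics {sorted(bad)}")
        if "auc" in self.metrics and not self.t_list:
            raise ValueError("auc requested but t_list is empty")


@dataclass
class MetricNull:
    """Observed value, null draws and permutation p for one metric."""

    observed: float
    p: float
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    n_extreme: int
    n_failed: int
    null_values: np.ndarray = field(repr=False)


@dataclass
class RandTestResult:
    mode: str
    seed: int
    n_perm: int
    metrics: dict[str, MetricNull]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "seed": self.seed, "n_perm": self.n_perm,
            "metrics": {
                name: {
                    "observed": m.observed, "p": m.p,
                    "null_mean": m.null_mean, "null_sd": m.null_sd,
                    "null_quantiles": m.null_quantiles,
                    "n_extreme": m.n_extreme, "n_failed": m.n_failed,
                }
                for name, m in self.metrics.items()
            },
        }


def permute_training(train: SurvivalDataset, rng: np.random.Generator) -> SurvivalDataset:
    """Null training set: (time, event) pairs shuffled across subjects.

    Pairs move together — permuting times independently of their indicators
    would fabricate censoring patterns that never occurred.  The input
    dataset is untouched.
    """
    perm = rng.permutation(train.n)
    return train.with_outcomes(train.time[perm], train.event[perm])


def _metric_values(scores: RiskScores, test: SurvivalDataset, metrics: tuple[str, ...],
                   t_list: tuple[float, ...], ties: str) -> dict[str, float]:
    """Requested metrics for one scored replicate; NaN marks a failure."""
    out: dict[str, float] = {}
    if "dxy" in metrics:
        try:
            out["dxy"] = somers_dxy(scores, test.time, test.event)
        except ValueError:
            out["dxy"] = float("nan")
    if "cox1_p" in metrics or "r2" in metrics:
        try:
            c1 = cox_model_one(scores, test.time, test.event, ties=ties)
            p = c1.get("p")
            r2 = c1.get("r2")
        except ValueError:
            p = r2 = None
        if "cox1_p" in metrics:
            out["cox1_p"] = float("nan") if p is None else p
        if "r2" in metrics:
            out["r2"] = float("nan") if r2 is None else r2
    if "auc" in metrics:
        for t in t_list:
            try:
                _, auc = roc_auc_at(scores, test.time, test.event, t)
            except ValueError:
                auc = float("nan")
            out[f"auc@{t:g}"] = auc
    return out


def _refit_conditional(model: FittedModel, null_train: SurvivalDataset) -> FittedModel:
    """M1 replicate: same covariate construction, Cox coefficients refit."""
    from .models import _design_for  # same construction path as prediction

    design = _design_for(model, null_train)
    cox = fit_cox(design, null_train.time, null_train.event, ties=model.spec.ties,
                  names=model.covariate_names)
    train_scores = design @ cox.coef
    return FittedModel(
        spec=model.spec, screen=model.screen, pca=model.pca,
        clinical_names=model.clinical_names, gene_covariates=model.gene_covariates,
        covariate_names=model.covariate_names, cox=cox,
        training_scores=RiskScores(ids=list(null_train.ids), values=train_scores,
                                   reference=float(np.median(train_scores))),
        warnings=[] if cox.converged else ["Cox fit did not converge"],
    )


def randomization_test(train: SurvivalDataset, test: SurvivalDataset,
                       cfg: RandTestConfig) -> RandTestResult:
    """Permutation p-values for the requested metrics under the M1 or M2 null.

    Replicates whose model or metric is degenerate are never dropped: the
    failed metric is counted as extreme (conservative) and tallied in
    ``n_failed``.  Replicate randomness comes from independent child streams
    of the master seed, so results do not depend on evaluation order.
    """
    model = build_model(cfg.model_spec, train)
    observed_scores = predict_risk(model, test)
    observed = _metric_values(observed_scores, test, cfg.metrics, cfg.t_list, cfg.model_spec.ties)
    for name, value in observed.items():
        if not np.isfinite(value):
            raise ValueError(f"observed metric {name!r} is unavailable on the real data")

    keys = list(observed)
    null_values = {k: np.empty(cfg.n_perm) for k in keys}
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_perm)
    for r in range(cfg.n_perm):
        rng = np.random.default_rng(seeds[r])
        null_train = permute_training(train, rng)
        if cfg.mode == "M1":
            null_model = _refit_conditional(model, null_train)
        else:
            null_model = build_model(cfg.model_spec, null_train)
        null_scores = predict_risk(null_model, test)
        vals = _metric_values(null_scores, test, cfg.metrics, cfg.t_list, cfg.model_spec.ties)
        for k in keys:
            null_values[k][r] = vals[k]

    results: dict[str, MetricNull] = {}
    for k in keys:
        base = k.split("@")[0]
        nulls = null_values[k]
        failed = ~np.isfinite(nulls)
        if _LOWER_IS_EXTREME[base]:
            extreme = nulls[~failed] <= observed[k]
        else:
            extreme = nulls[~failed] >= observed[k]
        n_extreme = int(extreme.sum()) + int(failed.sum())  # failures counted as extreme
        if cfg.plus_one:
            p = (n_extreme + 1) / (cfg.n_perm + 1)
        else:
            p = n_extreme / cfg.n_perm
        finite = nulls[~failed]
        qs = {q: float(np.quantile(finite, float(q))) if finite.size else float("nan")
              for q in ("0.025", "0.5", "0.975")}
        results[k] = MetricNull(
            observed=observed[k], p=float(p),
            null_mean=float(finite.mean()) if finite.size else float("nan"),
            null_sd=float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
            null_quantiles=qs, n_extreme=n_extreme, n_failed=int(failed.sum()),
            null_values=nulls,
        )
    return RandTestResult(mode=cfg.mode, seed=cfg.seed, n_perm=cfg.n_perm, metrics=results)
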