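"""Power estimation by repeated random training/test splitting.

Each replicate draws one uniform random split of the pooled cohort, rebuilds
every model spec from scratch on the training part (screening, PCA and Cox
fit all re-run — the signature is data-driven, so it must be re-derived on
every split), and evaluates three test-set p-values: the simple hazard ratio
("Cox Model I"), the two-group hazard ratio at the training-score median
("Cox Model II"), and the log-rank test on the same dichotomy.  Power is the
proportion of replicates with p <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import SurvivalDataset
from .metrics import cox_model_one, cox_model_two, logrank_test, two_group_indicator
from .models import ModelSpec, build_model, predict_risk

__all__ = ["PowerConfig", "PowerResult", "estimate_power", "ratio_sweep"]

TESTS = ("cox1", "cox2", "logrank")


@dataclass(frozen=True)
class PowerConfig:
    """Split sizes, replicate count and decision rule for a power run.

    ``n_reps`` defaults to 5,000 (reference resolution); ``failure_policy``
    decides how degenerate replicates (monotone Cox likelihood, one-sided
    dichotomy, no events in the test part) are counted — ``"nonreject"``
    (default, conservative), ``"exclude"`` or ``"error"``.
    """

    model_specs: tuple[ModelSpec, ...]
    n_train: int
    n_test: int
    n_reps: int = 5_000
    alpha: float = 0.05
    tests: tuple[str, ...] = TESTS
    seed: int = 0
    failure_policy: str = "nonreject"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        bad = set(self.tests) - set(TESTS)
        if bad:
            raise ValueError(f"unknown tests {sorted(bad)}")
        if self.failure_policy not in ("nonreject", "exclude", "error"):
            raise ValueError(f"unknown failure_policy {self.failure_policy!r}")


@dataclass
class PowerResult:
    """Rejection proportions per (model, test) over all replicates."""

    n_train: int
    n_test: int
    n_reps: int
    alpha: float
    seed: int
    power: dict[str, dict[str, float]]        # model_id -> test -> power
    n_ok: dict[str, dict[str, int]]
    n_failed: dict[str, dict[str, int]]

    def to_rows(self) -> list[dict]:
        rows = []
        for model_id, by_test in self.power.items():
            row = {"model": model_id, "n_train": self.n_train, "n_test": self.n_test}
            for test, value in by_test.items():
                row[test] = value
                row[f"{test}_failed"] = self.n_failed[model_id][test]
            rows.append(row)
        return rows


def _replicate_pvalues(spec: ModelSpec, train: SurvivalDataset, test: SurvivalDataset,
                       tests: tuple[str, ...]) -> dict[str, float]:
    """Test-set p-values for one split; NaN marks a degenerate replicate."""
    out = {t: float("nan") for t in tests}
    try:
        model = build_model(spec, train)
        test_scores = predict_risk(model, test)
    except (ValueError, KeyError):
        return out
    if "cox1" in tests:
        try:
            c1 = cox_model_one(test_scores, test.time, test.event, ties=spec.ties)
            out["cox1"] = float("nan") if c1.get("p") is None else c1["p"]
        except ValueError:
            pass
    if "cox2" in tests or "logrank" in tests:
        try:
            group = two_group_indicator(model.training_scores, test_scores)
            if "cox2" in tests:
                c2 = cox_model_two(model.training_scores, test_scores, test.time, test.event,
                                   ties=spec.ties)
                out["cox2"] = float("nan") if c2.get("p") is None else c2["p"]
            if "logrank" in tests:
                _, out["logrank"] = logrank_test(test.time, test.event, group)
        except ValueError:
            pass
    return out


def estimate_power(pool: SurvivalDataset, cfg: PowerConfig) -> PowerResult:
    """Monte-Carlo power of each model spec at the configured split sizes."""
    if cfg.n_train + cfg.n_test != pool.n:
        raise ValueError(f"n_train + n_test must equal the pool size {pool.n}")
    if cfg.n_train < 2 or cfg.n_test < 2:
        raise ValueError("both split parts need at least 2 subjects")

    reject = {s.model_id: {t: 0 for t in cfg.tests} for s in cfg.model_specs}
    ok = {s.model_id: {t: 0 for t in cfg.tests} for s in cfg.model_specs}
    failed = {s.model_id: {t: 0 for t in cfg.tests} for s in cfg.model_specs}

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_reps)
    for r in range(cfg.n_reps):
        rng = np.random.default_rng(seeds[r])
        perm = rng.permutation(pool.n)
        train = pool.subset(perm[:cfg.n_train])
        test = pool.subset(perm[cfg.n_train:])
        for spec in cfg.model_specs:
            pvals = _replicate_pvalues(spec, train, test, cfg.tests)
            for t in cfg.tests:
                p = pvals[t]
                if np.isfinite(p):
                    ok[spec.model_id][t] += 1
                    if p <= cfg.alpha:
                        reject[spec.model_id][t] += 1
                else:
                    if cfg.failure_policy == "error":
                        raise RuntimeError(f"degenerate replicate {r} for model {spec.model_id}/{t}")
                    failed[spec.model_id][t] += 1

    power: dict[str, dict[str, float]] = {}
    for spec in cfg.model_specs:
        power[spec.model_id] = {}
        for t in cfg.tests:
            denom = ok[spec.model_id][t] if cfg.failure_policy == "exclude" else cfg.n_reps
            power[spec.model_id][t] = reject[spec.model_id][t] / denom if denom else float("nan")
    return PowerResult(n_train=cfg.n_train, n_test=cfg.n_test, n_reps=cfg.n_reps,
                       alpha=cfg.alpha, seed=cfg.seed, power=power, n_ok=ok, n_failed=failed)


def ratio_sweep(pool: SurvivalDataset, cfg: PowerConfig,
                train_sizes: list[int]) -> list[PowerResult]:
    """Re-run ``estimate_power`` for a list of training-set sizes.

    The test part is always the complement of the training part in the pool.
    A shared master seed spawns one independent stream per size.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(train_sizes))
    results = []
    for size, seed in zip(train_sizes, seeds):
        if not 2 <= size <= pool.n - 2:
            raise ValueError(f"infeasible training size {size} for pool of {pool.n}")
        sub_cfg = PowerConfig(
            model_specs=cfg.model_specs, n_train=size, n_test=pool.n - size,
            n_reps=cfg.n_reps, alpha=cfg.alpha, tests=cfg.tests,
            seed=int(seed.generate_state(1)[0] % (2**31)), failure_policy=cfg.failure_policy,
        )
        results.append(estimate_power(pool, sub_cfg))
    return results
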