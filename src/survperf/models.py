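"""Risk-signature construction: clinical and gene-expression Cox models A–E.

Model A uses clinical covariates only.  The expression models first screen
genes one at a time with a univariate Cox fit and keep those with p below a
pre-set threshold (default 0.001); Model B then uses the first ``k`` principal
components of the screened set as signature variables, Model C the top-ranked
genes themselves.  Models D and E add the clinical covariates of A to the
signatures of B and C respectively.  The final multivariable Cox coefficients
define a per-subject risk score (the linear predictor beta'x), computed for
new subjects with the training-derived gene means and loadings frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .datasets import SurvivalDataset
from .survival import CoxFit, fit_cox

__all__ = [
    "ModelSpec",
    "GeneScreenResult",
    "PCASignature",
    "FittedModel",
    "RiskScores",
    "screen_genes",
    "pca_signature",
    "build_model",
    "predict_risk",
]

MODEL_IDS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one of the five model families.

    A: clinical only; B: PCs of the screened genes; C: top-ranked genes;
    D: clinical + PCs; E: clinical + top genes.
    """

    model_id: str
    screening_alpha: float = 0.001
    n_pcs: int = 5
    n_top_genes: int = 10
    clinical_selection: str = "all"  # or "univariate-p<0.05"
    screening_test: str = "wald"  # or "lr"
    ties: str = "efron"

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}, got {self.model_id!r}")
        if not 0 < self.screening_alpha <= 1:
            raise ValueError("screening_alpha must lie in (0, 1]")
        if self.clinical_selection not in ("all", "univariate-p<0.05"):
            raise ValueError(f"unknown clinical_selection {self.clinical_selection!r}")

    @property
    def uses_clinical(self) -> bool:
        return self.model_id in ("A", "D", "E")

    @property
    def uses_pca(self) -> bool:
        return self.model_id in ("B", "D")

    @property
    def uses_top_genes(self) -> bool:
        return self.model_id in ("C", "E")

    @property
    def uses_genes(self) -> bool:
        return self.uses_pca or self.uses_top_genes


@dataclass
class GeneScreenResult:
    """Univariate Cox screen over all genes, ordered by ascending p-value.

    Ties in p are broken by input gene order so the ranking is reproducible.
    Genes with a constant profile or a failed fit get p = 1 and are never
    selected by the threshold.
    """

    genes: list[str]          # ascending by p, stable
    coefs: np.ndarray
    pvalues: np.ndarray
    alpha: float
    selected: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.selected = [g for g, p in zip(self.genes, self.pvalues) if p < self.alpha]

    def top(self, k: int) -> list[str]:
        return self.genes[:k]


@dataclass
class PCASignature:
    """Frozen PCA of the training expression sub-matrix.

    Centering uses the per-gene training means; no unit-variance scaling.
    Component signs are fixed so the largest-magnitude loading of each
    component is positive.
    """

    genes: list[str]
    means: np.ndarray          # per-gene training means
    loadings: np.ndarray       # genes x k, orthonormal columns
    k: int

    def project(self, expr: np.ndarray) -> np.ndarray:
        """Map an (n, |genes|) expression block to (n, k) component scores."""
        return (expr - self.means) @ self.loadings


@dataclass
class RiskScores:
    """Per-sample Cox linear predictor (unitless log relative hazard)."""

    ids: list[str]
    values: np.ndarray
    reference: float  # training-score median

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class FittedModel:
    """A model spec plus every trained artifact needed to score new subjects."""

    spec: ModelSpec
    screen: GeneScreenResult | None
    pca: PCASignature | None
    clinical_names: list[str]
    gene_covariates: list[str]
    covariate_names: list[str]
    cox: CoxFit
    training_scores: RiskScores
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return self.cox.converged

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "spec": self.spec.__dict__,
            "clinical_names": self.clinical_names,
            "gene_covariates": self.gene_covariates,
            "covariate_names": self.covariate_names,
            "coef": self.cox.coef.tolist(),
            "se": self.cox.se.tolist(),
            "converged": self.cox.converged,
            "ties_method": self.cox.ties_method,
            "warnings": self.warnings,
            "training_scores": {
                "ids": self.training_scores.ids,
                "values": self.training_scores.values.tolist(),
                "reference": self.training_scores.reference,
            },
        }
        if self.pca is not None:
            doc["pca"] = {
                "genes": self.pca.genes,
                "means": self.pca.means.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "k": self.pca.k,
            }
        return json.dumps(doc, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _univariate_p(x: np.ndarray, times: np.ndarray, events: np.ndarray,
                  test: str, ties: str) -> tuple[float, float]:
    """(coef, p) of a single-covariate Cox fit; p = 1 on any failure."""
    if np.all(x == x[0]):
        return 0.0, 1.0
    try:
        fit = fit_cox(x[:, None], times, events, ties=ties)
    except (ValueError, np.linalg.LinAlgError):
        return 0.0, 1.0
    if not fit.converged or not np.isfinite(fit.se[0]) or fit.se[0] <= 0:
        return float(fit.coef[0]), 1.0
    if test == "lr":
        p = float(stats.chi2.sf(fit.lr_statistic, df=1))
    else:
        p = float(fit.wald_p()[0])
    return float(fit.coef[0]), p


def _univariate_cox_batch(X: np.ndarray, times: np.ndarray, events: np.ndarray,
                          ties: str, test: str,
                          max_iter: int = 30, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Single-covariate Cox fits for every column of X at once.

    Vectorized Newton–Raphson across columns; agrees with per-column
    ``fit_cox`` to numerical precision.  Columns that are constant, hit the
    monotone-likelihood bound, or fail to converge get p = 1.
    """
    from .survival import MONOTONE_BETA_BOUND

    order = np.argsort(times, kind="stable")
    x = np.asarray(X, dtype=float)[order]
    ts = np.asarray(times, dtype=float)[order]
    es = np.asarray(events, dtype=int)[order]
    n, g = x.shape
    event_times = np.unique(ts[es == 1])
    first = np.searchsorted(ts, event_times, side="left")
    death_blocks = [np.flatnonzero((ts == t) & (es == 1)) for t in event_times]
    x_death_sum = np.array([x[dk].sum(axis=0) for dk in death_blocks])  # K x g

    def quantities(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        eta = x * beta  # n x g
        eta = eta - eta.max(axis=0, keepdims=True)
        w = np.exp(eta)
        wx = w * x
        wxx = wx * x
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum(wx[::-1], axis=0)[::-1]
        s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        ll = np.zeros(g)
        grad = np.zeros(g)
        info = np.zeros(g)
        for k, dk in enumerate(death_blocks):
            f = first[k]
            m = len(dk)
            ll += eta[dk].sum(axis=0)
            grad += x_death_sum[k]
            r0, r1, r2 = s0[f], s1[f], s2[f]
            if ties == "breslow" or m == 1:
                ll -= m * np.log(r0)
                grad -= m * r1 / r0
                info += m * (r2 / r0 - (r1 / r0) ** 2)
            else:
                d0 = w[dk].sum(axis=0)
                d1 = wx[dk].sum(axis=0)
                d2 = wxx[dk].sum(axis=0)
                for ell in range(m):
                    phi = ell / m
                    q0 = r0 - phi * d0
                    q1 = r1 - phi * d1
                    q2 = r2 - phi * d2
                    ll -= np.log(q0)
                    grad -= q1 / q0
                    info += q2 / q0 - (q1 / q0) ** 2
        return ll, grad, info

    constant = np.all(x == x[0, :], axis=0)
    beta = np.zeros(g)
    ll0, grad, info = quantities(beta)
    ll = ll0.copy()
    active = ~constant
    for _ in range(max_iter):
        step = np.where(active & (info > 0), grad / np.where(info > 0, info, 1.0), 0.0)
        if not np.any(np.abs(step) > 0):
            break
        new_beta = beta + step
        new_ll, new_grad, new_info = quantities(new_beta)
        # per-column step halving on likelihood decrease
        for _ in range(20):
            worse = active & (new_ll < ll - 1e-12)
            if not worse.any():
                break
            step = np.where(worse, step * 0.5, step)
            new_beta = beta + step
            new_ll, new_grad, new_info = quantities(new_beta)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        active = active & (np.abs(grad) >= tol) & (np.abs(beta) <= MONOTONE_BETA_BOUND)
        if not active.any():
            break

    ok = (~constant) & (np.abs(beta) <= MONOTONE_BETA_BOUND) & (np.abs(grad) < 1e-6) & (info > 0)
    se = np.where(info > 0, 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.inf)
    if test == "lr":
        chi2 = 2.0 * (ll - ll0)
        pvals = np.where(ok, stats.chi2.sf(np.clip(chi2, 0, None), df=1), 1.0)
    else:
        z = np.where(ok, beta / se, 0.0)
        pvals = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    beta = np.where(ok, beta, 0.0)
    return beta, pvals


def screen_genes(train: SurvivalDataset, alpha: float, *,
                 test: str = "wald", ties: str = "efron") -> GeneScreenResult:
    """Rank every gene by its univariate Cox p-value; select those below alpha."""
    if train.n_events == 0:
        raise ValueError("gene screening requires at least one event")
    if train.n_genes == 0:
        return GeneScreenResult(genes=[], coefs=np.zeros(0), pvalues=np.ones(0), alpha=alpha)
    coefs, pvals = _univariate_cox_batch(train.expression, train.time, train.event, ties, test)
    order = np.argsort(pvals, kind="stable")  # stable: p-ties keep input gene order
    return GeneScreenResult(
        genes=[train.gene_names[j] for j in order],
        coefs=coefs[order],
        pvalues=pvals[order],
        alpha=alpha,
    )


def pca_signature(train: SurvivalDataset, genes: list[str], k: int) -> PCASignature:
    """Principal components of the training expression sub-matrix.

    ``k`` is capped at the numerical rank of the centered matrix.
    """
    if not genes:
        raise ValueError("empty gene list for PCA signature")
    idx = train.gene_index(genes)
    sub = train.expression[:, idx]
    means = sub.mean(axis=0)
    centered = sub - means
    # SVD of (n x g); right singular vectors are the gene-space loadings
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s[0] * max(centered.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    k_eff = max(1, min(k, rank)) if rank else 1
    loadings = vt[:k_eff].T  # genes x k
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(k_eff):
        pivot = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[pivot, c] < 0:
            loadings[:, c] = -loadings[:, c]
    return PCASignature(genes=list(genes), means=means, loadings=loadings, k=k_eff)


def _select_clinical(train: SurvivalDataset, spec: ModelSpec) -> list[str]:
    if spec.clinical_selection == "all":
        return list(train.clinical_names)
    keep = []
    for j, name in enumerate(train.clinical_names):
        _, p = _univariate_p(train.clinical[:, j], train.time, train.event, spec.screening_test, spec.ties)
        if p < 0.05:
            keep.append(name)
    return keep or list(train.clinical_names)  # never drop to zero covariates


def _signature_genes(screen: GeneScreenResult, needed: int, warnings: list[str],
                     use_all_selected: bool) -> list[str]:
    """Screened genes for a signature, falling back to top-ranked when the
    threshold leaves fewer than ``needed`` (permutation replicates must never
    fail outright)."""
    if use_all_selected:
        genes = screen.selected if screen.selected else screen.top(needed)
        if not screen.selected:
            warnings.append(f"no gene passed alpha={screen.alpha}; using top {len(genes)} ranked genes")
    else:
        if len(screen.selected) >= needed:
            genes = screen.selected[:needed]
        else:
            genes = screen.top(needed)
            warnings.append(
                f"only {len(screen.selected)} genes passed alpha={screen.alpha}; "
                f"using top {needed} ranked genes")
    return genes


def build_model(spec: ModelSpec, train: SurvivalDataset) -> FittedModel:
    """Assemble the spec's covariates from the training data and fit one
    multivariable Cox model."""
    warnings: list[str] = []
    screen: GeneScreenResult | None = None
    pca: PCASignature | None = None

    blocks: list[np.ndarray] = []
    covariate_names: list[str] = []
    clinical_names: list[str] = []
    gene_covariates: list[str] = []

    if spec.uses_clinical:
        clinical_names = _select_clinical(train, spec)
        if clinical_names:
            cidx = [train.clinical_names.index(c) for c in clinical_names]
            blocks.append(train.clinical[:, cidx])
            covariate_names.extend(clinical_names)

    if spec.uses_genes:
        screen = screen_genes(train, spec.screening_alpha, test=spec.screening_test, ties=spec.ties)
        if spec.uses_pca:
            genes = _signature_genes(screen, spec.n_pcs, warnings, use_all_selected=True)
            pca = pca_signature(train, genes, spec.n_pcs)
            if pca.k < spec.n_pcs:
                warnings.append(f"PCA capped at k={pca.k} (requested {spec.n_pcs})")
            blocks.append(pca.project(train.expression[:, train.gene_index(pca.genes)]))
            covariate_names.extend(f"PC{c + 1}" for c in range(pca.k))
        else:
            gene_covariates = _signature_genes(screen, spec.n_top_genes, warnings, use_all_selected=False)
            blocks.append(train.expression[:, train.gene_index(gene_covariates)])
            covariate_names.extend(gene_covariates)

    if not blocks or sum(b.shape[1] for b in blocks) == 0:
        raise ValueError(f"model {spec.model_id}: zero usable covariates")
    design = np.column_stack(blocks)
    cox = fit_cox(design, train.time, train.event, ties=spec.ties, names=covariate_names)
    if not cox.converged:
        warnings.append("Cox fit did not converge" + (" (monotone likelihood)" if cox.monotone else ""))
    train_scores = design @ cox.coef
    model = FittedModel(
        spec=spec, screen=screen, pca=pca,
        clinical_names=clinical_names, gene_covariates=gene_covariates,
        covariate_names=covariate_names, cox=cox,
        training_scores=RiskScores(ids=list(train.ids), values=train_scores,
                                   reference=float(np.median(train_scores))),
        warnings=warnings,
    )
    return model


def _design_for(model: FittedModel, data: SurvivalDataset) -> np.ndarray:
    blocks: list[np.ndarray] = []
    if model.clinical_names:
        missing = [c for c in model.clinical_names if c not in data.clinical_names]
        if missing:
            raise KeyError(f"missing clinical covariate(s): {missing}")
        cidx = [data.clinical_names.index(c) for c in model.clinical_names]
        blocks.append(data.clinical[:, cidx])
    if model.pca is not None:
        blocks.append(model.pca.project(data.expression[:, data.gene_index(model.pca.genes)]))
    if model.gene_covariates:
        blocks.append(data.expression[:, data.gene_index(model.gene_covariates)])
    return np.column_stack(blocks)


def predict_risk(model: FittedModel, data: SurvivalDataset) -> RiskScores:
    """Risk score beta'x for each subject, using the frozen training artifacts."""
    design = _design_for(model, data)
    return RiskScores(ids=list(data.ids), values=design @ model.cox.coef,
                      reference=model.training_scores.reference)
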