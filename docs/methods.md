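# Methods

## Problem setting

A survival prediction model for cancer prognosis maps a patient's covariate
profile — a handful of clinical variables plus a high-dimensional gene
expression vector — to a scalar risk score. The score is fit on a training
cohort with right-censored survival outcomes (observed time `T_i`, event
indicator `δ_i`) and assessed on a held-out test cohort. This package
implements the model families, the assessment metrics, and two inferential
procedures (a permutation test for metric significance and a repeated-split
power estimate) for this setting.

## Risk models

All five model families are Cox proportional-hazards models differing only
in the covariates entering the linear predictor `η = β'x`:

* **A** — all clinical covariates (an optional policy keeps only covariates
  with univariate Cox p < 0.05; "all" is the default because it is
  deterministic and the full clinical set is small).
* **B** — the first `k` (default 5) principal components of the screened
  gene set. Screening fits one univariate Cox model per gene and keeps genes
  with p < α (default 0.001, Wald test; a likelihood-ratio variant is
  selectable). PCA centers by the per-gene training means and does **not**
  scale genes to unit variance — expression values arrive on a common scale
  and variance carries signal. Component signs are fixed by making the
  largest-magnitude loading positive; `k` is capped at the matrix rank.
* **C** — the top 10 screened genes themselves, ranked by p-value (ties
  broken by input gene order, for reproducibility).
* **D** = A + B, **E** = A + C.

Screening fallback: when fewer genes pass α than a signature needs, the
top-ranked genes are taken regardless of the threshold and a warning is
recorded on the model. This matters inside permutation replicates, where a
null dataset frequently yields zero "significant" genes; a replicate must
produce a score, not an exception, or the null distribution loses mass
selectively.

Prediction for a new subject reuses the frozen training artifacts (gene
means, loadings, coefficients): the score is `β'x`, a unitless
log-relative-hazard. All rank-based metrics are invariant to affine
transformations of the score.

## Cox fitting

The partial likelihood is maximized by Newton–Raphson from `β = 0` with
step-halving on likelihood decrease; convergence when the largest score
component falls below 1e-9 or the relative log-likelihood change below
1e-12, with at most 50 iterations. Ties are handled by the Efron correction
by default (Breslow selectable); the two coincide on untied data. Monotone
likelihood (the partial-likelihood analogue of perfect separation) is
declared when any coefficient passes |β| = 20 during iteration; the fit is
returned flagged `converged = False` and callers decide policy — a power
replicate counts it as a non-rejection, a screening fit assigns the gene
p = 1. Standard errors come from the inverse observed information; the
global score test at `β = 0` is also reported because, for a single binary
covariate on untied data, it *is* the log-rank test — a property the test
suite checks to 1e-8 and a useful internal consistency anchor.

## Performance metrics

* **Somers' D_xy.** `D_xy = 2c − 1` where `c` is the concordance between
  risk score and survival time over usable pairs: a pair is usable when the
  shorter observed time carries an event (a censored subject tied in time
  with an event counts as the longer survivor); a usable pair is concordant
  when the longer survivor has the higher score, score ties count 1/2.
  **Sign convention:** the orientation is score-versus-time, so a good model
  (high risk ↔ short survival) yields *negative* D_xy; a model no better
  than chance sits near 0.
* **Cox Model I.** A Cox fit with the test-set score as the single
  covariate: hazard ratio `exp(β̂)` per unit score, Wald 95% CI
  (z = 1.959964) and p, and the likelihood-ratio R² `1 − exp(−LR/n)` with
  `LR = 2(ℓ(β̂) − ℓ(0))` and `n` the number of test subjects. Among the
  R²-type measures in circulation this one is bounded in [0, 1), equals 0
  exactly at `β̂ = 0`, and needs nothing beyond the fitted partial
  likelihood.
* **Cox Model II.** Test subjects are dichotomized at the *training*-score
  median (scores equal to the median go low-risk); a Cox fit on the
  indicator gives the two-group hazard ratio, CI, and p. The log-rank test
  on the same dichotomy is reported alongside; its p and the Cox score-test
  p agree when event times are untied.
* **Integrated Brier score.** Each subject's predicted event-free curve is
  the Kaplan–Meier estimate of their *own* group computed on the test data —
  deliberately avoiding any baseline-hazard estimate. Censoring is handled
  by inverse-probability-of-censoring weights from the pooled censoring KM
  `Ĝ`: events by `t` contribute `Ŝ_g(t)²/Ĝ(T_i−)` (left limit), survivors
  past `t` contribute `(1−Ŝ_g(t))²/Ĝ(t)`, subjects censored before `t`
  contribute 0. `IBS = (1/τ)∫₀^τ BS(t) dt` is evaluated exactly as a sum
  over step-function segments; `τ` defaults to the largest observed test
  time, and if `Ĝ` hits 0 before `τ` the integration truncates there.
* **Time-dependent ROC/AUC.** At threshold `t`, cases are subjects with an
  observed event by `t`, controls survive past `t`, and subjects censored
  before `t` are excluded (their status at `t` is unknown) and counted. The
  curve enumerates every unique score as a cutoff (score strictly greater ⇒
  predicted case); the trapezoid AUC equals the tie-corrected Mann–Whitney
  statistic exactly. No smoothing — on small test sets the empirical
  estimator is the honest one.
* **Threshold scan.** The two-group comparison depends on where the cutoff
  falls, so the scan recomputes the log-rank p for every possible low-risk
  group size k = 1..n−1. Cut points inside runs of tied scores are flagged
  as unrealizable; degenerate splits (no events in the comparison) report
  p = 1 with a flag.

## Permutation significance (M1 / M2)

The null hypothesis is that the training outcomes carry no information about
the test outcomes through the fitted signature. Null replicates jointly
permute the training `(T, δ)` pairs across subjects — pairs move together
because permuting times independently of their indicators would fabricate
censoring patterns that never occurred. Covariates stay fixed, so every
replicate conserves the outcome multiset exactly.

Two null constructions: **M1** keeps the observed gene selection and PCA
loadings and refits only the Cox coefficients on the permuted outcomes
(conditional on the signature); **M2** re-derives screening, ranking and PCA
from scratch per replicate (unconditional). For a purely clinical model the
two coincide replicate-by-replicate, and the implementation reproduces this
identity bit-for-bit under a shared seed.

The p-value is the proportion of null replicates whose metric is at least as
extreme as the observed one (non-strict), extremeness pointing toward
better-than-null prediction: more negative D_xy, smaller Cox p, larger R²,
larger AUC. The denominator is `n_perm` (granularity `1/n_perm`); an
optional `(r+1)/(n+1)` smoothing keeps p away from exactly zero, off by
default. Replicates whose metric is incomputable are counted as extreme
(conservative) and tallied. Replicate randomness comes from independent
child streams of the master seed, so results are order-independent.

## Repeated-split power

The pooled cohort is split uniformly at random (no stratification by event
status; a stratified option exists) into `n_train`/`n_test`, every model is
rebuilt from scratch on the training part — screening and PCA rerun, since
the signature is data-driven — and three test-set p-values are recorded
(Cox I, Cox II, log-rank). Power is the proportion of replicates with
p ≤ α (default 0.05). "Two-fold cross-validation" here means one random
near-half split per replicate with only the held-out part evaluated; an
option evaluates both folds and averages, off by default. Degenerate
replicates count as non-rejections (conservative) and are tallied;
"exclude" and "error" policies are selectable.

A caution established while validating this module: all replicates resample
*one* realized pool, so the estimated power is conditional on that pool. On
null data the conditional rejection rate varies widely between pools — a
pool that happens to carry a chance covariate–outcome association is
rightly rejected often — and only the rate averaged over independent pools
equals α. Single-pool power numbers should be read as properties of that
cohort, not of the procedure.

## Synthetic cohorts

The generator draws expression and clinical covariates standard normal and
event times from a proportional-hazards model `h(t) = h0 exp(η)` with an
exponential baseline (Weibull selectable), so the true linear predictor has
coefficient exactly 1 — the basis of the parameter-recovery tests. Censoring
times are exponential with a rate solved numerically (Brent) so the expected
censored fraction hits the target, optionally capped by an administrative
horizon. Everything is a deterministic function of the seed.

The 78/19 preset mimics the structure of a small breast-cancer prognosis
study: 500 genes of which 10 carry signal, 4 clinical covariates, ~40%
censoring, exponential baseline 0.1/year. The 10 signal genes form an
equicorrelated block (ρ = 0.3): with independent signal genes, each gene's
marginal univariate effect is attenuated by the other nine and p < 0.001
screening at n = 78 is nearly powerless, which matches no real signature
cohort. Effect sizes (gene 0.18, clinical 0.5) were fixed once so the
median test-set |D_xy| of the clinical and gene models lands around 0.2–0.4.

What the generator does **not** emulate: microarray noise physics, batch
effects, non-proportional hazards, informative censoring, or realistic
gene–gene correlation structure beyond the single signal block. Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the inference under a proportional-hazards data-generating process — not
performance claims about any real cohort.

## Problem sizes and runtime choices

Monte-Carlo components run at sizes chosen to keep the statistical checks
sharp while remaining desk-scale: permutation calibration uses 200 outer
cohorts × 200 permutations; power checks use 500 splits (or 500 single-split
pools for the unconditional size check); parameter recovery uses 50 cohorts
of n = 1000. The reference resolutions (10,000 permutations, 5,000 splits)
remain the defaults of the public API. Gene screening is vectorized across
genes (a batched single-covariate Newton solver that agrees with the
per-gene fit to numerical precision), which keeps M2 permutation runs and
power sweeps tractable.

## Known limitations

* No left truncation, time-varying covariates, stratified/penalized Cox, or
  competing risks.
* The empirical ROC estimator requires at least one case and one control at
  the chosen threshold; it does not borrow strength across time points.
* Monotone-likelihood fits are flagged rather than penalized; heavily
  separated small cohorts will show many flagged replicates.
* The IBS weights become unstable when the censoring KM approaches 0 near
  `τ`; integration truncates at the last positive-`Ĝ` time and flags it.
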