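# survperf

Assessment of survival prediction models for cancer prognosis.

Prognostic studies fit a risk model — clinical covariates, a gene-expression
signature, or both — on a training cohort with right-censored survival
outcomes, then ask how well the predicted risk scores order the survival
times of a held-out test cohort. Different performance metrics can and do
disagree, most of them come without a significance test, and dichotomizing
patients into high/low risk groups makes the answer depend on an arbitrary
cutoff. `survperf` is a toolkit for doing this assessment carefully:

* **Models.** Five Cox proportional-hazards model families built from a
  training cohort: clinical covariates only (A); the first five principal
  components of the genes passing univariate Cox screening at p < 0.001 (B);
  the top 10 screened genes (C); and the clinical + gene combinations
  (D = A + B, E = A + C). The fitted coefficients define each patient's risk
  score `β'x`.
* **Metrics.** Somers' rank correlation `D_xy = 2c − 1` (censoring-adjusted
  concordance, oriented so a good model is negative); the simple hazard
  ratio `exp(β̂)` with 95% CI, Wald p and `R² = 1 − exp(−LR/n)` from a Cox
  fit on the score ("Cox Model I"); the two-group hazard ratio after
  dichotomizing at the training-score median ("Cox Model II") with the
  log-rank test and a baseline-free integrated Brier score
  `(1/τ)∫₀^τ BS(t) dt` using inverse-probability-of-censoring weights;
  time-dependent ROC curves and AUC(t); and a log-rank scan over *all*
  possible cutoffs.
* **Inference.** A permutation test assigning p-values to D_xy, the Cox
  p-value, R² and AUC(t) by permuting training outcomes — conditional on
  the observed signature (M1) or re-deriving the signature per replicate
  (M2) — and a repeated random-split procedure estimating each model's
  power to detect association at chosen training:test ratios.
* **Synthetic cohorts.** A generator with known ground truth (proportional
  hazards, calibrated censoring, an optional correlated signal-gene block)
  so the entire pipeline is testable end to end without external data,
  including a 78/19-patient preset shaped like the classic breast-cancer
  signature studies.

## Worked example

Generate the preset cohort, then build and evaluate all five models:

```sh
survperf simulate --seed 1 --preset --out demo
survperf evaluate \
    --train-clinical demo/train_clinical.tsv --train-expression demo/train_expression.tsv \
    --test-clinical  demo/test_clinical.tsv  --test-expression  demo/test_expression.tsv \
    --t-list 5 --out demo/metrics.tsv
```

`demo/metrics.tsv` (abridged):

```
model       dxy       r2    hr_1      p_1    hr_2      p_2      ibs  logrank_p    auc_5
    A -0.473684 0.227422 3.58648 0.027176 2.85045 0.127310 0.141563   0.112210 0.763889
    B -0.308271 0.076641 1.63708 0.230870 3.97622 0.045798 0.119597   0.032303 0.763889
    C -0.203008 0.046763 1.23122 0.338095 1.24926 0.690425 0.138471   0.689835 0.708333
    D -0.609023 0.368898 2.15127 0.004207 5.72871 0.014954 0.126056   0.006390 0.847222
    E -0.578947 0.363840 1.89957 0.007826 8.90082 0.007062 0.116937   0.001329 0.902778
```

Reading the first row: the clinical model's scores rank-correlate with test
survival at D_xy = −0.47 (negative = higher risk, shorter survival); one
unit of score multiplies the hazard by 3.59 (Wald p = 0.027, R² = 0.23);
splitting the 19 test patients at the training-score median gives a
two-group hazard ratio of 2.85 whose Wald p (0.13) and log-rank p (0.11)
are *not* significant — the single-score and two-group analyses disagree,
which is precisely the kind of discordance the toolkit is built to expose.
The two-group prediction's integrated Brier score is 0.14, and the score
separates 5-year events from survivors with AUC 0.76.

Permutation significance of the clinical model's metrics (M1 null,
conditional on the signature):

```sh
survperf randtest \
    --train-clinical demo/train_clinical.tsv --train-expression demo/train_expression.tsv \
    --test-clinical  demo/test_clinical.tsv  --test-expression  demo/test_expression.tsv \
    --model A --mode M1 --n-perm 1000 --seed 2 --out demo/randtest_A.json
# dxy: observed=-0.4737 p=0.0290 (failed replicates: 0)
# cox1_p: observed=0.0272 p=0.1010 (failed replicates: 0)
# r2: observed=0.2274 p=0.1150 (failed replicates: 0)
```

So a D_xy of −0.47 on 19 test patients occurs in about 2.9% of
no-association permutations. The same library calls are available in
Python (`build_model`, `evaluate_all`, `randomization_test`,
`estimate_power`, `ratio_sweep`) for scripted analyses.

Everything else: `survperf --help`, `survperf power --help`, etc.

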