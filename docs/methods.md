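# Methods

## The model

The response Y is 1 for an O-GlcNAc glycosylated S/T site and 0 for an
N-glycosylated control site re-centered on the S/T of its `N-X-S/T`
sequon (position +2 from the N; single-sugar N-glyc sites are excluded as
plausible crystallization artifacts). The linear probability model (LPM)
treats E(Y|x) = x'β directly as the glycosylation probability. Its
attractions here are interpretability (most predictors are 0/1
indicators, so coefficients are probability increments) and the fact that
the error variance is known exactly: Var(u) = E(Y)(1−E(Y)).

The estimation chain follows that structure:

1. **OLS** on the indicator design (±8 residue window, `m{i}{A}` /
   `p{i}{A}` columns; `m2*` excluded because the control class has an
   invariant N at −2, so any other residue there would tautologically
   flag the positive class), plus `pos` (site position ÷ protein length)
   and, when available, `ASA`, `ASA_zero`, turn/secondary-structure
   dummies, `phi` and `psi`. Window cells beyond a protein terminus are
   gap-padded and encode as all-zero indicators.
2. **Minimal-k ridge.** OLS fitted values can leave [0, 1], which makes
   the binomial variances negative. The chain finds the smallest ridge
   penalty k for which every fitted value lies in [0, 1] (geometric
   bracketing, then bisection to 1e-5). Ridge is computed in correlation
   form — predictors centered and scaled to unit length, penalty applied
   on that scale, intercept unpenalized — because k is convention-
   dependent and this is the convention of the major statistical packages'
   ridge traces. Feasibility is treated as monotone in k; this is checked
   empirically over the bisection bracket rather than assumed globally.
3. **WLS** with weights 1/clamp(p̂(1−p̂), 1e-6, 0.25) from the ridge
   probabilities. The clamp floor (1e-6) guards the boundary predictions
   that the minimal k produces by construction; the cap at 0.25 is the
   binomial maximum.
4. **Selection.** Stepwise forward-backward search scored by K-fold
   cross-validated PRESS (folds stratified by class, seeded), then a
   pruning loop: re-run the ridge+WLS stages and drop the single worst
   predictor until every remaining p-value is below α = 5%. The pruning
   loop re-estimates the minimal k at every iteration, as the published
   procedure describes ("the entire estimation process is redone"); a
   config switch re-runs the stepwise search instead, but the default is
   drop-worst because the full re-search is seed-dependent and orders of
   magnitude slower. Exact replication of the originally selected
   variable sets is explicitly out of scope — printed coefficient tables
   are bundled as fixtures instead and can be applied verbatim
   ("fixture mode").

Classification uses the raw linear index with a 50% cutoff; a probability
of exactly 0.5 classifies positive, since the misprediction definition is
"predicted probability *less than* 50% for a true positive".

## Diagnostics

* **KS statistic** (classifier sense): max over observed scores of
  |F̂₁ − F̂₀| between class-conditional CDFs of predicted probabilities;
  the reported location is the smallest maximizing threshold
  (deterministic tie-break). Cross-checked in tests against the generic
  two-sample KS distance.
* **Brier score**: mean squared (Y − p̂).
* **Durbin–Watson** on residuals in source-row order. Row order of the
  input file is part of the data contract; DW is meaningless otherwise.
* **Cook's distance** with the weighted hat matrix when the fit is WLS;
  D > 0.5 flagged.
* **VIF** via auxiliary regressions; exact collinearity reported as ∞.
* **Ridge ANOVA.** Ridge shrinkage breaks the orthogonality of fitted
  values and residuals, so SST splits into regression, residual, and a
  *nonorthogonal* component equal to the cross term 2·e'(ŷ−ȳ). Effective
  degrees of freedom come from the ridge hat matrix H: df_reg = tr(H)−1,
  df_res = n − tr(2H − H²), df_non = tr(H) − tr(H²). These sum to n−1
  identically, collapse to the classical table at k = 0 (where the cross
  term vanishes and the fit-residual angle is 90°), and df_res is the
  standard residual effective df of penalized regression. The exact
  construction behind the published fractional-df table is not
  recoverable from its source, so the sum identities are the binding
  contract here; the F-ratio is labeled approximate and never used for
  testing.

## The comparison models

The lasso-penalized logit minimizes −loglik + λ‖b‖₁ (intercept
unpenalized) by accelerated proximal gradient (FISTA: soft-threshold
proximal step, momentum with restart on objective increase, backtracking
line search; relative objective tolerance 1e-8, 10,000 iterations per λ,
warm starts). The path uses λᵢ = ρⁱ for up to 200 steps and selects the
step minimizing SBC = −2·loglik + (nnz+1)·ln n, with the lasso df
estimated by the nonzero count — the standard estimate. Firth's
penalized likelihood (modified score U* = X'(y − p + h(½ − p)), h the
leverages of the weighted design) provides finite logistic estimates
under the quasi-complete separation that this data induces; p-values are
Wald on the penalized information (profile intervals out of scope).
Out-of-sample comparison uses the 5-fold CV Brier signal-to-noise ratio
μ/σ with the Rose criterion (SNR > 5).

## Sequon analysis

Patterns are '-'-delimited tokens: optional `~`, then `X` (wildcard) or a
`/`-separated residue set; the center token is the unique S/T-class token
or an explicit `*` marker; `~( ... )` negates the whole pattern (so
De Morgan expansions are testable as set identities). A terminal gap
satisfies negated tokens and fails positive ones — a nonexistent residue
cannot *be* tryptophan; the source material is silent on this edge.
Occurrence CIs use the Wilson score interval; the method was fixed by
verifying it reproduces both published intervals exactly at printed
rounding (Clopper–Pearson is available as a config alternative).
Cross-PTM overlap counts shift N-glycosylation positions by +2 so S/T
sites align across modification types.

## Nonparametric layer

Per-residue positional profiles of two PTM classes are compared with the
Wilcoxon signed-rank test across shared offsets (two-sided, Pratt
handling of zero differences, mid-ranked ties — the 14–16 paired
percentages contain near-ties, so tie policy matters and agreement with
the published 1/0 flags is checked at an ≥18/20 tolerance rather than
exactly). ASA class comparisons use the rank-sum test (normal
approximation, tie correction, direction reported) and the two-sample KS
test. No multiple-testing correction is applied across the 20 residues,
matching the original analysis.

## Synthetic data

The generator emulates the estimation data's statistical structure:

* **Windows**: positions sampled independently from per-class positional
  marginals; defaults are the bundled published O-GlcNAc marginals for
  the positive class. The control-class marginals are not published, so
  the default negative background is the pooled positional mean of the
  positive table, with the sequon constraints imposed on top (N at −2,
  no P at −1 for negatives; no `W-S/T-W` for positives; both
  configurable off). Center S:T ratio defaults to the published 59.12% S.
  Independence across positions is a deliberate simplification — only
  marginals are published — and a user-supplied joint sampler can replace
  it.
* **Structure**: ASA is a point mass at 0 (probability 0.002 for the
  positive class, mirroring the 2-in-~2000 burial rate; 0 for controls)
  plus a lognormal body, with the control class location higher so its
  ASA is stochastically larger, as observed. φ/ψ come from 2–3
  Ramachandran-like bivariate modes; secondary-structure and turn-type
  categories are class-conditional draws, independent of ASA and the
  window (the joint distribution is not published).
* **Response**: by default the class label. With a supplied effect
  vector, Y ~ Bernoulli(clamp(x'β, 0, 1)) on the encoded design — a
  literal LPM data-generating process, so recovery tests run under
  correct specification. Recovery tests use effect vectors whose index
  stays inside [0, 1]; when the index saturates the clamp, the linear fit
  estimates a flattened function and attenuates, which is a property of
  the DGP, not an estimator defect.
* One global seed drives all streams; identical configs are
  bit-reproducible.

What passing synthetic tests does **not** show: real windows have
positional couplings, real structure correlates with sequence, and the
real class separation is far stronger than the marginals-only synthetic
signal (the synthetic in-sample KS sits near 50–60%, nowhere near the
~99% reported on the real structural data). The synthetic study validates
the machinery — estimability, invariants, calibration of the selection
and pruning steps — not the biological effect sizes.

## Problem sizes and numerical choices

The default synthetic study runs at half the original sample sizes
(≈494 + 542 structural records; `--scale` adjusts), which the pruning
chain handles in under a minute; tests use smaller slices. Rank-deficient
designs are an error naming the dependent columns; complete indicator
blocks (which are collinear with the intercept when no gaps occur) are
reduced by pivoted QR on the centered predictors, so the intercept is
always retained. Indicators with fewer than `min_indicator_count`
(default 10) occurrences are dropped before refitting. The bisection
tolerance for the minimal k is 1e-5; ridge ANOVA closure identities hold
to ~1e-9 in practice.

## Known limitations

* The original estimation spreadsheet is not redistributable here, so the
  published-data anchors (KS 99.2%, Brier 0.0094, k = 3.77895, ANOVA MSE
  0.0827, subset counts) are expressed as tests that require
  `data/glycos_public.xlsx` and fail explicitly without it.
* The fractional-df ANOVA convention is pinned by its sum identities, not
  by the published table's exact df split (see above).
* `pos` for re-centered N-glyc records uses the shifted (+2) position
  (the re-centering helper updates the stored site position); calling the
  helper with offset 0 leaves a record untouched.
* Whether the published Table-5 signed-rank tests were one- or two-sided
  is not stated; two-sided is used.
* The phosphorylation site table is represented only by its published
  positional marginals; phospho-dependent analyses run on those and on
  synthetic draws.
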