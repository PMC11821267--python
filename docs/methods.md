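# Methods

## Scope and model

`cramed` infers which microbial taxa mediate the effect of a binary
treatment `T` on a continuous outcome `Y`, given an `n × m` count matrix
`M` and optional confounders `X`.  Counts for each taxon are modelled as a
zero-inflated negative binomial (ZINB): a structural zero with probability
`pi_ij` (logistic in `T` and `X`) mixed with an NB draw whose log-mean is
linear in `T` and `X` plus a per-sample offset `o_i` (log sequencing
depth) and whose dispersion `phi_j` satisfies
`Var = lambda + lambda^2/phi`.  The outcome model is Gaussian and linear in
`(T, X, M)`.

Identification of natural direct/indirect effects requires the standard
sequential-ignorability assumptions (no unmeasured confounding of the
treatment–outcome, mediator–outcome and treatment–mediator relationships,
and no treatment-induced mediator–outcome confounding), plus causally
unrelated mediators.  None of these are testable from the data; the
confounded benchmark generator exists precisely to measure behavior when
the first one fails.

## Effect decomposition

Introducing the latent presence indicator `Z_j` (the structural-zero
state) splits the path `T → M_j → Y` into `T → Z_j → M_j → Y`.  At
covariate profile `x`, with `a_t = exp(alpha0 + alpha1 t + alpha_x'x)` and
`g_t = 1 + exp(gamma0 + gamma1 t + gamma_x'x)`:

- `NIE_j  = beta_mj (a_1/g_1 − a_0/g_0)`
- `NIEP_j = beta_mj (a_1/g_1 − a_1/g_0)` — mediated by presence–absence,
- `NIEA_j = beta_mj (a_1/g_0 − a_0/g_0)` — mediated by abundance when present,

with `NIE_j = NIEP_j + NIEA_j` as an algebraic identity (tested to 1e-10).
All ratios are evaluated in log space (`exp(la − log1pexp(lg))`) so large
linear predictors cannot overflow.  The natural direct effect is `beta1`.
Effects are reported at the reference profile `x = 0` and at offset 0
(depth `S = 1`); a taxon with no zeros has a non-identifiable zero model
and its effect is attributed entirely to the abundance path.

Implementation choices where the procedure was genuinely open:

- **Post-selection coefficients.** `beta_mj` for reporting comes from an
  unpenalized least-squares fit of `Y` on `(T, X, M_selected)` — standard
  de-biasing after LASSO selection.
- **Confidence intervals.** Intervals for `(NIE, NIEP, NIEA)` are
  nonparametric-bootstrap percentile intervals (resample rows with
  replacement, re-fit, default 1000 repetitions).  A label-permutation
  scheme was considered and rejected: permuting treatment yields a null
  distribution for testing, not a sampling distribution for a point
  estimate.  CIs are opt-in in the pipeline configuration because each
  taxon costs `n_rep` ZINB re-fits.

## Hypothesis testing

The per-taxon null is composite: `H0j: beta_mj = 0 or alpha1j = gamma1j = 0`.

**Mediator → outcome (zidCRT).** The distilled conditional randomization
test adapted to counts: fit the ZINB of `M_j` on `(T, X)`; fit a
cross-validated LASSO of `Y` on `(T, X, M_−j)` giving fitted values
`Yhat_j`; draw `B` synthetic count vectors from the fitted ZINB law,
re-fit each, and rank the observed statistic

```
|(Y − Yhat_j)' (M_j − Mhat_j)| / ||M_j − Mhat_j||_2
```

(`Mhat_j` = fitted conditional mean `(1 − pi) * lambda`, the canonical
"fitted value" of a mixture model) among the resampled ones:
`p1 = (1 + #{stat_b ≥ stat_obs}) / (B + 1)`, ties counted as exceedances,
floor `1/(B+1)`.  Default `B = 100`.  Each resample is re-fit by the same
ZINB regression (warm-started at the original estimates) because
exchangeability of the statistic requires the resamples to pass through
the same fitting map; a fast mode that reuses the original fitted means
exists but is off by default.  Resample re-fit failures fall back to the
original fitted means and are counted; above 20% the taxon is flagged.

**Treatment → mediator (Wald).** `W² = theta' cov(theta)^{-1} theta` with
`theta = (alpha1, gamma1)` against chi-square with 2 df.  The covariance is
the corresponding block of the inverse observed information, obtained by
central finite differences of the analytic score at the optimum (the
choice among observed/expected/sandwich information was open; observed
information is the default for ML fits and matched Monte-Carlo standard
errors well).  For a taxon with no zeros the test degrades to 1 df on
`alpha1` alone.

**Combination and multiplicity.** `pmax = max(p1, p2)`; Benjamini–Hochberg
across the screened set `D` only, since the per-taxon tests are run
conditional on `D` and p-values outside it are never computed.  Selected =
adjusted `pmax` below the FDR level (default 5%).

## Screening and distillation

A LASSO of `Y` on `(T, X, M)` with the `(1, T, X)` block unpenalized
defines `D` = taxa with nonzero coefficients.  Keeping treatment and
confounders unpenalized is implemented by profiling them out
(Frisch–Waugh): both `Y` and the standardized mediator columns are
residualized against `(1, T, X)` before the penalized fit, which is
exactly equivalent to leaving that block unpenalized.

Cross-validation (10-fold) is run once per dataset over a 50-point penalty
path; two penalties are extracted:

- **screening** uses the one-standard-error penalty (the sparsest model
  within one SE of the CV minimum).  The randomization p-value cannot go
  below `1/(B+1)`, so BH across `D` can only ever reject when
  `|D| ≲ (B+1) · fdr · (number of true signals)`; a prediction-optimal
  screen admits enough noise taxa to make rejection arithmetically
  impossible at `B = 100`.  The one-SE rule is the standard sparser choice
  and keeps the candidate set compatible with the discreteness of the
  randomization p-value.
- **distillation** (the leave-one-taxon-out fits producing `Yhat_j`) uses
  the CV-minimum penalty, since there the only goal is predictive accuracy
  of `Yhat_j`.

## ZINB fitting

Per taxon: initialize `gamma` by a ridge-stabilized logistic IRLS on the
zero indicator, `alpha` by Poisson IRLS on the positive counts, `phi` by
method of moments; refine by a short EM over the latent presence indicator
(weighted logistic + weighted Poisson-like M-steps, 4 iterations); polish
by L-BFGS-B on the observed-data log-likelihood with an analytic score,
`phi` parameterized on the log scale (bounds `log phi ∈ [−7, 13]`,
coefficients `|·| ≤ 40`, linear predictors clipped at ±30).  Convergence:
scipy defaults with `ftol = 1e-11`; on failure one perturbed restart, then
a plain-NB fallback, then the taxon is flagged untestable.  Degenerate
taxa: all-zero → excluded with a logged reason; no zeros → plain NB fit
with `pi ≡ 0`, `gamma = NaN` and a 1-df Wald test.

Sampling from a fit uses the gamma–Poisson representation of the NB, with
structural zeros overlaid.

## Synthetic benchmark generators

The generators reproduce the simulation design the benchmark figures are
based on; their defaults are the study conditions, not tuning knobs.

Common scheme over `m ≥ 26` taxa: `gamma0 ~ U(−2, 2)`,
`phi ~ U(0.1, 10)`, `alpha0 = −7`, `beta0 = 1`, `beta1 = −2`,
`sigma² = 1`; treatment `Bernoulli(0.5)`; log depth
`log S ~ U(7.1, 10.5)` entering the count mean as an offset.  Class
structure of `(gamma1, alpha1, beta_m)`: taxa 1–3 draw all three from
`N(−2,1)/N(−2,1)/N(2,1)`; taxon 4 has `gamma1 = 0`; taxon 5 has
`alpha1 = 0`; taxa 6–10 have only `beta_m ≠ 0`; taxa 11–25 have only
treatment paths in three patterns; taxa 26–m are pure noise.  A taxon is
labelled causal iff `beta_m ≠ 0` and at least one treatment path is
nonzero — exactly taxa 1–5.  The resulting count matrix is ~50–60% zeros
at `(n, m) = (100, 100)`.

Variants: **hurdle** counts (zero w.p. `pi`, else zero-truncated NB or
Poisson via inverse-CDF on the positive tail) probe robustness to
mixture-model misspecification; the **confounded** generator draws `d = 3`
standard-normal unmeasured confounders that drive both the treatment
(`logit = Delta_u'X_u`) and the outcome (additive `beta_u'X_u`), with
`Delta_u, beta_u ~ N(0.2h, 0.5)` and strength `h ∈ {1, 3, 9}`, and
amplifies the scheme's path/outcome coefficient means to −5/+5.

What the generators do **not** emulate: compositionality (counts are
independent across taxa given the parameters, no fixed total),
taxon–taxon correlation, phylogenetic structure, and covariate-dependent
dispersion.  Passing benchmarks therefore demonstrates correctness of the
machinery under the generating model and robustness to the two stated
misspecifications — not performance on arbitrary real data.

## Evaluation conventions

Selections are scored against the generating truth by TP/FP/TN/FN,
`Recall = TP/(TP+FN)`, `Precision = TP/(TP+FP)` and F1.  When a method
selects nothing, precision is undefined and excluded from aggregate means
with a reported count (coercing it to 0 or 1 would bias the comparison
either way); F1 is 0 whenever there is no true positive but positives
exist, since zero recall pins the harmonic mean at its zero limit, and is
undefined only when there is neither a selection nor a causal taxon.
Benchmarks run each replicate with the true simulated log depth as offset
and with per-replicate derived seeds; reports are bit-reproducible.

## Problem sizes

The test suite runs the statistical checks at reduced but meaningful
scale, chosen to keep Monte-Carlo error well below the tested margins:
null calibration of the zidCRT at `n = 200`, `B = 50`, 300 replicates;
Wald type-I error at `n = 500`, 500 replicates; parameter recovery at
`n ∈ {200, 500, 2000}` with 100 replicates each; pipeline benchmarks at
`(n, m) = (100, 100)` with 20 replicates and `B = 100` (`B = 50` for the
permuted-treatment null, where nothing should be selected at any `B`).

## Known limitations

- The Wald branch loses power under quasi-separation of the zero model
  (very strong `gamma1` with few informative zeros): the estimate runs to
  the box bound and the curvature-based variance explodes, a familiar
  failure of Wald tests near boundaries.  Such taxa are flagged
  (`negative-variance` / `information-singular`); a likelihood-ratio
  alternative is out of scope.
- The discrete `1/(B+1)` floor interacts with BH step-up: with few true
  signals, rejection requires the screened set to stay small (see above).
  Larger `B` buys resolution linearly in compute.
- Perfectly collinear mediator columns leak signal into the distilled fit
  `Yhat_j` and inflate `p1` for the duplicated taxon — inherent to
  distillation, not detected automatically.
- Bootstrap CIs assume the sampling distribution of the effect estimate is
  well approximated by resampling rows; with `n ≲ 50` or near-degenerate
  taxa the re-fit failure rate rises and the interval errors out above 20%
  failures.
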