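# cramed

Mediation analysis for sparse microbiome count data: which taxa carry the
effect of a binary treatment (or exposure) on a continuous outcome?

Microbiome count tables are high-dimensional, heavily zero-inflated and
over-dispersed, which breaks mediation methods built for Gaussian
mediators.  `cramed` implements the CRAmed framework: each taxon's counts
are modelled with a zero-inflated negative-binomial (ZINB) regression, the
mediator→outcome path is tested with a zero-inflated distilled conditional
randomization test (zidCRT), the treatment→mediator path with a Wald test,
and the two are combined by joint significance with Benjamini–Hochberg
control of the false discovery rate.  For each selected taxon the natural
indirect effect is decomposed into a presence–absence component and an
abundance component — whether a microbe mediates by appearing/disappearing
or by changing its abundance when present.

## Model

For taxon *j* with counts *M<sub>j</sub>*, treatment *T* and covariates *X*:

```
M_j ~ 0                 with probability pi_j,   logit(pi_j)  = gamma0_j + gamma1_j T + gamma_xj' X
      NB(lambda_j, phi_j) otherwise,             log(lambda_j) = o + alpha0_j + alpha1_j T + alpha_xj' X
Y   ~ N(beta0 + beta1 T + beta_x' X + beta_m' M, sigma^2)
```

with *o* an optional log-sequencing-depth offset.  The per-taxon natural
indirect effect at covariate profile *x*, with
`a_t = exp(alpha0_j + alpha1_j t + alpha_xj'x)` and
`g_t = 1 + exp(gamma0_j + gamma1_j t + gamma_xj'x)`, is

```
NIE_j  = beta_mj (a_1/g_1 - a_0/g_0)              (total)
NIEP_j = beta_mj (a_1/g_1 - a_1/g_0)              (presence–absence path)
NIEA_j = beta_mj (a_1/g_0 - a_0/g_0)              (abundance path)
```

and `NIE_j = NIEP_j + NIEA_j` exactly.  The null of no mediation for taxon
*j* is composite — `beta_mj = 0` **or** `alpha1_j = gamma1_j = 0` — and is
tested by `pmax_j = max(p1_j, p2_j)` where `p1_j` is the zidCRT p-value and
`p2_j` the 2-df Wald p-value on `(alpha1_j, gamma1_j)`.

See `docs/methods.md` for the full procedure, its assumptions and the
numerical choices.

## Worked example

Simulate a benchmark dataset with 5 truly causal taxa out of 100, run the
pipeline, and score the selection:

```sh
cramed simulate --n 100 --m 100 --seed 2 --out-prefix demo
cramed run --counts demo.counts.tsv --metadata demo.metadata.tsv \
    --treatment treatment --outcome outcome \
    --offset column:log_depth --prevalence 0 \
    --b 100 --fdr 0.05 --seed 2 --no-ci --out demo.results.tsv
cramed evaluate --results demo.results.tsv --truth demo.truth.json \
    --out demo.metrics.json
```

The `run` step prints `tested 16 taxa, selected 5 at FDR 0.05` and writes
one row per screened taxon; the selected rows are exactly the five causal
taxa of this draw:

```
 taxon       p1           p2    p_adj       nie      niep      niea
taxon1 0.009901 2.364968e-17 0.031683 -0.003450 -0.000040 -0.003410
taxon2 0.009901 5.177045e-12 0.031683  0.000196 -0.000025  0.000221
taxon3 0.009901 7.885052e-10 0.031683 -0.000397 -0.000005 -0.000392
taxon4 0.009901 1.576577e-18 0.031683 -0.001267  0.000018 -0.001285
taxon5 0.009901 7.414663e-04 0.031683  0.003113  0.003142 -0.000030
```

Each `p1` sits at the randomization floor `1/(B+1) ≈ 0.0099` (the observed
statistic beat all 100 resamples), each Wald `p2` is tiny, and the
decomposition is informative: taxon 5 is simulated with an effect on
presence–absence only (`alpha1 = 0`), and indeed its indirect effect is
carried almost entirely by `niep`, while taxa 1–4 mediate mainly through
abundance.  `evaluate` confirms `recall = precision = 1` against the truth
labels.  Effects are reported at the reference covariate profile and unit
sequencing depth, hence the small magnitudes.

Not every draw is this clean: averaged over 20 replicates at
`(n, m) = (100, 100)` the pipeline reaches recall ≈ 0.56 and F1 ≈ 0.59
with almost no false positives (precision ≈ 0.95), while the
Gaussian-mediator baseline (`--naive`) stays near recall 0.02 — zero
inflation breaks its mediator model.  See the benchmark API:

```python
from cramed import CramedConfig, run_benchmark
rep = run_benchmark(100, 100, method="cramed", generator="zinb",
                    n_replicates=20, config=CramedConfig(B=100, compute_ci=False),
                    seed=0)
print(rep.recall, rep.precision, rep.f1)
```

The same count table can come from real data: a samples×taxa TSV/CSV plus a
metadata table with treatment/outcome (and optional covariate) columns;
taxa seen in fewer than 10% of samples are filtered by default and the log
library size is used as the count-model offset.

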