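# bmdd — bimodal-Dirichlet imputation of zero-inflated microbiome counts

Microbiome sequencing data arrive as a sparse sample-by-taxon count table:
many cells are zero because a taxon is truly absent *or* merely undetected
at the achieved sequencing depth.  Downstream analyses that work on the
log scale (differential abundance, log-ratio ordination, ...) cannot handle
zeros, and the traditional fix — adding a pseudocount to every count — is
ad hoc and can change results materially.

`bmdd` treats the zeros as a Bayesian inference problem.  Each taxon's
Dirichlet shape parameter is modelled as a two-point mixture

```
delta_ij ~ Bernoulli(pi_j)
X_i      ~ Dirichlet(alpha_{1,delta_i1}, ..., alpha_{m,delta_im})
W_i      ~ Multinomial(N_i, X_i)
```

with a low mode `alpha_j0` (often far below 1, producing a spike of
near-zero abundances) and a high mode `alpha_j1`.  This *bimodal Dirichlet*
prior captures the zero-inflated, sometimes two-regime abundance
distributions real taxa show, while still covering ordinary unimodal taxa.
The posterior over the latent composition `X` is approximated by mean-field
variational EM; the posterior mean is a strictly positive imputed
composition, and multiple posterior draws propagate imputation uncertainty
into downstream tests via Rubin's rule.

The package provides, as library functions and a thin `bmdd` CLI:

- `fit` / `posterior_mean` / `posterior_sample` — model fitting and
  imputation, plus an exact `2^m` enumeration oracle for validation;
- `simulate_bmdd` / `simulate_parametric` / `spike_signal` — ground-truth
  simulators (well-specified, and gamma / log-normal / Poisson /
  negative-binomial with inter-taxon correlation) and a two-group
  differential-abundance signal;
- `evaluate_all` / `naive_impute` — fifteen composition-recovery metrics
  and four pseudocount-style baselines;
- `mi_daa` / `benchmark_fdr_power` — multiple-imputation differential
  abundance analysis (per-draw log-linear tests, compositional bias
  correction by mode-centering, Rubin's-rule pooling, BH adjustment) and
  an empirical FDR/power harness.

See `docs/methods.md` for the model, algorithm and design choices.

## Worked example

```python
from bmdd import SimConfig, mi_daa, simulate_parametric, spike_signal

cfg = SimConfig(n_samples=100, n_taxa=50, setting="gamma",
                differential_fraction=0.1, seed=3)
truth = spike_signal(simulate_parametric(cfg), cfg)
res = mi_daa(truth.table, truth.group, n_imputations=20,
             target_fdr=0.05, seed=3)
```

Running `python examples/03_multiple_imputation_daa.py` (the script around
the snippet above) prints:

```
5 truly differential taxa out of 50; 4 rejections at FDR 0.05
true positives: 4, false positives: 0

top taxa by q-value:
  taxon11    effect -1.38 q=7.28e-06  (differential)
  taxon30    effect +1.61 q=0.000525  (differential)
  ...
```

`effect` is the pooled, bias-corrected slope of log abundance on the group
label (a log-fold-change scale), and `q` the BH-adjusted p-value: the
pipeline recovers 4 of the 5 spiked taxa with no false positives even
though the data were generated from a gamma model the prior does not
match.  The other example scripts show imputation of zero cells
(`01`), the fifteen-metric comparison against pseudocount baselines
(`02`, where the model wins on 13/15 metrics), and posterior uncertainty
intervals for unobserved taxa (`04`).

Equivalent shell usage:

```sh
bmdd simulate --setting s1 --n 80 --m 100 --seed 1 --out sim/
bmdd impute sim/counts.tsv --out imputed.tsv
bmdd evaluate --est imputed.tsv --truth sim/truth_composition.tsv --out report.tsv
```

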