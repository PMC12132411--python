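"""Differential abundance analysis with multiple imputation.

Simulates a two-group study from a gamma model (deliberately NOT the
fitted model) with 10% truly differential taxa, then runs the pipeline:
posterior draws -> per-draw log-linear tests with compositional bias
correction -> Rubin's-rule pooling -> Benjamini-Hochberg.  Because every
posterior draw is strictly positive, no ad-hoc pseudocount is needed, and
pooling across draws propagates the imputation uncertainty into the
p-values.
"""

import numpy as np

from bmdd import SimConfig, mi_daa, simulate_parametric, spike_signal

cfg = SimConfig(n_samples=100, n_taxa=50, setting="gamma",
                differential_fraction=0.1, seed=3)
truth = spike_signal(simulate_parametric(cfg), cfg)

res = mi_daa(truth.table, truth.group, n_imputations=20, target_fdr=0.05,
             seed=3)

rej = res.rejected
true_hits = int((rej & truth.differential).sum())
false_hits = int((rej & ~truth.differential).sum())
print(f"{int(truth.differential.sum())} truly differential taxa out of "
      f"{truth.table.n_taxa}; {int(rej.sum())} rejections at FDR 0.05")
print(f"true positives: {true_hits}, false positives: {false_hits}")
print("\ntop taxa by q-value:")
order = np.argsort(res.q_value)[:8]
for j in order:
    flag = "differential" if truth.differential[j] else "null"
    print(f"  {res.taxon_ids[j]:<10} effect {res.effect[j]:+.2f} "
          f"q={res.q_value[j]:.3g}  ({flag})")
print("-> pooled effects are on the log-fold-change scale after "
      "mode-centering; q-values control the FDR across the 50 taxa.")
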