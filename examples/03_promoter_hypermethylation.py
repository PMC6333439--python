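"""Promoter mCG dynamics: hyper-mCG calling and the distance-resolved
correlation between mCG change and expression change around the TSS.

A promoter is TSS +/- 500 bp; a promoter is hyper-methylated when its
weighted mCG rises by strictly more than 0.1 between two samples.
"""

import numpy as np

import methyldyn as md

sim = md.simulate(md.SimConfig(seed=0))
tps = list(sim.methylomes)

early = md.promoter_levels(sim.methylomes[tps[0]], sim.genes)
late = md.promoter_levels(sim.methylomes[tps[-1]], sim.genes)
calls = md.call_hyper_promoters(early, late, threshold=0.1)
truth = sim.truth.hyper_promoters
called = set(calls.index[calls["is_hyper"]])
print(f"hyper promoters called: {len(called)} "
      f"(planted: {len(truth)}; recall "
      f"{len(called & truth) / len(truth):.2f}, precision "
      f"{len(called & truth) / len(called):.2f})")

logfc = np.log2((sim.expression[tps[-1]] + 0.1) / (sim.expression[tps[0]] + 0.1))
curve = md.distance_resolved_correlation(
    sim.methylomes[tps[0]], sim.methylomes[tps[-1]], sim.genes, logfc,
    window_bp=2000, bin_bp=500)
print("\noffset_bp  spearman_r  n_genes")
for row in curve.itertuples():
    r = f"{row.r:+.3f}" if not np.isnan(row.r) else "   NA "
    print(f"{row.offset:>8}   {r}      {row.n_genes}")
print("\nThe most negative correlation sits at the TSS-proximal bins: genes "
      "whose promoters gain mCG are the ones whose expression falls.")
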