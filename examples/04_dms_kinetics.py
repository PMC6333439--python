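"""Differential methylation sites and the transition-vector kinetics
encoding.

Calls DMSs between every ordered pair of samples (Fisher exact + BH,
q < 0.1), combines hypomethylation calls into per-site kinetics vectors
(adjacent call -1, two-step -0.5, three-step -0.33; element-wise minimum
across calls), groups sites by exact pattern, and checks how far DMSs sit
from the nearest TSS.
"""

import methyldyn as md
from methyldyn.kinetics import assign_categories

sim = md.simulate(md.SimConfig(seed=0))
tps = list(sim.methylomes)

calls = [md.call_dms_pair(sim.methylomes[tps[i]], sim.methylomes[tps[j]])
         for i in range(len(tps)) for j in range(i + 1, len(tps))]
vectors = md.encode_kinetics(calls, sim.design)
groups = md.group_by_kinetics(vectors, min_size=100)
print(f"{len(vectors)} DMSs encoded into {len(groups)} distinct kinetic patterns")
print("\npatterns with more than 100 members (earliest-demethylating first):")
displayed = groups.loc[groups["displayed"]]
for _, row in displayed.iterrows():
    pat = "(" + ", ".join(f"{v:+.2f}" for v in row["pattern"]) + ")"
    print(f"  {pat}  n={row['size']}")

rep = md.evaluate_recovery(sim.truth, kinetics=vectors)
print("\nplanted-class confusion matrix (rows: planted drop transition):")
print(rep["dms"]["confusion"].to_string())
print(f"diagonal fraction among resolved sites: "
      f"{rep['dms']['diagonal_fraction']:.3f}")

frac = md.tss_distance_fraction(vectors.reset_index()[["chrom", "pos"]],
                                sim.genes, cutoff=2500)
print(f"\nfraction of DMSs more than 2.5 kb from the nearest TSS: {frac:.3f}")
print("DMSs are planted in intergenic space; on this gene-dense synthetic "
      "genome about half end up more than 2.5 kb from a TSS.")
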