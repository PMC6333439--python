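"""PWM scanning with exact p-values and hypergeometric motif enrichment.

Scans the synthetic genome for the planted motif (log-odds score, exact
background p < 1e-5), masks peaks overlapping lowly-methylated regions of
the second sample, and tests motif enrichment in foreground vs background
peaks (center +/- 250 bp) with the hypergeometric test.
"""

import methyldyn as md

sim = md.simulate(md.SimConfig(seed=0))
tps = list(sim.methylomes)

hits = md.scan_genome(sim.genome, sim.pwm)
print(f"motif hits at p < 1e-5: {len(hits)} "
      f"(planted: {len(sim.truth.motif_fg_instances) + len(sim.truth.motif_bg_instances)})")

lmr = md.lowly_methylated_regions(sim.methylomes[tps[1]], max_level=0.5, min_cg=4)
fg = md.mask_regions(sim.fg_peaks, lmr)
print(f"foreground peaks after LMR masking: {len(fg)} of {len(sim.fg_peaks)}")

bg = md.extend_from_center(sim.bg_peaks, 250)
res = md.hypergeometric_enrichment(fg, bg, {sim.pwm.motif_id: hits})[0]
print(f"\n{res.motif_id}: {res.k}/{res.n} foreground vs {res.K}/{res.N} "
      f"background regions carry a hit")
print(f"direction={res.direction}, p={res.p:.3g}, q={res.q:.3g} "
      f"(significant at q < 1e-5: {res.significant})")
print("\nThe planted motif is strongly enriched in foreground peaks, the "
      "planted-rate difference the hypergeometric test is built to detect.")
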