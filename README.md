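# methyldyn

Analysis toolkit for whole-genome bisulfite methylomes measured as an
**ordered sample series** — the setting of direct-reprogramming and
differentiation time courses, where the questions are *where* methylation
changes, *when* it changes, and *how* those changes relate to
transcription.

It is written for computational epigenomicists working from per-cytosine
count tables (allc-style TSVs as produced by methylome mapping pipelines),
gene annotations, region sets (BED) and expression matrices. Everything is
importable Python on pandas/NumPy containers; a thin `methyldyn` console
script exposes the main pipelines, and `examples/` contains one short
narrative script per capability.

## What it computes

**Weighted methylation levels.** Every level is the pooled ratio
`Σ mc / Σ cov` over a site set, resolved by context class: mCG
(trinucleotide `CGN`) versus mCH (`CHN`, H ∈ {A, C, T}) and any
trinucleotide subclass such as mCAC. The bisulfite failure-to-convert rate
is estimated from an unmethylated lambda spike-in after excluding
dcm-methylated CAG/CTG positions; reported levels are raw fractions (the
rate feeds only the binomial per-site methylation caller).

**Flank-normalized metagene mCH profiles.** Each gene body is scaled to a
fixed number of equal-fraction bins (TSS→TES in transcriptional
orientation) with fixed-width flanking windows (100 kb by default); the
profile is divided by the pooled flank level, removing the genome-wide
baseline so samples with very different global mCH are comparable.
Profiles are clustered with seeded k-means; samples are clustered by
Spearman correlation of gene-body mCH with average linkage.

**Promoter mCG dynamics.** A promoter is TSS ± 500 bp; a promoter is
called hyper-methylated when its weighted mCG rises by strictly more than
0.1 between two samples. A distance-resolved curve correlates per-bin
ΔmCG around the TSS with expression log fold change across genes.

**DMS kinetics encoding.** Differentially methylated sites between sample
pairs (site-level two-sided Fisher exact test, Benjamini–Hochberg,
q < 0.1 by default) are combined into a per-site *transition vector* with
one element per consecutive transition of the series: a hypomethylation
call spanning d transitions contributes `round(−1/d, 2)` (−1 adjacent,
−0.5 two-step, −0.33 three-step) to every transition it covers, and a
site's vector is the element-wise minimum over its calls. Sites group by
exact pattern; groups with more than 100 members are flagged as robust.

**Motif and interval statistics.** FIMO-style PWM scanning (log₂-odds
scores, exact background p-values by dynamic programming, hits at
p < 1e−5), half-open interval overlap (≥ 1 bp rule), ± 250 bp site
extension, a windowed lowly-methylated-region masker, ChIP-signal
meta-profiles around anchor sites, and hypergeometric enrichment of motif
hits in a foreground region set against a background (significant at
q < 1e−5).

**Expression integration.** Genes ranked by early gene-body mCH, per-bin
hypergeometric enrichment of up/down-regulated genes along the ranking,
expression-stratified mCH trajectories (with an RPKM > 3 "actively
expressed" filter), and rank-sum / Fisher group comparisons.

**Synthetic data with ground truth.** `methyldyn.simulate` generates a
complete, internally consistent input suite — methylomes across the
series, lambda spike-in, genes, expression, DE labels, peaks, a genome
with planted motif instances — with every planted effect recorded, so the
whole pipeline can be exercised end to end and scored against truth
(`evaluate_recovery`).

## Worked example

```bash
python examples/04_dms_kinetics.py
```

prints (abridged):

```
963 DMSs encoded into 20 distinct kinetic patterns

patterns with more than 100 members (earliest-demethylating first):
  (-0.33, -0.50, -1.00)  n=108
  (-0.33, -0.33, -0.33)  n=120

planted-class confusion matrix (rows: planted drop transition):
     1    2    3  unresolved
1  161    0    0         157
2    0  188    0         155
3    0    0  167         126
diagonal fraction among resolved sites: 1.000
```

Reading this: the caller recovered 963 of 1,200 planted DMSs; each
recovered site's transition vector was combined from all of its pairwise
calls. The confusion matrix compares the planted demethylation transition
(rows) against the transition carrying the vector's unique −1 element
(columns): every site whose timing was resolved by an adjacent-timepoint
call was assigned to the correct transition, and sites detected only
through non-adjacent comparisons are reported as unresolved rather than
guessed.

The other examples cover global levels and the spike-in
(`01_global_levels.py`), metagene profiling and sample clustering (`02`),
promoter hyper-mCG and the TSS-distance-resolved correlation (`03`), motif
enrichment with LMR masking (`05`), and expression integration (`06`).

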