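# Methods

This note records the models, conventions and numerical choices behind
methyldyn, and what the synthetic-data tests do and do not establish.

## Coordinates, contexts and containers

Per-cytosine tables use 1-based positions of the cytosine on its own
strand with a strand-resolved trinucleotide context read 5'→3'; interval
sets use 0-based half-open BED coordinates. Conversion happens only
through the `pos_to_interval` / `interval_to_pos` helpers, never
implicitly. Chromosome names match by exact string equality; a
`normalize_chrom` helper exists but is never applied automatically. Both
strands of a CpG are independent records and are never pooled unless an
operation's definition pools them. Rows with zero coverage are kept on
load (input fidelity) but contribute nothing to any level, since every
level is a pooled ratio Σmc/Σcov.

Context class is decided by the second base alone: G → CG; A/C/T → CH;
N → ambiguous (such rows are excluded from class-level statistics; rows
whose *first* base is N are dropped at load time and counted in the load
report).

## Levels and the non-conversion rate

The weighted methylation level Σmc/Σcov is the standard WGBS summary; the
alternative (mean of per-site fractions) over-weights shallow sites and is
deliberately not used. The failure-to-convert rate is the pooled level of
an unmethylated lambda spike-in after removing CAG/CTG positions, which in
lambda DNA grown in dcm+ E. coli carry genuine 5mC. Reported levels are
**not** corrected for non-conversion — they are raw fractions, so a sample
with true mCH of 0.2% and a 0.3% conversion floor reads ≈0.5%. The rate's
only consumer is the per-site binomial caller: one-sided tail
P[X ≥ mc | cov, rate], Benjamini–Hochberg within each context class
separately (CG and CH base rates differ by two orders of magnitude, and a
joint adjustment would let the CG signal drag the CH threshold), call at
adjusted p < 0.01.

The mCAC share of mCH is methylated-read-weighted by default (Σmc at CAC
over Σmc at CH); counting binomially *called* sites instead is available
via `weighting="sites"` — the two differ when coverage is uneven, and the
read-weighted form matches how the global levels themselves are pooled.

## Metagene profiles

Bodies are scaled to 60 equal-fraction bins and each 100 kb flank to 20
fixed-width bins (defaults chosen to keep bins ≳1 kb on typical genes; all
exposed). Minus-strand profiles are computed in transcriptional
orientation, so "upstream" is always 5' of the TSS. The normalizer is the
pooled level over both flanks; it makes the profile invariant to any
per-sample global scaling, which is what lets samples at very different
absolute mCH be clustered together. When the flanks have no coverage or no
methylation the raw profile is returned and the normalized one is marked
missing rather than dividing by zero.

For the clustering matrix, genes shorter than the body bin count (in bp)
are dropped (they cannot fill their bins); genes with more than 30%
empty bins are dropped; remaining empty bins are imputed with the gene's
own mean normalized level — gene-local imputation cannot leak structure
across genes, at the cost of slightly shrinking within-gene variance.
K-means uses a fixed seed and relabels clusters by decreasing size
(ties broken by original label), making label vectors reproducible and
comparable across runs. The default k = 20 reflects the scale at which
reprogramming-stage profile families separate on data of this kind; it is
a display resolution, not an inferred quantity.

Sample clustering uses Spearman correlation (robust to the strongly
skewed distribution of gene-body mCH) on pairwise-complete genes and
average linkage on 1 − r. Samples with fewer than 3 non-missing genes are
excluded with a warning rather than silently producing degenerate
correlations.

## Promoter mCG

Promoters are TSS ± 500 bp inclusive (1001 bp); strand matters only for
the sign of distances, not the window. Hyper-methylation is a strict
inequality on the level difference (Δ > 0.1) with a float-tie guard so a
delta exactly at the threshold never calls. The distance-resolved curve
bins [−5 kb, +5 kb) around the TSS at 200 bp (both configurable), computes
per-gene ΔmCG per bin, and reports Spearman r against expression logFC
over genes with coverage in that bin; bins informative for fewer than 20
genes are masked. Pearson is available, but rank correlation is the
default because ΔmCG per bin is bounded and heavy-tailed. Swapping early
and late samples negates every delta and hence (up to ties) every r.

## DMS calling and the kinetics encoding

The pairwise caller is a site-level two-sided Fisher exact test on
(mc, cov−mc) pairs for CG sites covered ≥ 5× in both samples, BH across
tested sites, calls at q < 0.1. It is deliberately assumption-light: no
smoothing, no dispersion model, so a call means the two count pairs alone
are incompatible. The p-values come from a vectorised log-gamma
implementation (probability-mass summation with the conventional
1 + 1e−7 tie slack); the test suite pins it against `scipy.stats.
fisher_exact` to 1e−9 relative error. The encoding is agnostic to the
caller — any source of (earlier, later, sites) triples can be encoded.

A hypomethylation call between samples d transitions apart contributes
round(−1/d, 2) to each covered transition: −1, −0.5, −0.33 for d = 1, 2, 3.
The three-step weight is stored as −0.33 exactly (not −1/3): the encoding
is a bookkeeping convention and the printed two-decimal value *is* the
convention. A site's vector is the element-wise **minimum** of its calls'
contributions — the unique simple combination rule consistent with the
worked multi-call examples (e.g. calls MEF>5d & MEF>22d & 5d>22d give
(−0.5, −0.5, −1); calls 2d>5d & 2d>22d & 5d>22d give (0, −1, −1)); it is
idempotent under duplicated calls and monotone under added calls. Only
hypo-direction calls are encoded (the analysis tracks mCG *reduction*);
hyper calls are retained in the pairwise tables. Grouping is by exact
vector identity, ordered lexicographically (most negative first, i.e.
earliest demethylation first); groups larger than 100 members are flagged
as statistically robust for display. An optional k-means mode is not
provided: exact patterns are finite, interpretable, and already a
partition.

## Interval, motif and enrichment statistics

Half-open intervals overlap iff startA < endB and startB < endA — abutting
intervals share no base and do not overlap. Site extension by ±250 bp
gives 501 bp windows (the site itself plus 250 bp each side), clipped at
chromosome bounds. The lowly-methylated-region masker is a windowed
stand-in for HMM-based UMR/LMR callers: maximal runs of ≥ 4 consecutive
covered CG sites each at level ≤ 0.5 become regions; peaks overlapping
(≥ 1 bp) any such region of the designated early sample are removed before
demethylation analyses, so pre-existing open/lowly-methylated regions
cannot masquerade as induced demethylation. It has no FDR control and no
posterior segmentation; boundaries are site positions, not inferred
change-points.

PWM scanning scores log₂(p_i(base)/bg(base)) summed over the motif, both
strands, N-containing windows skipped. P-values are exact for the 0-order
background: the score distribution of a random width-w word is built by
dynamic programming over scores discretised to a 1e−3 bit grid (zero
matrix entries floored at 1e−4 before log-odds). The DP agrees with
exhaustive 4^w enumeration on the same grid; the only approximation is
the grid itself. Hits are kept at p < 1e−5; note that a width-4 motif
cannot pass this threshold even as a perfect match (p = 4⁻⁴ ≈ 3.9e−3) —
informative motifs need width ≳ 9.

Enrichment per motif is hypergeometric on region counts: k of n foreground
and K of N background regions carrying ≥ 1 hit; upper tail for enrichment,
lower for depletion, the smaller reported with its direction; BH across
motifs, significance at q < 1e−5. The foreground is not a subset of the
background (foreground DMS neighborhoods versus an independent background
region atlas), so the hypergeometric model is an approximation — the
convention this family of analyses uses — and k > K yields p = 0. The
background "extend 250 bp from center" preprocessing is an explicit helper
(`extend_from_center`) applied by the pipeline, keeping the statistic
itself pure.

The signal meta-profile treats a scored region set as piecewise-constant
per-base signal (0 where uncovered, intervals assumed non-overlapping) and
averages per 50 bp offset bin over ±3 kb around anchors.

## Expression integration

Rank enrichment: genes sorted by descending early normalized gene-body
mCH (ties broken by gene id for determinism), consecutive bins of 200;
per bin the hypergeometric upper tail for over-representation of "down"
(and separately "up") labels, with the labeled genes in the ranking as the
population — unlabeled genes dilute a bin's draw count but are not
"failures", and a bin with no labeled genes has p = 1. DE labels are
inputs: no expression model is fitted here, which decouples the pipeline
from any particular DE caller. "Average expression across the series" is
the arithmetic mean of RPKM over timepoints, log-transformed afterwards;
expression bins are half-open in log2(RPKM+1); the "actively expressed"
filter is strict (mean RPKM > 3). Heatmap normalization is per-gene
z-score.

## The synthetic generator

The generator emulates the statistical structure these analyses assume:
four ordered timepoints with rising global mCG (0.727 → 0.795) and mCH
(0.10% → 0.28%), per-site truth q assembled additively from the global
trajectory plus planted offsets, clipped to [0, 1], and observed counts
mc ~ Binomial(cov, q + (1−q)·r) with cov ~ Poisson(30) and r = 0.003 the
failure-to-convert rate (a fixed-coverage mode exists for exact tests).
Default scale is 2 chromosomes × 2 Mb, ~40,000 CG and ~150,000 CH sites,
500 non-overlapping genes — chosen so the full pipeline runs in well under
five minutes on one CPU; the methylome site catalogue is positional and
independent of the generated genome sequence, which serves motif scanning
only.

Planted structure, each recorded in the ground truth: (i) gene-body mCH
at the late timepoints gains an additive term scaled by
(1 − expression percentile), producing the mCH–expression anticorrelation,
plus an extra +0.003 on downregulated genes (half-strength at the
penultimate timepoint); (ii) baseline mCH at CAC sites scales up linearly
to 2× by the final timepoint, reproducing progressive mCAC predominance;
(iii) promoters are lowly methylated (0.20) and a 10% quota — drawn from
downregulated genes first, the silenced program — gains Δ = +0.3 from the
third timepoint on; (iv) DMSs are single CG sites in intergenic space at
level 0.9 stepping down by 0.4 at a chosen transition, 400 per class;
(v) the lambda spike-in has q = 0 plus dcm-like CAG/CTG sites at q = 0.8,
exercising the exclusion rule; (vi) a width-10 consensus motif is written
into 60% of foreground and 5% of background peak regions. Identical seeds
give byte-identical output files; all randomness flows from one
`numpy.random.Generator`.

What the generator does *not* emulate: read-level bisulfite chemistry,
chromatin-state-dependent methylation landscapes, spatial autocorrelation
of methylation beyond the planted blocks, overlapping genes and isoforms,
copy-number or SNV artifacts. Passing recovery tests therefore shows the
estimators are correct and well calibrated under the stated sampling
model, not that they are robust to every artifact of real libraries.

### Recovery scoring

`evaluate_recovery` assigns a recovered DMS its kinetic class as the
transition holding the vector's **unique −1** element: a −1 exists exactly
when an adjacent-timepoint call resolved the timing. Sites detected only
through non-adjacent comparisons (e.g. a lone MEF→22d call, vector
(−0.33, −0.33, −0.33)) genuinely carry no timing information and are
reported as "unresolved" rather than forced into a class; the confusion
matrix is computed over resolved sites, with sensitivity (any detection)
and the observed false-site rate reported alongside. At the default study
conditions (Δ = 0.4, coverage ~30×, FDR 0.1 across ~40k tested sites) the
per-pair test has moderate power (~0.6), so demanding the *complete*
expected vector would conflate caller power with encoder correctness;
timing resolution via an adjacent call is the scientifically meaningful
unit of recovery.

## Numerical choices and degenerate inputs

BH is the "q value" convention throughout. Fisher and rank-sum tests are
two-sided; the rank-sum uses the normal approximation. Constant inputs to
a correlation return a missing value with the input flagged rather than
raising. Empty region sets raise in enrichment (no valid population);
regions with no covered site are excluded from level distributions;
metagene bins with no sites are NaN in raw profiles. K-means requires a
complete matrix and refuses k larger than the gene count. The kinetics
encoder rejects calls between identical samples and calls whose order
contradicts the series.

## Known limitations

The Fisher caller ignores biological replication and overdispersion, so
its q-values are calibrated against sampling noise only. The LMR masker
and the hypergeometric background convention are simplified stand-ins for
HMM segmentation and matched-background resampling respectively. PWM
scanning supports only 0-order backgrounds. The TSS-distance statistic
uses TSS positions only (no gene-body exclusion zone). Chromosome-end
clipping is recorded for promoters but windows are not re-centered.
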