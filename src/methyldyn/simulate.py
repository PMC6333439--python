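"""Synthetic methylome series with planted, recoverable ground truth.

The generator emulates the statistical structure of a fibroblast-to-neuron
reprogramming methylome time course: a four-sample ordered series with
rising global mCG and mCH, gene-body mCH accumulating preferentially on
genes that become downregulated, promoter hyper-mCG on a chosen gene
subset, single-cytosine demethylation events (DMSs) with chosen kinetic
classes, an unmethylated lambda spike-in with dcm-like CAG/CTG positions,
and a genome carrying planted motif instances inside a fraction of
foreground peak regions.

Per site i and timepoint t a true methylation probability q[i,t] is
assembled additively from the global trajectory and the planted offsets
(clipped to [0,1]); the observed methylated count is
Binomial(cov, q + (1-q)*r) with cov ~ Poisson(coverage_mean) and r the
failure-to-convert rate.  The same seed yields byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import GeneModel, RegionSet, SampleMethylome, SeriesDesign
from .io import PWM, write_allc, write_genes, write_pwm, write_regions
from .kinetics import encode_kinetics

LAMBDA_GENOME_SIZE = 48_502


@dataclass
class SimConfig:
    seed: int = 42
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    timepoints: tuple = ("MEF", "Ascl1_2d", "Ascl1_5d", "Ascl1_22d")
    # global weighted-level targets per timepoint (fractions)
    global_mcg_trajectory: tuple = (0.727, 0.740, 0.770, 0.795)
    global_mch_trajectory: tuple = (0.0010, 0.0012, 0.0018, 0.0028)
    cg_density: float = 0.010   # CG sites per bp
    ch_density: float = 0.0375  # CH sites per bp
    n_genes: int = 500
    frac_up: float = 0.15
    frac_down: float = 0.15
    # additive mCH gain on down genes (half at 5d, full at 22d)
    mch_gain_for_down: float = 0.003
    # additive mCH at 22d scaled by (1 - expression percentile), all genes
    mch_expr_anticorr: float = 0.004
    # fold enrichment of baseline mCH at CAC sites by the final timepoint
    # (mCAC becomes the dominant mCH subclass as the series matures)
    mcac_enrichment_final: float = 2.0
    promoter_hyper_fraction: float = 0.10
    promoter_hyper_delta: float = 0.30
    promoter_base_mcg: float = 0.20
    # per-site level heterogeneity (uniform half-widths); 0 for exact modes
    cg_site_jitter: float = 0.08
    promoter_site_jitter: float = 0.05
    # (drop_transition 1-based, count, delta-level) per kinetic class
    dms_catalog: tuple = ((1, 400, 0.4), (2, 400, 0.4), (3, 400, 0.4))
    dms_high_level: float = 0.90
    coverage_mean: float = 30.0
    fixed_coverage: int | None = None  # exact-test mode
    nonconversion_rate: float = 0.003
    lambda_n_ch: int = 10_000
    lambda_n_cag: int = 2_000
    lambda_cag_level: float = 0.80
    motif_consensus: str = "TGCATGACGT"
    motif_fg_rate: float = 0.60
    motif_bg_rate: float = 0.05
    n_fg_peaks: int = 300
    n_bg_peaks: int = 1_000
    peak_width: int = 500

    def validate(self) -> None:
        T = len(self.timepoints)
        if T < 2:
            raise ValueError("need at least two timepoints")
        for traj in (self.global_mcg_trajectory, self.global_mch_trajectory):
            if len(traj) != T or any(not 0 <= v <= 1 for v in traj):
                raise ValueError("trajectories must give one fraction in [0,1] per timepoint")
        for name in ("frac_up", "frac_down", "promoter_hyper_fraction",
                     "motif_fg_rate", "motif_bg_rate", "nonconversion_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.promoter_base_mcg + self.promoter_hyper_delta > 1 + 1e-9:
            raise ValueError("promoter hyper delta pushes level above 1")
        for k, count, delta in self.dms_catalog:
            if not 1 <= k <= T - 1:
                raise ValueError(f"DMS drop transition {k} outside 1..{T - 1}")
            if not 0 < delta <= self.dms_high_level:
                raise ValueError("DMS delta pushes level below 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "dms_catalog" in raw:
            raw["dms_catalog"] = tuple(tuple(x) for x in raw["dms_catalog"])
        for key in ("timepoints", "global_mcg_trajectory", "global_mch_trajectory"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    nonconversion_rate: float
    labels: pd.Series                 # gene_id -> up/down/static
    expression_percentile: pd.Series  # gene_id -> rank fraction of mean RPKM
    hyper_promoters: set
    dms: pd.DataFrame                 # chrom,pos,strand,drop_transition + expected v columns
    motif_fg_instances: list          # (chrom, start0) of planted foreground instances
    motif_bg_instances: list
    gene_mch_offsets: pd.Series       # planted per-gene mCH offset at the final timepoint


@dataclass
class SimResult:
    config: SimConfig
    design: SeriesDesign
    methylomes: dict
    lambda_methylome: SampleMethylome
    genes: list
    expression: pd.DataFrame
    labels: pd.Series
    fg_peaks: RegionSet
    bg_peaks: RegionSet
    genome: dict
    pwm: PWM
    chip_track: RegionSet
    truth: GroundTruth

    def write(self, out_dir) -> None:
        """Write every output in standard text formats."""
        os.makedirs(out_dir, exist_ok=True)
        for name, meth in self.methylomes.items():
            write_allc(meth, os.path.join(out_dir, f"allc_{name}.tsv"))
        write_allc(self.lambda_methylome, os.path.join(out_dir, "allc_lambda.tsv"))
        write_genes(self.genes, os.path.join(out_dir, "genes.tsv"))
        self.expression.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
        self.labels.rename("label").to_csv(os.path.join(out_dir, "labels.tsv"), sep="\t")
        write_regions(self.fg_peaks, os.path.join(out_dir, "peaks_foreground.bed"))
        write_regions(self.bg_peaks, os.path.join(out_dir, "peaks_background.bed"))
        write_regions(self.chip_track, os.path.join(out_dir, "chip_track.bedgraph.bed"))
        write_pwm([self.pwm], os.path.join(out_dir, "motif.meme"))
        with open(os.path.join(out_dir, "genome.fa"), "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        gt_dir = os.path.join(out_dir, "ground_truth")
        os.makedirs(gt_dir, exist_ok=True)
        self.truth.dms.to_csv(os.path.join(gt_dir, "dms.tsv"), sep="\t", index=False)
        self.truth.labels.rename("label").to_csv(os.path.join(gt_dir, "labels.tsv"), sep="\t")
        pd.Series(sorted(self.truth.hyper_promoters), name="gene_id").to_csv(
            os.path.join(gt_dir, "hyper_promoters.tsv"), sep="\t", index=False
        )


def _consensus_pwm(consensus: str, strength: float = 0.94) -> PWM:
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(consensus), 4), (1 - strength) / 3)
    for i, b in enumerate(consensus):
        mat[i, base_idx[b]] = strength
    return PWM("planted_motif", mat)


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = list(cfg.chrom_sizes)
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    genes = []
    gid = 0
    for chrom in chroms:
        size = cfg.chrom_sizes[chrom]
        slot = size // per_chrom
        for s in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            length = int(slot * rng.uniform(0.3, 0.8))
            offset = int(rng.integers(0, slot - length))
            start = s * slot + offset + 1
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand, tss, tes))
            gid += 1
    return genes


def _expected_patterns(cfg: SimConfig, design: SeriesDesign) -> dict[int, tuple]:
    """Kinetics vector a perfect caller would produce for a step drop at
    transition k: every ordered pair straddling the drop is called."""
    out = {}
    probe = ("chrX", 1, "+")
    for k in {c[0] for c in cfg.dms_catalog}:
        calls = [
            (design.ordered_samples[i], design.ordered_samples[j], [probe])
            for i in range(k)
            for j in range(k, len(design.ordered_samples))
        ]
        vec = encode_kinetics(calls, design)
        out[k] = tuple(vec.iloc[0])
    return out


def simulate(config: SimConfig | None = None, out_dir=None) -> SimResult:
    """Generate the full synthetic input suite; optionally write it."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = SeriesDesign(list(cfg.timepoints))
    T = len(cfg.timepoints)
    r = cfg.nonconversion_rate

    genes = _place_genes(cfg, rng)

    # --- expression, DE labels -------------------------------------------
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    n_up = int(round(cfg.frac_up * n))
    n_down = int(round(cfg.frac_down * n))
    perm = rng.permutation(n)
    labels = pd.Series("static", index=gene_ids, name="label")
    labels.iloc[perm[:n_up]] = "up"
    labels.iloc[perm[n_up : n_up + n_down]] = "down"
    base_rpkm = rng.lognormal(mean=2.0, sigma=1.2, size=n)
    ramps = {
        "static": np.ones(T),
        "down": np.linspace(1.0, 0.15, T),
        "up": np.linspace(1.0, 4.0, T),
    }
    noise = rng.lognormal(0.0, 0.10, size=(n, T))
    expr = np.array([base_rpkm[i] * ramps[labels.iloc[i]] for i in range(n)]) * noise
    expression = pd.DataFrame(expr, index=gene_ids, columns=cfg.timepoints)
    mean_rpkm = expression.mean(axis=1)
    pct = mean_rpkm.rank(method="average") / n  # expression percentile in (0,1]

    # --- site catalogue ---------------------------------------------------
    frames = {t: [] for t in cfg.timepoints}
    truth_dms_rows = []
    # hyper-mCG promoters target the silenced program: down genes first,
    # padded with static genes if the quota exceeds the down set
    n_hyper = int(round(cfg.promoter_hyper_fraction * n))
    down_ids = list(labels.index[labels == "down"])
    static_ids = list(labels.index[labels == "static"])
    pool = [down_ids[i] for i in rng.permutation(len(down_ids))]
    pool += [static_ids[i] for i in rng.permutation(len(static_ids))]
    hyper_set: set[str] = set(pool[:n_hyper])
    gene_offset_final = pd.Series(0.0, index=gene_ids)

    dms_quota = list(cfg.dms_catalog)
    for chrom, size in cfg.chrom_sizes.items():
        n_cg = int(round(size * cfg.cg_density))
        n_ch = int(round(size * cfg.ch_density))
        pos = rng.choice(size, size=n_cg + n_ch, replace=False) + 1
        pos.sort()
        is_cg = np.zeros(n_cg + n_ch, dtype=bool)
        is_cg[rng.choice(n_cg + n_ch, size=n_cg, replace=False)] = True
        strand = np.where(rng.random(n_cg + n_ch) < 0.5, "+", "-")
        third = rng.choice(list("ACGT"), size=n_cg + n_ch)
        second_ch = rng.choice(list("ACT"), size=n_cg + n_ch, p=[0.5, 0.25, 0.25])
        context = np.where(
            is_cg,
            np.char.add("CG", third.astype("U1")),
            np.char.add(np.char.add("C", second_ch.astype("U1")), third.astype("U1")),
        )

        chrom_genes = [g for g in genes if g.chrom == chrom]
        gene_start = np.array([g.start for g in chrom_genes])
        gene_end = np.array([g.end for g in chrom_genes])
        gene_tss = np.array([g.tss for g in chrom_genes])
        # gene body membership (genes are non-overlapping and sorted)
        gi = np.searchsorted(gene_start, pos, side="right") - 1
        in_body = (gi >= 0) & (pos <= gene_end[np.clip(gi, 0, None)])
        body_gene = np.where(in_body, gi, -1)
        # promoter membership: nearest TSS within 500 bp
        order = np.argsort(gene_tss)
        tss_sorted = gene_tss[order]
        j = np.searchsorted(tss_sorted, pos)
        dist_r = np.where(j < len(tss_sorted), np.abs(tss_sorted[np.clip(j, 0, len(tss_sorted) - 1)] - pos), np.inf)
        dist_l = np.where(j > 0, np.abs(tss_sorted[np.clip(j - 1, 0, None)] - pos), np.inf)
        nearest = np.where(dist_r <= dist_l, np.clip(j, 0, len(tss_sorted) - 1), np.clip(j - 1, 0, None))
        in_promoter = np.minimum(dist_r, dist_l) <= 500
        promoter_gene = np.where(in_promoter, order[nearest], -1)

        # per-site q across timepoints
        q = np.zeros((n_cg + n_ch, T))
        site_u = rng.uniform(-cfg.cg_site_jitter, cfg.cg_site_jitter, size=n_cg + n_ch)
        is_cac = (~is_cg) & (second_ch == "A") & (third == "C")
        for t in range(T):
            q[:, t] = np.where(
                is_cg, cfg.global_mcg_trajectory[t] + site_u, cfg.global_mch_trajectory[t]
            )
            # progressive mCAC predominance: baseline mCH at CAC sites is
            # scaled up linearly along the series
            cac_factor = 1.0 + (cfg.mcac_enrichment_final - 1.0) * t / max(T - 1, 1)
            q[is_cac, t] *= cac_factor
        # promoters: lowly methylated baseline; hyper subset ramps up late
        prom_sites = is_cg & in_promoter
        prom_u = rng.uniform(-cfg.promoter_site_jitter, cfg.promoter_site_jitter,
                             size=n_cg + n_ch)
        for t in range(T):
            q[prom_sites, t] = cfg.promoter_base_mcg + prom_u[prom_sites]
        prom_ids = np.array([chrom_genes[g].gene_id if g >= 0 else "" for g in promoter_gene])
        hyper_sites = prom_sites & np.isin(prom_ids, list(hyper_set))
        for t in range(T):
            if t >= 2:
                q[hyper_sites, t] += cfg.promoter_hyper_delta
        # gene-body mCH effects
        ch_body = (~is_cg) & in_body
        body_ids = np.array([chrom_genes[g].gene_id if g >= 0 else "" for g in body_gene])
        is_down_site = ch_body & np.isin(body_ids, list(labels.index[labels == "down"]))
        pct_map = dict(zip(gene_ids, pct))
        site_pct = np.array([pct_map.get(g, 0.5) for g in body_ids])
        anti = cfg.mch_expr_anticorr * (1.0 - site_pct)
        late = T - 1
        q[:, late] += np.where(ch_body, anti, 0.0)
        if T >= 3:
            q[:, late - 1] += np.where(ch_body, anti / 2, 0.0)
        q[is_down_site, late] += cfg.mch_gain_for_down
        if T >= 3:
            q[is_down_site, late - 1] += cfg.mch_gain_for_down / 2

        # DMS planting on non-promoter CG sites outside gene bodies
        eligible = np.nonzero(is_cg & ~in_promoter & ~in_body)[0]
        rng.shuffle(eligible)
        cursor = 0
        for ci, (k, count, delta) in enumerate(dms_quota):
            take = int(round(count / len(cfg.chrom_sizes)))
            chosen = eligible[cursor : cursor + take]
            cursor += take
            for t in range(T):
                q[chosen, t] = cfg.dms_high_level - (delta if t >= k else 0.0)
            for s in chosen:
                truth_dms_rows.append(
                    (chrom, int(pos[s]), strand[s], k)
                )
        q = np.clip(q, 0.0, 1.0)

        for t, tp in enumerate(cfg.timepoints):
            if cfg.fixed_coverage is not None:
                cov = np.full(n_cg + n_ch, cfg.fixed_coverage, dtype=np.int64)
            else:
                cov = rng.poisson(cfg.coverage_mean, size=n_cg + n_ch)
            qeff = q[:, t] + (1.0 - q[:, t]) * r
            mc = rng.binomial(cov, qeff)
            frames[tp].append(
                pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand,
                              "context": context, "mc": mc, "cov": cov})
            )

        # record per-gene planted final-timepoint mCH offset
        for g in chrom_genes:
            off = cfg.mch_expr_anticorr * (1.0 - pct_map[g.gene_id])
            if labels[g.gene_id] == "down":
                off += cfg.mch_gain_for_down
            gene_offset_final[g.gene_id] = off

    methylomes = {
        tp: SampleMethylome(tp, pd.concat(frames[tp], ignore_index=True))
        for tp in cfg.timepoints
    }

    # --- lambda spike-in --------------------------------------------------
    n_lam = cfg.lambda_n_ch + cfg.lambda_n_cag
    lam_pos = np.sort(rng.choice(LAMBDA_GENOME_SIZE, size=n_lam, replace=False) + 1)
    lam_is_cag = np.zeros(n_lam, dtype=bool)
    lam_is_cag[rng.choice(n_lam, size=cfg.lambda_n_cag, replace=False)] = True
    lam_ctx = np.where(
        lam_is_cag,
        rng.choice(["CAG", "CTG"], size=n_lam),
        rng.choice(["CAT", "CAA", "CAC", "CTT", "CCT", "CTA"], size=n_lam),
    )
    lam_q = np.where(lam_is_cag, cfg.lambda_cag_level, 0.0)
    if cfg.fixed_coverage is not None:
        lam_cov = np.full(n_lam, cfg.fixed_coverage, dtype=np.int64)
    else:
        lam_cov = rng.poisson(cfg.coverage_mean, size=n_lam)
    lam_mc = rng.binomial(lam_cov, lam_q + (1 - lam_q) * r)
    lambda_methylome = SampleMethylome(
        "lambda", pd.DataFrame({
            "chrom": "lambda", "pos": lam_pos,
            "strand": np.where(rng.random(n_lam) < 0.5, "+", "-"),
            "context": lam_ctx, "mc": lam_mc, "cov": lam_cov,
        }),
    )

    # --- genome, peaks, motif instances ----------------------------------
    genome = {}
    seq_arrays = {}
    for chrom, size in cfg.chrom_sizes.items():
        seq_arrays[chrom] = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=size)
    chroms = list(cfg.chrom_sizes)
    slot_w = 1000
    slots = [(c, s) for c in chroms for s in range(cfg.chrom_sizes[c] // slot_w)]
    pick = rng.permutation(len(slots))[: cfg.n_fg_peaks + cfg.n_bg_peaks]
    peak_pos = [slots[i] for i in pick]
    fg_iv, bg_iv = [], []
    motif_fg, motif_bg = [], []
    w = len(cfg.motif_consensus)
    cons = np.frombuffer(cfg.motif_consensus.encode(), dtype=np.uint8)
    for i, (chrom, s) in enumerate(peak_pos):
        start = s * slot_w + int(rng.integers(0, slot_w - cfg.peak_width))
        iv = (chrom, start, start + cfg.peak_width)
        is_fg = i < cfg.n_fg_peaks
        (fg_iv if is_fg else bg_iv).append(iv)
        rate = cfg.motif_fg_rate if is_fg else cfg.motif_bg_rate
        if rng.random() < rate:
            mstart = start + cfg.peak_width // 2 - w // 2
            seq_arrays[chrom][mstart : mstart + w] = cons
            (motif_fg if is_fg else motif_bg).append((chrom, mstart))
    genome = {c: arr.tobytes().decode() for c, arr in seq_arrays.items()}
    fg_peaks = RegionSet("foreground_peaks", fg_iv)
    bg_peaks = RegionSet("background_peaks", bg_iv)
    pwm = _consensus_pwm(cfg.motif_consensus)

    # --- ChIP-like track: elevated signal around first-class DMSs ---------
    truth_dms = pd.DataFrame(truth_dms_rows, columns=["chrom", "pos", "strand", "drop_transition"])
    expected = _expected_patterns(cfg, design)
    vcols = [f"v{i}" for i in range(1, T)]
    for i, col in enumerate(vcols):
        truth_dms[col] = [expected[k][i] for k in truth_dms["drop_transition"]]
    track_iv, track_sc = [], []
    early = truth_dms.loc[truth_dms["drop_transition"] == truth_dms["drop_transition"].min()]
    for row in early.itertuples():
        track_iv.append((row.chrom, max(row.pos - 101, 0), row.pos + 100))
        track_sc.append(5.0)
    chip_track = RegionSet("chip_track", track_iv, track_sc)

    truth = GroundTruth(
        nonconversion_rate=r,
        labels=labels,
        expression_percentile=pct,
        hyper_promoters=hyper_set,
        dms=truth_dms,
        motif_fg_instances=motif_fg,
        motif_bg_instances=motif_bg,
        gene_mch_offsets=gene_offset_final,
    )
    result = SimResult(
        cfg, design, methylomes, lambda_methylome, genes, expression, labels,
        fg_peaks, bg_peaks, genome, pwm, chip_track, truth,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def kinetic_class_from_vector(vector) -> int | None:
    """Transition (1-based) carrying the vector's unique -1, else None.

    A -1 element means an adjacent-timepoint call resolved the timing of
    demethylation; without one (or with conflicting -1s) the timing is
    unresolved and the site is excluded from the class confusion matrix.
    """
    v = np.asarray(vector, dtype=float)
    at_min = np.nonzero(np.isclose(v, -1.0))[0]
    if len(at_min) == 1:
        return int(at_min[0]) + 1
    return None


def evaluate_recovery(
    truth: GroundTruth, *, kinetics: pd.DataFrame | None = None,
    hyper_calls: pd.DataFrame | None = None, enrichment=None,
    mch_expr_r: float | None = None,
    nonconv_rate: float | None = None, lambda_cov_total: int | None = None,
) -> dict:
    """Compare pipeline outputs against the planted ground truth.

    Any subset of outputs may be supplied; each present component adds its
    section to the report.
    """
    report: dict = {}
    if kinetics is not None:
        vcols = [c for c in kinetics.columns if c.startswith("v")]
        planted = truth.dms.set_index(["chrom", "pos", "strand"])
        recovered = kinetics.index.intersection(planted.index)
        n_classes = len(vcols)
        class_names = list(range(1, n_classes + 1)) + ["unresolved"]
        confusion = pd.DataFrame(0, index=sorted(planted["drop_transition"].unique()),
                                 columns=class_names)
        for site in recovered:
            true_k = int(planted.at[site, "drop_transition"])
            got = kinetic_class_from_vector(kinetics.loc[site, vcols])
            confusion.loc[true_k, got if got is not None else "unresolved"] += 1
        resolved = confusion[list(range(1, n_classes + 1))].to_numpy()
        diag = sum(confusion.at[k, k] for k in confusion.index if k in confusion.columns)
        total_resolved = resolved.sum()
        false_sites = kinetics.index.difference(planted.index)
        report["dms"] = {
            "confusion": confusion,
            "diagonal_fraction": diag / total_resolved if total_resolved else float("nan"),
            "sensitivity": len(recovered) / len(planted) if len(planted) else float("nan"),
            "n_false_sites": int(len(false_sites)),
            "observed_fdr": len(false_sites) / max(len(kinetics), 1),
        }
    if hyper_calls is not None:
        called = set(hyper_calls.index[hyper_calls["is_hyper"]])
        tp = len(called & truth.hyper_promoters)
        report["hyper_promoters"] = {
            "recall": tp / len(truth.hyper_promoters) if truth.hyper_promoters else float("nan"),
            "precision": tp / len(called) if called else float("nan"),
            "n_called": len(called),
        }
    if enrichment is not None:
        report["motif"] = {
            res.motif_id: {"q": res.q, "direction": res.direction,
                           "detected": res.significant and res.direction == "enriched"}
            for res in enrichment
        }
    if mch_expr_r is not None:
        report["mch_expression"] = {
            "spearman_r": mch_expr_r,
            "sign_correct": mch_expr_r < 0,
        }
    if nonconv_rate is not None and lambda_cov_total:
        true_r = truth.nonconversion_rate
        se = float(np.sqrt(true_r * (1 - true_r) / lambda_cov_total))
        report["nonconversion"] = {
            "estimate": nonconv_rate, "truth": true_r, "se": se,
            "within_3se": abs(nonconv_rate - true_r) <= 3 * se,
        }
    return report
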