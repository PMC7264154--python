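"""Synthetic study generator with planted ground truth.

Generates every input shape the pipeline consumes — TSS annotation,
histone-mark consensus peaks consistent with the enhancer classification
rules, NB count matrices with planted treatment effects, distance-decaying
promoter-capture interaction counts with planted loops, LD-block
genotypes, cohort expression with planted additive eQTLs, and phenotype
panels with planted monotone associations — at desk scale (2 chromosomes
x 10 Mb, 2000 genes, 500 enhancers by default), so every stage of the
analysis is testable without any external download.

All randomness flows from one top-level seed through independent named
streams, so adding one generator call never perturbs the draws of
another. Planted treatment effects are balanced between up- and
down-regulation, matching the roughly balanced regulation observed in
stimulated myotubes and keeping library composition stable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountMatrix, DesignSpec
from .eqtl import GenotypeMatrix
from .intervals import GenomicInterval, TssRecord
from .regulatory import PeakSet, RegulatoryAnnotation, define_active_promoters, define_enhancers
from .variants import VariantRecord

__all__ = [
    "TruthBundle",
    "SyntheticStudy",
    "stream",
    "gen_annotation",
    "gen_peaks_counts",
    "gen_interactions",
    "gen_genotypes",
    "gen_cohort",
    "gen_phenotypes",
    "simulate_study",
]


def stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG: independent per (seed, name)."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (var = mu + disp*mu^2)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mean, float)))


@dataclass
class TruthBundle:
    """Planted ground truth plus the generator parameters and seed."""

    seed: int
    params: dict = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    gene_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    enhancer_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    loops: pd.DataFrame = field(default_factory=pd.DataFrame)
    cascades: pd.DataFrame = field(default_factory=pd.DataFrame)
    eqtls: pd.DataFrame = field(default_factory=pd.DataFrame)
    phenotype_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def gen_annotation(
    n_genes: int = 2000,
    n_chroms: int = 2,
    chrom_len: int = 10_000_000,
    seed: int = 0,
    min_spacing: int = 2000,
) -> tuple[list[TssRecord], dict[str, int]]:
    """Evenly spaced, jittered, non-overlapping gene TSSs with random strands."""
    if n_genes <= 0 or n_chroms <= 0 or chrom_len <= 0:
        raise ValueError("all size parameters must be positive")
    rng = stream(seed, "annotation")
    per = int(np.ceil(n_genes / n_chroms))
    spacing = chrom_len / (per + 1)
    if spacing < min_spacing:
        raise ValueError(
            f"{n_genes} genes do not fit {n_chroms} x {chrom_len} bp "
            f"at minimum spacing {min_spacing}"
        )
    chrom_sizes = {f"chr{c + 1}": chrom_len for c in range(n_chroms)}
    tss: list[TssRecord] = []
    g = 0
    for chrom in chrom_sizes:
        for i in range(per):
            if g >= n_genes:
                break
            jitter = rng.integers(-int(spacing * 0.05), int(spacing * 0.05) + 1)
            pos = int((i + 1) * spacing) + int(jitter)
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append(TssRecord(f"gene_{g:05d}", chrom, max(0, pos), strand))
            g += 1
    return tss, chrom_sizes


@dataclass
class PeaksCounts:
    """Output bundle of :func:`gen_peaks_counts`."""

    k27ac: PeakSet
    k4me1: PeakSet
    k4me3: PeakSet
    gene_counts: CountMatrix
    peak_counts: CountMatrix          # H3K27ac counts on all K27ac peaks
    design: DesignSpec
    annotation: RegulatoryAnnotation
    gene_truth: pd.DataFrame
    enhancer_truth: pd.DataFrame


def gen_peaks_counts(
    tss: list[TssRecord],
    chrom_sizes: dict[str, int],
    n_enhancers: int = 500,
    n_samples_per_group: int = 4,
    effect_log2fc: float = 2.0,
    frac_diff_genes: float = 0.10,
    frac_diff_enhancers: float = 0.20,
    dispersion: float = 0.1,
    active_promoter_frac: float = 0.8,
    enhancer_width: int = 1500,
    base_mean: float = 100.0,
    seed: int = 0,
) -> PeaksCounts:
    """Peak sets satisfying the classification rules plus NB count matrices.

    Active promoters get an H3K4me3 peak inside their window; enhancers
    are placed at midpoints between adjacent TSSs (where they cannot touch
    a promoter window) and carry both an H3K27ac and an H3K4me1 peak. A
    planted fraction of genes and enhancers receive balanced +-
    ``effect_log2fc`` treatment effects. Counts follow NB(mu, dispersion)
    with log-normal baseline means.
    """
    if effect_log2fc < 0 or not np.isfinite(effect_log2fc):
        raise ValueError("effect_log2fc must be finite and non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = stream(seed, "peaks_counts")

    # --- active promoters ------------------------------------------------
    n_genes = len(tss)
    active_mask = rng.random(n_genes) < active_promoter_frac
    k4me3_peaks = [
        (f"k4me3_{i:05d}", GenomicInterval(t.chrom, max(0, t.tss - 200), t.tss + 200))
        for i, t in enumerate(tss)
        if active_mask[i]
    ]
    k4me3 = PeakSet("H3K4me3", k4me3_peaks)
    promoters = define_active_promoters(tss, k4me3)

    # --- enhancer placement at inter-gene midpoints ----------------------
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    candidates: list[GenomicInterval] = []
    for chrom, ts in by_chrom.items():
        ts = sorted(ts, key=lambda t: t.tss)
        for a, b in zip(ts, ts[1:]):
            mid = (a.tss + b.tss) // 2
            iv_start = mid - enhancer_width // 2
            iv_end = iv_start + enhancer_width
            # keep clear of both flanking promoter windows (3 kb reach)
            if iv_start > a.tss + 3000 + 300 and iv_end < b.tss - 3000 - 300:
                candidates.append(GenomicInterval(chrom, iv_start, iv_end))
    if len(candidates) < n_enhancers:
        raise ValueError(
            f"only {len(candidates)} enhancer slots available for {n_enhancers} enhancers"
        )
    pick = np.sort(rng.choice(len(candidates), size=n_enhancers, replace=False))
    enh_ivs = [candidates[i] for i in pick]
    k27_peaks = [(f"k27_{i:05d}", iv) for i, iv in enumerate(enh_ivs)]
    k4me1_peaks = [
        (f"k4me1_{i:05d}",
         GenomicInterval(iv.chrom, max(0, iv.start - 200), iv.end + 200))
        for i, iv in enumerate(enh_ivs)
    ]
    # primed enhancers: H3K4me1-only peaks in unused slots
    unused = [i for i in range(len(candidates)) if i not in set(pick.tolist())]
    n_primed = min(len(unused), n_enhancers // 5)
    for j, ci in enumerate(unused[:n_primed]):
        iv = candidates[ci]
        k4me1_peaks.append((f"k4me1_p{j:05d}", iv))
    # promoter-overlapping H3K27ac peaks (classified out by the rules)
    active_tss = [t for i, t in enumerate(tss) if active_mask[i]]
    n_prom_peaks = min(len(active_tss), n_enhancers // 5)
    for j in range(n_prom_peaks):
        t = active_tss[j]
        k27_peaks.append(
            (f"k27_prom{j:05d}", GenomicInterval(t.chrom, max(0, t.tss - 500), t.tss + 500))
        )
    k27ac = PeakSet("H3K27ac", k27_peaks)
    k4me1 = PeakSet("H3K4me1", k4me1_peaks)
    ann = define_enhancers(k27ac, k4me1, promoters)

    # --- designed experiment ---------------------------------------------
    n = 2 * n_samples_per_group
    sample_ids = [f"ctrl_{i + 1}" for i in range(n_samples_per_group)] + [
        f"treat_{i + 1}" for i in range(n_samples_per_group)
    ]
    group = ["Control"] * n_samples_per_group + ["Treatment"] * n_samples_per_group
    block = [f"P{5 + i % 2}" for i in range(n_samples_per_group)] * 2
    design = DesignSpec(sample_ids, group, {"Treatment": 1.0, "Control": -1.0}, block=block)
    treat = np.array([g == "Treatment" for g in group])

    def _counts(ids: list[str], n_feat: int, frac_diff: float, label: str):
        base = rng.lognormal(np.log(base_mean), 1.0, n_feat)
        n_diff = int(round(frac_diff * n_feat))
        diff_idx = rng.choice(n_feat, size=n_diff, replace=False)
        lfc = np.zeros(n_feat)
        signs = np.where(np.arange(n_diff) % 2 == 0, 1.0, -1.0)
        lfc[diff_idx] = signs * effect_log2fc
        mu = np.outer(base, np.ones(n))
        mu[:, treat] *= 2.0 ** lfc[:, None]
        counts = _nb_draw(rng, mu, dispersion)
        truth = pd.DataFrame(
            {
                "feature_id": ids,
                "true_log2fc": lfc,
                "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "ns")),
            }
        )
        return CountMatrix(ids, sample_ids, counts), truth

    gene_ids = [t.gene_id for t in tss]
    gene_counts, gene_truth = _counts(gene_ids, n_genes, frac_diff_genes, "gene")
    peak_ids = [pid for pid, _ in k27_peaks]
    peak_counts, peak_truth = _counts(peak_ids, len(peak_ids), 0.0, "peak")

    # plant enhancer effects only on true enhancers (redraw their counts)
    enh_ids = [eid for eid, _ in ann.enhancers]
    n_diff = int(round(frac_diff_enhancers * len(enh_ids)))
    diff_enh = rng.choice(len(enh_ids), size=n_diff, replace=False)
    enh_lfc = pd.Series(0.0, index=enh_ids)
    signs = np.where(np.arange(n_diff) % 2 == 0, 1.0, -1.0)
    enh_lfc.iloc[diff_enh] = signs * effect_log2fc
    pos = {pid: i for i, pid in enumerate(peak_ids)}
    # planted regulated enhancers are moderately expressed: differential
    # activity is only observable on elements with appreciable signal
    for eid, lfc in enh_lfc.items():
        if lfc == 0.0:
            continue
        i = pos[eid]
        base = rng.lognormal(np.log(2 * base_mean), 0.5)
        mu = np.full(n, base)
        mu[treat] *= 2.0 ** lfc
        peak_counts.counts[i] = _nb_draw(rng, mu, dispersion)
    peak_truth["true_log2fc"] = [enh_lfc.get(p, 0.0) for p in peak_ids]
    peak_truth["direction"] = np.where(
        peak_truth["true_log2fc"] > 0, "up",
        np.where(peak_truth["true_log2fc"] < 0, "down", "ns"),
    )
    enhancer_truth = peak_truth[peak_truth["feature_id"].isin(enh_ids)].reset_index(drop=True)
    enhancer_truth = enhancer_truth.rename(columns={"feature_id": "enhancer_id"})

    return PeaksCounts(
        k27ac=k27ac, k4me1=k4me1, k4me3=k4me3,
        gene_counts=gene_counts, peak_counts=peak_counts, design=design,
        annotation=ann,
        gene_truth=gene_truth.rename(columns={"feature_id": "gene_id"}),
        enhancer_truth=enhancer_truth,
    )


def gen_interactions(
    ann: RegulatoryAnnotation,
    tss: list[TssRecord],
    n_loops: int = 50,
    loop_genes: list[tuple[str, str]] | None = None,
    decay_exponent: float = -1.0,
    loop_fold: float = 5.0,
    n_conditions: int = 3,
    n_replicates: int = 3,
    base_mean: float = 100.0,
    ref_distance: float = 50_000.0,
    max_distance: float = 2_000_000.0,
    k_per_promoter: int = 4,
    dispersion: float = 0.05,
    frac_decoy_ends: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter-capture interaction counts with distance decay and loops.

    Every captured promoter (all active promoters) is paired with up to
    ``k_per_promoter`` same-chromosome enhancers within ``max_distance``;
    background means follow ``base_mean * (d / ref_distance)**decay_exponent``
    and planted loops multiply the mean by ``loop_fold``. When
    ``loop_genes`` (gene, enhancer) pairs are given they are planted as
    loops, topped up randomly to ``n_loops``. Returns (interaction table,
    loop truth table).
    """
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    rng = stream(seed, "interactions")
    tss_by_gene = {t.gene_id: t for t in tss}
    enh_list = ann.enhancers
    enh_by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for eid, iv in enh_list:
        enh_by_chrom.setdefault(iv.chrom, []).append((eid, iv))

    rows = []
    pair_index: dict[tuple[str, str], int] = {}
    for gene, win in ann.active_promoters.items():
        t = tss_by_gene[gene]
        bait = GenomicInterval(t.chrom, max(0, t.tss - 2000), t.tss + 2000)
        cands = [
            (eid, iv)
            for eid, iv in enh_by_chrom.get(t.chrom, [])
            if 0 < abs(iv.midpoint - bait.midpoint) <= max_distance
        ]
        if not cands:
            continue
        k = min(k_per_promoter, len(cands))
        # nearer enhancers are more likely capture partners
        d = np.array([abs(iv.midpoint - bait.midpoint) for _, iv in cands], float)
        w = (d / ref_distance) ** (decay_exponent / 2)
        idx = rng.choice(len(cands), size=k, replace=False, p=w / w.sum())
        for j in np.sort(idx):
            eid, iv = cands[j]
            pair_index[(gene, eid)] = len(rows)
            rows.append((gene, bait, iv))
        if rng.random() < frac_decoy_ends:  # other end at a random locus
            start = int(rng.integers(0, max(1, bait.start + 1_000_000)))
            rows.append((gene, bait, GenomicInterval(bait.chrom, start + 1, start + 4001)))

    # loops: requested gene-enhancer pairs that exist, topped up randomly
    loop_rows: list[int] = []
    loops = []
    if loop_genes:
        for gene, eid in loop_genes:
            i = pair_index.get((gene, eid))
            if i is None:
                # force-create the pair so every requested loop exists
                t = tss_by_gene[gene]
                iv = dict(enh_list)[eid]
                bait = GenomicInterval(t.chrom, max(0, t.tss - 2000), t.tss + 2000)
                i = len(rows)
                pair_index[(gene, eid)] = i
                rows.append((gene, bait, iv))
            loop_rows.append(i)
            loops.append((gene, eid))
    remaining = [ix for key, ix in pair_index.items() if ix not in set(loop_rows)]
    n_extra = max(0, n_loops - len(loop_rows))
    if n_extra and remaining:
        extra = rng.choice(len(remaining), size=min(n_extra, len(remaining)), replace=False)
        inv = {ix: key for key, ix in pair_index.items()}
        for e in np.sort(extra):
            ix = remaining[e]
            loop_rows.append(ix)
            loops.append(inv[ix])

    n_libs = n_conditions * n_replicates
    dist = np.array(
        [abs(b.midpoint - o.midpoint) if b.chrom == o.chrom else np.inf for _, b, o in rows],
        float,
    )
    mu = base_mean * (np.maximum(dist, 1.0) / ref_distance) ** decay_exponent
    mu[~np.isfinite(dist)] = base_mean * (max_distance / ref_distance) ** decay_exponent
    mu = np.clip(mu, 1.0, 50 * base_mean)
    is_loop = np.zeros(len(rows), bool)
    is_loop[loop_rows] = True
    mu[is_loop] *= loop_fold
    counts = _nb_draw(rng, np.repeat(mu[:, None], n_libs, axis=1), dispersion)

    conds = [f"cond{c + 1}" for c in range(n_conditions) for _ in range(n_replicates)]
    table = pd.DataFrame(
        {
            "bait_gene_id": [g for g, _, _ in rows],
            "chrom1": [b.chrom for _, b, _ in rows],
            "start1": [b.start for _, b, _ in rows],
            "end1": [b.end for _, b, _ in rows],
            "chrom2": [o.chrom for _, _, o in rows],
            "start2": [o.start for _, _, o in rows],
            "end2": [o.end for _, _, o in rows],
        }
    )
    for j in range(n_libs):
        table[f"count_{conds[j]}_r{j % n_replicates + 1}"] = counts[:, j]
    loop_truth = pd.DataFrame(loops, columns=["gene_id", "enhancer_id"])
    return table, loop_truth


def gen_genotypes(
    n_individuals: int = 500,
    n_blocks: int = 60,
    snps_per_block: int = 5,
    within_block_r2: float = 0.9,
    maf_range: tuple[float, float] = (0.15, 0.5),
    block_centers: list[tuple[str, int]] | None = None,
    block_span: int = 100_000,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """LD-block genotype panel via an ancestral-haplotype copy model.

    Each block draws an ancestral haplotype pair per individual at a
    block-level MAF; every SNP in the block copies the ancestral alleles
    with a small flip probability chosen so the expected pairwise dosage
    r^2 within the block equals ``within_block_r2``; between-block r^2 is
    ~0. Returns the genotype matrix and a panel frame (rsid, chrom, pos).
    """
    if not (0 < within_block_r2 <= 1):
        raise ValueError("within_block_r2 must be in (0, 1]")
    rng = stream(seed, "genotypes")
    if block_centers is None:
        block_centers = [("chr1", int(1e6 + b * 2e5)) for b in range(n_blocks)]
    n_blocks = len(block_centers)
    snp_ids, chroms, poss = [], [], []
    dosages = np.empty((n_blocks * snps_per_block, n_individuals))

    def _flip_eps(p: float) -> float:
        """Flip probability giving expected pairwise allele r^2 == target."""
        from scipy.optimize import brentq

        def corr2(e: float) -> float:
            ps = p * (1 - e) + (1 - p) * e
            cov = p * (1 - e) ** 2 + (1 - p) * e**2 - ps * ps
            return (cov / (ps * (1 - ps))) ** 2 - within_block_r2

        if within_block_r2 >= 1.0:
            return 0.0
        return brentq(corr2, 0.0, 0.49)

    for b, (chrom, center) in enumerate(block_centers):
        maf = rng.uniform(*maf_range)
        eps = _flip_eps(maf)
        anc = (rng.random((2, n_individuals)) < maf).astype(int)
        offs = np.linspace(-block_span // 2, block_span // 2, snps_per_block).astype(int)
        for s in range(snps_per_block):
            flips = rng.random((2, n_individuals)) < eps
            hap = np.where(flips, 1 - anc, anc)
            row = b * snps_per_block + s
            dosages[row] = hap.sum(axis=0)
            snp_ids.append(f"rs{b:03d}_{s}")
            chroms.append(chrom)
            poss.append(max(0, int(center + offs[s])))
    imp_r2 = rng.uniform(0.5, 1.0, len(snp_ids))
    gm = GenotypeMatrix(
        snp_ids, [f"ind_{i:04d}" for i in range(n_individuals)], dosages, imp_r2
    )
    panel = pd.DataFrame({"rsid": snp_ids, "chrom": chroms, "pos": poss})
    return gm, panel


def gen_cohort(
    gene_ids: list[str],
    gm: GenotypeMatrix,
    planted_eqtls: pd.DataFrame,
    n_individuals: int = 140,
    n_latent: int = 3,
    latent_sd: float = 0.5,
    age_effect: float = 0.3,
    group_effect: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort expression with planted additive eQTLs.

    Expression (genes x individuals) = age + group + latent-factor
    structure + beta * dosage (for planted (snp, gene, beta) rows) + N(0,1)
    noise; beta is therefore in noise-sd units per allele. The cohort is
    the first ``n_individuals`` columns of the genotype panel. Returns
    (expression, covariates, eqtl truth).
    """
    missing = set(planted_eqtls["snp"]) - set(gm.snp_ids)
    if missing:
        raise ValueError(f"planted eQTL SNPs absent from genotypes: {sorted(missing)[:5]}")
    if n_individuals > len(gm.individual_ids):
        raise ValueError("cohort larger than genotype panel")
    rng = stream(seed, "cohort")
    inds = gm.individual_ids[:n_individuals]
    age = rng.normal(45.0, 8.0, n_individuals)
    group = (rng.random(n_individuals) < 0.5).astype(float)
    latent = rng.standard_normal((n_latent, n_individuals))
    loadings = rng.normal(0.0, latent_sd, (len(gene_ids), n_latent))
    age_z = (age - age.mean()) / age.std()
    expr = (
        age_effect * age_z[None, :]
        + group_effect * group[None, :]
        + loadings @ latent
        + rng.standard_normal((len(gene_ids), n_individuals))
    )
    snp_row = {s: i for i, s in enumerate(gm.snp_ids)}
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    for snp, gene, beta in planted_eqtls[["snp", "gene", "beta"]].itertuples(index=False):
        if gene not in gene_row:
            continue
        dos = np.nan_to_num(gm.dosages[snp_row[snp], :n_individuals], nan=0.0)
        expr[gene_row[gene]] += beta * dos
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=inds)
    cov_df = pd.DataFrame({"age": age, "group": group}, index=inds)
    return expr_df, cov_df, planted_eqtls.copy()


def gen_phenotypes(
    expr_genes: list[str],
    n_strains: int = 40,
    n_phenotypes: int = 48,
    planted: pd.DataFrame | None = None,
    group: str = "CD_muscle",
    missing_frac: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Strain phenotype panel with planted Spearman associations.

    For each planted (gene, phenotype, rho) the phenotype is drawn from a
    Gaussian copula with latent Pearson correlation 2 sin(pi rho / 6), so
    the target Spearman correlation is achieved up to sampling error.
    Missing values are injected at ``missing_frac``. Returns
    (expression genes x strains, phenotype strains x phenotypes, truth).
    """
    planted = (
        pd.DataFrame(columns=["gene", "phenotype", "rho"]) if planted is None else planted
    )
    if (planted["rho"].abs() >= 1).any():
        raise ValueError("target |rho| must be < 1")
    rng = stream(seed, "phenotypes")
    strains = [f"BXD{i + 1:03d}" for i in range(n_strains)]
    phenos = [f"pheno_{j + 1:02d}" for j in range(n_phenotypes)]
    expr = pd.DataFrame(
        rng.standard_normal((len(expr_genes), n_strains)), index=expr_genes, columns=strains
    )
    panel = pd.DataFrame(
        rng.standard_normal((n_strains, n_phenotypes)), index=strains, columns=phenos
    )
    for gene, pheno, rho in planted[["gene", "phenotype", "rho"]].itertuples(index=False):
        if gene not in expr.index or pheno not in panel.columns:
            raise ValueError(f"planted association references unknown {gene}/{pheno}")
        r = 2 * np.sin(np.pi * rho / 6)
        g = expr.loc[gene].to_numpy()
        panel[pheno] = r * g + np.sqrt(1 - r * r) * rng.standard_normal(n_strains)
    if missing_frac > 0:
        mask = rng.random(panel.shape) < missing_frac
        panel = panel.mask(mask)
    truth = planted.copy()
    truth["group"] = group
    return expr, panel, truth


@dataclass
class SyntheticStudy:
    """All pipeline inputs for one simulated study, with planted truth."""

    tss: list[TssRecord]
    chrom_sizes: dict[str, int]
    peaks: PeaksCounts
    interactions: pd.DataFrame
    interaction_design: DesignSpec
    index_snps: list[VariantRecord]
    panel: pd.DataFrame
    panel_genotypes: GenotypeMatrix
    cohort_expression: pd.DataFrame
    cohort_covariates: pd.DataFrame
    phenotype_expression: pd.DataFrame
    phenotype_panel: pd.DataFrame
    truth: TruthBundle


def simulate_study(
    seed: int = 0,
    n_genes: int = 2000,
    n_chroms: int = 2,
    chrom_len: int = 10_000_000,
    n_enhancers: int = 500,
    n_samples_per_group: int = 4,
    n_cascades: int = 50,
    effect_log2fc: float = 2.0,
    cascade_log2fc: float = 3.0,
    eqtl_beta: float = 1.0,
    n_panel: int = 500,
    n_cohort: int = 140,
    n_strains: int = 40,
    pheno_rho: float = 0.6,
) -> SyntheticStudy:
    """Full desk-scale study with ``n_cascades`` planted
    SNP -> enhancer -> loop -> gene cascades.

    Each cascade is a differentially active enhancer harbouring a causal
    SNP (tagged by a GWAS index SNP in its LD block), looped to the
    promoter of a gene regulated in the same direction, with a planted
    additive eQTL in the cohort. Cascade enhancers and genes carry strong
    effects (``cascade_log2fc``, 8-fold by default, emulating validated
    stimulus-responsive enhancer loci) on moderately expressed baselines;
    decoy differential features elsewhere use ``effect_log2fc``. Decoy
    structure (differential features without cascades, index SNPs in
    unregulated enhancers, background interactions) is generated
    alongside.
    """
    tss, chrom_sizes = gen_annotation(n_genes, n_chroms, chrom_len, seed=seed)
    pk = gen_peaks_counts(
        tss, chrom_sizes, n_enhancers=n_enhancers,
        n_samples_per_group=n_samples_per_group, effect_log2fc=effect_log2fc,
        seed=seed,
    )
    ann = pk.annotation
    rng = stream(seed, "cascades")

    # cascade enhancers: differential enhancers looped to a nearby gene
    # whose planted direction matches the enhancer's.
    enh_by_id = dict(ann.enhancers)
    diff_enh = pk.enhancer_truth[pk.enhancer_truth["direction"] != "ns"]
    tss_by_gene = {t.gene_id: t for t in tss}
    gene_dir = pk.gene_truth.set_index("gene_id")["direction"]
    cascades = []
    used_genes: set[str] = set()
    order = rng.permutation(len(diff_enh))
    for i in order:
        if len(cascades) >= n_cascades:
            break
        row = diff_enh.iloc[i]
        eid, edir = row["enhancer_id"], row["direction"]
        iv = enh_by_id[eid]
        # nearest captured promoters within 1 Mb whose gene we can regulate
        near = [
            (abs(tss_by_gene[g].tss - iv.midpoint), g)
            for g in ann.active_promoters
            if tss_by_gene[g].chrom == iv.chrom
            and abs(tss_by_gene[g].tss - iv.midpoint) <= 1_000_000
            and g not in used_genes
        ]
        if not near:
            continue
        near.sort()
        gene = near[int(rng.integers(0, min(5, len(near))))][1]
        used_genes.add(gene)
        cascades.append({"enhancer_id": eid, "gene_id": gene, "direction": edir})
    if len(cascades) < n_cascades:
        raise ValueError(f"could only place {len(cascades)} of {n_cascades} cascades")

    # replant cascade genes and enhancers with strong, concordant effects
    # on moderately-expressed baselines (the study's validated linked
    # targets are active genes with multi-fold responses)
    treat = np.array([g == "Treatment" for g in pk.design.group])
    n = len(pk.design.sample_ids)
    gpos = {g: i for i, g in enumerate(pk.gene_counts.feature_ids)}
    ppos = {p: i for i, p in enumerate(pk.peak_counts.feature_ids)}
    rng_counts = stream(seed, "cascade_counts")
    for c in cascades:
        lfc = cascade_log2fc if c["direction"] == "up" else -cascade_log2fc
        for cm_, row, truth_df, key_col, key in (
            (pk.gene_counts, gpos[c["gene_id"]], pk.gene_truth, "gene_id", c["gene_id"]),
            (pk.peak_counts, ppos[c["enhancer_id"]], pk.enhancer_truth, "enhancer_id",
             c["enhancer_id"]),
        ):
            base = rng_counts.lognormal(np.log(200.0), 0.5)
            mu = np.full(n, base)
            mu[treat] *= 2.0 ** lfc
            cm_.counts[row] = _nb_draw(rng_counts, mu, 0.1)
            truth_df.loc[truth_df[key_col] == key,
                         ["true_log2fc", "direction"]] = [lfc, c["direction"]]
    gene_dir = pk.gene_truth.set_index("gene_id")["direction"]

    # interactions with cascade loops planted
    loop_genes = [(c["gene_id"], c["enhancer_id"]) for c in cascades]
    # cascade loops plus random loops (mostly to unregulated enhancers),
    # so connected promoters populate the Up/Down/None groups
    inter, loop_truth = gen_interactions(
        ann, tss, n_loops=len(loop_genes) + 150, loop_genes=loop_genes, seed=seed
    )
    from .interactions import count_columns

    ccols = count_columns(inter)
    cond = [c.split("_")[1] for c in ccols]
    inter_design = DesignSpec(
        ccols, cond, {"cond2": 1.0, "cond1": -1.0}, block=None
    )

    # genotypes: one LD block per cascade enhancer plus decoy blocks
    block_centers = [(enh_by_id[c["enhancer_id"]].chrom, enh_by_id[c["enhancer_id"]].midpoint)
                     for c in cascades]
    n_decoy_blocks = 10
    decoy_enh = [eid for eid, _ in ann.enhancers
                 if eid not in {c["enhancer_id"] for c in cascades}]
    decoy_pick = rng.choice(len(decoy_enh), size=n_decoy_blocks, replace=False)
    for j in np.sort(decoy_pick):
        iv = enh_by_id[decoy_enh[j]]
        block_centers.append((iv.chrom, iv.midpoint))
    gm, panel = gen_genotypes(
        n_individuals=n_panel, snps_per_block=5, block_centers=block_centers, seed=seed
    )
    # middle SNP of each block sits at the block center == enhancer midpoint,
    # hence inside the (>=1.5 kb wide) enhancer; it is the causal SNP.
    traits = ["T2D", "IR", "BMI", "WHR"]
    index_snps: list[VariantRecord] = []
    causal = []
    for b, c in enumerate(cascades):
        mid_snp = f"rs{b:03d}_2"
        idx_snp = f"rs{b:03d}_0"
        trait = traits[b % 4]
        pos = int(panel.loc[panel["rsid"] == idx_snp, "pos"].iloc[0])
        chrom = str(panel.loc[panel["rsid"] == idx_snp, "chrom"].iloc[0])
        index_snps.append(VariantRecord(idx_snp, chrom, pos, trait))
        causal.append({"rsid": mid_snp, **c, "trait": trait, "index_rsid": idx_snp})
    for jb in range(len(cascades), len(block_centers)):
        idx_snp = f"rs{jb:03d}_0"
        pos = int(panel.loc[panel["rsid"] == idx_snp, "pos"].iloc[0])
        chrom = str(panel.loc[panel["rsid"] == idx_snp, "chrom"].iloc[0])
        index_snps.append(VariantRecord(idx_snp, chrom, pos, traits[jb % 4]))

    # cohort: cascade genes plus decoy genes, eQTLs planted at causal SNPs
    decoy_genes = [g for g in gene_dir.index if g not in used_genes][:50]
    cohort_genes = [c["gene_id"] for c in cascades] + list(decoy_genes)
    eqtl_truth = pd.DataFrame(
        {
            "snp": [c["rsid"] for c in causal],
            "gene": [c["gene_id"] for c in causal],
            "beta": eqtl_beta,
        }
    )
    expr, cov, _ = gen_cohort(cohort_genes, gm, eqtl_truth, n_individuals=n_cohort, seed=seed)

    # phenotype panel for the cascade genes
    pheno_genes = cohort_genes[: min(13, len(cohort_genes))]
    planted_ph = pd.DataFrame(
        {
            "gene": pheno_genes,
            "phenotype": [f"pheno_{j + 1:02d}" for j in range(len(pheno_genes))],
            "rho": pheno_rho,
        }
    )
    ph_expr, ph_panel, ph_truth = gen_phenotypes(
        pheno_genes, n_strains=n_strains, planted=planted_ph, seed=seed
    )

    truth = TruthBundle(
        seed=seed,
        params={
            "n_genes": n_genes, "n_chroms": n_chroms, "chrom_len": chrom_len,
            "n_enhancers": n_enhancers, "n_samples_per_group": n_samples_per_group,
            "n_cascades": n_cascades, "effect_log2fc": effect_log2fc,
            "eqtl_beta": eqtl_beta, "n_panel": n_panel, "n_cohort": n_cohort,
            "n_strains": n_strains, "pheno_rho": pheno_rho,
        },
        chrom_sizes=chrom_sizes,
        gene_truth=pk.gene_truth,
        enhancer_truth=pk.enhancer_truth,
        loops=loop_truth,
        cascades=pd.DataFrame(causal),
        eqtls=eqtl_truth,
        phenotype_truth=ph_truth,
    )
    return SyntheticStudy(
        tss=tss, chrom_sizes=chrom_sizes, peaks=pk,
        interactions=inter, interaction_design=inter_design,
        index_snps=index_snps, panel=panel, panel_genotypes=gm,
        cohort_expression=expr, cohort_covariates=cov,
        phenotype_expression=ph_expr, phenotype_panel=ph_panel,
        truth=truth,
    )
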