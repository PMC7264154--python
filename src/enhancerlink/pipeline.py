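"""Stage orchestration: annotation -> differential -> interactions ->
variant linking -> eQTL -> phenotype correlation.

Each stage reads the previous stages' tables from the output directory,
so stages can also be run individually. A run manifest records package
version, seed, a config hash and per-stage record counts; identical
config + seed reruns produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .counts import tmm_factors
from .differential import DifferentialResult, leading_logfc_distances, nb_differential
from . import interactions as ix
from .eqtl import CovariateSet, hidden_factors, hierarchical_correct, int_residuals, snp_qc, test_pairs
from .phenotypes import PhenotypePanel, panel_correlate
from .variants import ld_expand, link_targets, links_frame, overlap_snps_enhancers

logger = logging.getLogger(__name__)

STAGES = ("annotate", "diff", "interactions", "link", "eqtl", "phenocorr")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _timed(manifest: dict, stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.setdefault("stages", {}).setdefault(stage, {})[
                "seconds"] = round(time.perf_counter() - self.t0, 3)
            return False

    return _Ctx()


def _record(manifest: dict, stage: str, **counts) -> None:
    manifest.setdefault("stages", {}).setdefault(stage, {}).update(counts)
    for k, v in counts.items():
        logger.info("[%s] %s = %s", stage, k, v)


def _diff_table(res: DifferentialResult, path: Path) -> None:
    res.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _read_diff(path: Path, alpha: float) -> DifferentialResult:
    return DifferentialResult(pd.read_csv(path, sep="\t"), alpha)


def stage_annotate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    tss = io.read_tss(cfg.path("tss"))
    k27 = io.read_peaks(cfg.path("k27ac_peaks"), "H3K27ac")
    k4m1 = io.read_peaks(cfg.path("k4me1_peaks"), "H3K4me1")
    k4m3 = io.read_peaks(cfg.path("k4me3_peaks"), "H3K4me3")
    from .regulatory import define_active_promoters, define_enhancers

    promoters = define_active_promoters(tss, k4m3, cfg.promoter_up, cfg.promoter_down)
    ann = define_enhancers(k27, k4m1, promoters, cfg.promoter_up, cfg.promoter_down)
    io.write_annotation_bed(ann, out / "enhancers.bed", out / "promoters.bed")
    _record(manifest, "annotate", active_promoters=len(ann.active_promoters),
            enhancers=len(ann.enhancers), primed=len(ann.primed))


def stage_diff(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    design = io.read_design(cfg.path("design"), cfg.contrast)
    gcm = io.read_counts(cfg.path("gene_counts"))
    pcm = io.read_counts(cfg.path("peak_counts"))
    ann = io.read_annotation_bed(out / "enhancers.bed", out / "promoters.bed")
    enh_ids = {eid for eid, _ in ann.enhancers}

    gres = nb_differential(gcm, design, tmm_factors(gcm), alpha=cfg.de_fdr)
    _diff_table(gres, out / "genes_diff.tsv")
    pres = nb_differential(pcm, design, tmm_factors(pcm), alpha=cfg.de_fdr)
    eres = DifferentialResult(
        pres.table[pres.table["feature_id"].isin(enh_ids)].reset_index(drop=True),
        cfg.de_fdr,
    )
    _diff_table(eres, out / "enhancers_diff.tsv")
    _, coords = leading_logfc_distances(gcm, tmm_factors(gcm), top_k=min(
        cfg.mds_top_k, len(gcm.feature_ids)))
    pd.DataFrame(coords, index=gcm.sample_ids, columns=["dim1", "dim2"]).rename_axis(
        "sample_id").to_csv(out / "mds_genes.tsv", sep="\t", float_format="%.6g")
    _record(manifest, "diff",
            de_genes=int((gres.table["direction"] != "ns").sum()),
            de_enhancers=int((eres.table["direction"] != "ns").sum()))


def stage_interactions(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    inter = io.read_interactions(cfg.path("interactions"))
    ann = io.read_annotation_bed(out / "enhancers.bed", out / "promoters.bed")
    pairs = ix.extract_promoter_enhancer_pairs(inter, ann, widen=cfg.widen)
    trend = ix.fit_distance_trend(pairs)
    kept = ix.filter_interactions(pairs, trend, cfg.min_ave_cpm, cfg.min_fold)
    io.write_interactions(kept, out / "interactions_kept.tsv")

    idesign = io.read_design(cfg.path("interaction_design"), cfg.interaction_contrast)
    ires = ix.differential_interactions(pairs, idesign, alpha=cfg.interaction_fdr,
                                        min_ave_cpm=cfg.min_ave_cpm)
    ires.table.to_csv(out / "interactions_diff.tsv", sep="\t", index=False,
                      float_format="%.6g")

    eres = _read_diff(out / "enhancers_diff.tsv", cfg.de_fdr)
    groups = ix.assign_promoter_groups(kept, eres)
    groups.to_csv(out / "promoter_groups.tsv", sep="\t", index=False)
    gres = _read_diff(out / "genes_diff.tsv", cfg.de_fdr)
    logfc = gres.table.set_index("feature_id")["logFC"]
    try:
        ks = ix.ecdf_ks_compare(groups, logfc)
        ks.to_csv(out / "ks_tests.tsv", sep="\t", index=False, float_format="%.6g")
    except ValueError as exc:
        logger.warning("KS comparison skipped: %s", exc)
    stats = ix.interaction_stats(kept, ann)
    _record(manifest, "interactions", pairs_extracted=len(pairs), pairs_kept=len(kept),
            **{k: round(float(v), 4) for k, v in stats.items()})


def _read_genotypes(cfg: PipelineConfig):
    path = cfg.path("genotypes")
    if path.suffix == ".vcf" or str(path).endswith(".vcf.gz"):
        return io.read_vcf(path)
    return io.read_dosage_tsv(path)


def stage_link(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    index_snps = io.read_index_snps(cfg.path("index_snps"))
    gm, panel = _read_genotypes(cfg)
    snps = ld_expand(index_snps, panel, gm.dosages, window=cfg.ld_window,
                     r2_min=cfg.ld_r2)
    ann = io.read_annotation_bed(out / "enhancers.bed", out / "promoters.bed")
    eres = _read_diff(out / "enhancers_diff.tsv", cfg.de_fdr)
    overlaps = overlap_snps_enhancers(snps, eres, ann, treatment=cfg.treatment,
                                      alpha=cfg.de_fdr)
    kept = io.read_interactions(out / "interactions_kept.tsv")
    gres = _read_diff(out / "genes_diff.tsv", cfg.de_fdr)
    links = link_targets(overlaps, kept, gres, snps=snps, treatment=cfg.treatment)
    links_frame(links).to_csv(out / "target_links.tsv", sep="\t", index=False,
                              float_format="%.6g")
    _record(manifest, "link", snps_after_ld=len(snps),
            snp_bearing_enhancers=int(overlaps["enhancer_id"].nunique()) if len(overlaps) else 0,
            target_links=len(links))


def stage_eqtl(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    links = pd.read_csv(out / "target_links.tsv", sep="\t")
    expr = io.read_matrix_tsv(cfg.path("cohort_expression"))
    cov_df = io.read_matrix_tsv(cfg.path("cohort_covariates"))
    gm, _ = _read_genotypes(cfg)
    cohort = [i for i in expr.columns if i in set(gm.individual_ids)]
    col_idx = [gm.individual_ids.index(i) for i in cohort]
    from .eqtl import GenotypeMatrix

    gm_c = GenotypeMatrix(gm.snp_ids, cohort, gm.dosages[:, col_idx], gm.imputation_r2)
    gm_c = snp_qc(gm_c, cfg.max_missing, cfg.min_imp_r2, cfg.hwe_alpha)
    expr = expr[cohort]
    known = cov_df.loc[cohort]
    if not cfg.adjust_group and "group" in known.columns:
        known = known.drop(columns=["group"])
    cov = CovariateSet(cohort, known)
    cov.factors = hidden_factors(expr.to_numpy(float), cov, k=cfg.hidden_k)
    transformed = int_residuals(expr.to_numpy(float), cov)
    pairs = (links.rename(columns={"rsid": "snp", "gene_id": "gene"})
             [["snp", "gene"]].drop_duplicates().reset_index(drop=True))
    pair_res = test_pairs(pairs, gm_c, transformed, list(expr.index))
    res = hierarchical_correct(pair_res, fdr=cfg.eqtl_fdr)
    res.pairs.to_csv(out / "eqtl_pairs.tsv", sep="\t", index=False, float_format="%.6g")
    res.genes.to_csv(out / "egenes.tsv", sep="\t", index=False, float_format="%.6g")
    _record(manifest, "eqtl", pairs_tested=int(res.pairs["testable"].sum()),
            egenes=int(res.genes["egene"].sum()) if len(res.genes) else 0)


def stage_phenocorr(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    expr = io.read_matrix_tsv(cfg.path("phenotype_expression"))
    ph = io.read_matrix_tsv(cfg.path("phenotype_panel"))
    panel = PhenotypePanel(list(ph.index), list(ph.columns), ph, cfg.phenotype_group)
    table = panel_correlate(expr, [panel])
    table.to_csv(out / "phenotype_correlations.tsv", sep="\t", index=False,
                 float_format="%.6g")
    _record(manifest, "phenocorr", correlations=len(table),
            significant=int((table["fdr"] < 0.05).sum()))


_STAGE_FN = {
    "annotate": stage_annotate,
    "diff": stage_diff,
    "interactions": stage_interactions,
    "link": stage_link,
    "eqtl": stage_eqtl,
    "phenocorr": stage_phenocorr,
}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order, writing tables and a manifest.

    A stage failure aborts the run with the stage name; tables written by
    earlier stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from importlib.metadata import version

    try:
        ver = version("enhancerlink")
    except Exception:
        ver = "unknown"
    cfg_repr = json.dumps(cfg.__dict__, sort_keys=True, default=str)
    manifest: dict = {
        "package_version": ver,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "stages": {},
    }
    for stage in stages:
        with _timed(manifest, stage):
            try:
                _STAGE_FN[stage](cfg, out, manifest)
            except Exception as exc:  # abort, keep partial outputs
                manifest["failed_stage"] = stage
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise StageError(stage, exc) from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def write_study(study, input_dir: str | Path) -> dict[str, str]:
    """Write a :class:`~enhancerlink.synthetic.SyntheticStudy` to disk in
    the pipeline's input formats; returns the config path mapping."""
    d = Path(input_dir)
    d.mkdir(parents=True, exist_ok=True)
    io.write_tss(study.tss, d / "tss.bed")
    io.write_peaks(study.peaks.k27ac, d / "k27ac_peaks.bed")
    io.write_peaks(study.peaks.k4me1, d / "k4me1_peaks.bed")
    io.write_peaks(study.peaks.k4me3, d / "k4me3_peaks.bed")
    io.write_counts(study.peaks.gene_counts, d / "gene_counts.tsv")
    io.write_counts(study.peaks.peak_counts, d / "peak_counts.tsv")
    io.write_design(study.peaks.design, d / "design.tsv")
    io.write_interactions(study.interactions, d / "interactions.tsv")
    io.write_design(study.interaction_design, d / "interaction_design.tsv")
    io.write_index_snps(study.index_snps, d / "index_snps.tsv")
    io.write_dosage_tsv(study.panel_genotypes, study.panel, d / "genotypes.tsv")
    io.write_matrix_tsv(study.cohort_expression, d / "cohort_expression.tsv", "gene_id")
    io.write_matrix_tsv(study.cohort_covariates, d / "cohort_covariates.tsv", "individual")
    io.write_matrix_tsv(study.phenotype_expression, d / "phenotype_expression.tsv", "gene_id")
    io.write_matrix_tsv(study.phenotype_panel, d / "phenotype_panel.tsv", "strain")
    io.write_truth(study.truth, d / "truth.json")
    return {
        "tss": str(d / "tss.bed"),
        "k27ac_peaks": str(d / "k27ac_peaks.bed"),
        "k4me1_peaks": str(d / "k4me1_peaks.bed"),
        "k4me3_peaks": str(d / "k4me3_peaks.bed"),
        "gene_counts": str(d / "gene_counts.tsv"),
        "peak_counts": str(d / "peak_counts.tsv"),
        "design": str(d / "design.tsv"),
        "interactions": str(d / "interactions.tsv"),
        "interaction_design": str(d / "interaction_design.tsv"),
        "index_snps": str(d / "index_snps.tsv"),
        "genotypes": str(d / "genotypes.tsv"),
        "cohort_expression": str(d / "cohort_expression.tsv"),
        "cohort_covariates": str(d / "cohort_covariates.tsv"),
        "phenotype_expression": str(d / "phenotype_expression.tsv"),
        "phenotype_panel": str(d / "phenotype_panel.tsv"),
    }
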