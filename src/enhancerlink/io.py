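"""Readers and writers for the pipeline's on-disk formats.

All genomic text formats follow BED conventions (0-based, half-open,
tab-separated). Peaks are BED3+/narrowPeak (extra columns preserved as
metadata), TSS annotations are BED6 with the gene id in the name column,
interactions are BEDPE-plus TSV with one count column per library, and
genotypes come from a VCF (DS preferred, GT fallback; parsed with cyvcf2)
or a TSV dosage matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix, DesignSpec
from .eqtl import GenotypeMatrix
from .intervals import GenomicInterval, TssRecord
from .regulatory import PeakSet, RegulatoryAnnotation
from .variants import VariantRecord

NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                   "signalValue", "pValue", "qValue", "peak"]


# --------------------------------------------------------------------------
# peaks and TSS

def read_peaks(path: str | Path, mark: str) -> PeakSet:
    """BED3+/narrowPeak consensus peaks for one histone mark."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns=dict(enumerate(NARROWPEAK_COLS[: df.shape[1]])))
    names = (
        df["name"].astype(str)
        if "name" in df.columns and not (df["name"] == ".").all()
        else pd.Series([f"{mark}_{i}" for i in range(len(df))])
    )
    peaks = [
        (str(n), GenomicInterval(str(c), int(s), int(e)))
        for n, c, s, e in zip(names, df["chrom"], df["start"], df["end"])
    ]
    return PeakSet(mark, peaks)


def write_peaks(ps: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, iv in ps.peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pid}\n")


def read_tss(path: str | Path) -> list[TssRecord]:
    """BED6 TSS annotation: the interval start is the TSS, name = gene id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [
        TssRecord(str(r.name), str(r.chrom), int(r.start), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def write_tss(tss: list[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tss:
            fh.write(f"{t.chrom}\t{t.tss}\t{t.tss + 1}\t{t.gene_id}\t0\t{t.strand}\n")


def write_annotation_bed(ann: RegulatoryAnnotation, enhancers_path: str | Path,
                         promoters_path: str | Path) -> None:
    """Enhancers (active + primed) and promoter windows as BED with the
    state carried in the name column."""
    with open(enhancers_path, "w") as fh:
        for eid, iv in ann.enhancers:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{eid}|active\n")
        for eid, iv in ann.primed:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{eid}|primed\n")
    with open(promoters_path, "w") as fh:
        for gene, iv in ann.active_promoters.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}|active_promoter\n")


def read_annotation_bed(enhancers_path: str | Path,
                        promoters_path: str | Path) -> RegulatoryAnnotation:
    enh, primed = [], []
    for line in Path(enhancers_path).read_text().splitlines():
        chrom, start, end, name = line.split("\t")
        eid, state = name.rsplit("|", 1)
        iv = GenomicInterval(chrom, int(start), int(end))
        (enh if state == "active" else primed).append((eid, iv))
    promoters = {}
    for line in Path(promoters_path).read_text().splitlines():
        chrom, start, end, name = line.split("\t")
        gene = name.rsplit("|", 1)[0]
        promoters[gene] = GenomicInterval(chrom, int(start), int(end))
    return RegulatoryAnnotation(active_promoters=promoters, enhancers=enh, primed=primed)


# --------------------------------------------------------------------------
# count matrices and designs

def read_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(list(df.index.astype(str)), list(df.columns), df.to_numpy())


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().rename_axis("feature_id").to_csv(path, sep="\t")


def read_design(path: str | Path, contrast: dict[str, float]) -> DesignSpec:
    """Design TSV with columns sample_id, group and optional block."""
    df = pd.read_csv(path, sep="\t")
    block = list(df["block"].astype(str)) if "block" in df.columns else None
    return DesignSpec(list(df["sample_id"].astype(str)), list(df["group"].astype(str)),
                      contrast, block=block)


def write_design(design: DesignSpec, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": design.sample_ids, "group": design.group})
    if design.block is not None:
        df["block"] = design.block
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# interactions

def read_interactions(path: str | Path) -> pd.DataFrame:
    """BEDPE-plus TSV: bait fragment, other end, bait gene, count columns."""
    return pd.read_csv(path, sep="\t")


def write_interactions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# variants and genotypes

def read_index_snps(path: str | Path) -> list[VariantRecord]:
    """Index SNP TSV with columns rsid, chrom, pos, trait."""
    df = pd.read_csv(path, sep="\t")
    return [
        VariantRecord(str(r.rsid), str(r.chrom), int(r.pos), str(r.trait))
        for r in df.itertuples(index=False)
    ]


def write_index_snps(snps: list[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"rsid": [s.rsid for s in snps], "chrom": [s.chrom for s in snps],
         "pos": [s.pos for s in snps], "trait": [s.trait for s in snps]}
    ).to_csv(path, sep="\t", index=False)


def write_vcf(gm: GenotypeMatrix, panel: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT and DS fields from a dosage matrix.

    Hard genotypes are rounded dosages; REF/ALT are placeholder alleles.
    Imputation R2 goes in the INFO field when available.
    """
    pos_by_rsid = panel.set_index("rsid")
    order = sorted(range(len(gm.snp_ids)),
                   key=lambda i: (str(pos_by_rsid.loc[gm.snp_ids[i], "chrom"]),
                                  int(pos_by_rsid.loc[gm.snp_ids[i], "pos"])))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(panel["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individual_ids) + "\n")
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i in order:
            rsid = gm.snp_ids[i]
            chrom = str(pos_by_rsid.loc[rsid, "chrom"])
            pos = int(pos_by_rsid.loc[rsid, "pos"])
            info = (f"R2={gm.imputation_r2[i]:.4f}"
                    if gm.imputation_r2 is not None else ".")
            fields = []
            for d in gm.dosages[i]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gts[int(round(d))]}:{d:.3f}")
            fh.write(f"{chrom}\t{pos + 1}\t{rsid}\tA\tG\t.\tPASS\t{info}\tGT:DS\t"
                     + "\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes from VCF via cyvcf2 (DS preferred, GT fallback)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    snp_ids, chroms, poss, rows, imp = [], [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # back to 0-based
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, float).reshape(-1)
        else:
            gt = np.asarray(var.gt_types, float)  # 0,1,3=hom-alt, 2=unknown
            row = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        row = np.where(np.isfinite(row) & (row >= 0), row, np.nan)
        rows.append(np.clip(row, 0, 2))
        r2 = var.INFO.get("R2")
        imp.append(float(r2) if r2 is not None else np.nan)
    imp_arr = np.asarray(imp)
    gm = GenotypeMatrix(
        snp_ids, individuals, np.vstack(rows),
        None if np.all(np.isnan(imp_arr)) else imp_arr,
    )
    panel = pd.DataFrame({"rsid": snp_ids, "chrom": chroms, "pos": poss})
    return gm, panel


def read_dosage_tsv(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Dosage TSV: columns rsid, chrom, pos, imp_r2?, then one per individual."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in ("rsid", "chrom", "pos", "imp_r2") if c in df.columns]
    ind_cols = [c for c in df.columns if c not in meta_cols]
    gm = GenotypeMatrix(
        list(df["rsid"].astype(str)), ind_cols, df[ind_cols].to_numpy(float),
        df["imp_r2"].to_numpy(float) if "imp_r2" in df.columns else None,
    )
    panel = df[["rsid", "chrom", "pos"]].copy()
    return gm, panel


def write_dosage_tsv(gm: GenotypeMatrix, panel: pd.DataFrame, path: str | Path) -> None:
    df = panel[["rsid", "chrom", "pos"]].copy()
    if gm.imputation_r2 is not None:
        df["imp_r2"] = gm.imputation_r2
    dos = pd.DataFrame(gm.dosages, columns=gm.individual_ids)
    pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# tables and truth

def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    df.rename_axis(index_name).to_csv(path, sep="\t")


def write_truth(truth, path: str | Path) -> None:
    """Truth bundle as JSON (frames become records)."""
    payload = {"seed": truth.seed, "params": truth.params,
               "chrom_sizes": truth.chrom_sizes}
    for name in ("gene_truth", "enhancer_truth", "loops", "cascades",
                 "eqtls", "phenotype_truth"):
        payload[name] = getattr(truth, name).to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path):
    from .synthetic import TruthBundle

    payload = json.loads(Path(path).read_text())
    frames = {
        name: pd.DataFrame(payload[name])
        for name in ("gene_truth", "enhancer_truth", "loops", "cascades",
                     "eqtls", "phenotype_truth")
    }
    return TruthBundle(seed=payload["seed"], params=payload["params"],
                       chrom_sizes=payload["chrom_sizes"], **frames)
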