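"""LD expansion of GWAS index SNPs and direction-concordant target linking.

Index SNPs for each trait are expanded with panel SNPs in high LD
(squared Pearson correlation of genotype dosages above a threshold,
within a +-1 Mb window). Expanded SNPs are intersected with enhancers
that changed activity under a treatment, and a SNP-bearing enhancer is
linked to a target gene when a kept promoter-capture interaction connects
it to a promoter whose gene changed expression in the same direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import DifferentialResult
from .regulatory import RegulatoryAnnotation

logger = logging.getLogger(__name__)

__all__ = ["VariantRecord", "TargetLink", "dosage_r2", "ld_expand",
           "overlap_snps_enhancers", "link_targets"]

TRAITS = ("T2D", "IR", "BMI", "WHR", "other")


@dataclass(frozen=True)
class VariantRecord:
    """A (possibly LD-linked) GWAS variant."""

    rsid: str
    chrom: str
    pos: int
    trait: str
    is_index: bool = True
    r2_to_index: float = 1.0
    index_rsid: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_to_index <= 1.0):
            raise ValueError("r2_to_index must be in [0, 1]")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass(frozen=True)
class TargetLink:
    """SNP -> enhancer -> gene triplet with concordant directions."""

    variant: VariantRecord
    enhancer_id: str
    gene_id: str
    enhancer_direction: str
    gene_direction: str
    treatment: str
    enhancer_fdr: float
    gene_fdr: float

    def __post_init__(self) -> None:
        if self.enhancer_direction != self.gene_direction:
            raise ValueError("target links require direction concordance")


def dosage_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages, pairwise-complete."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    ok = np.isfinite(g1) & np.isfinite(g2)
    if ok.sum() < 2:
        return np.nan
    a, b = g1[ok], g2[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    r = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    return float(r * r)


def ld_expand(
    index_snps: list[VariantRecord],
    panel: pd.DataFrame,
    dosages: np.ndarray,
    window: int = 1_000_000,
    r2_min: float = 0.8,
) -> list[VariantRecord]:
    """Expand index SNPs with panel SNPs in high LD.

    ``panel`` has one row per panel SNP (columns rsid, chrom, pos, row
    order matching ``dosages`` rows); ``dosages`` is SNPs x individuals in
    [0, 2] (NaN for missing). For each index SNP every panel SNP within
    +-``window`` bp with r^2 strictly greater than ``r2_min`` is emitted,
    carrying the index's trait and its r2. Index SNPs are always retained;
    an index absent from the panel is retained unexpanded.
    """
    rsid_to_row = {r: i for i, r in enumerate(panel["rsid"])}
    out: list[VariantRecord] = []
    for idx in index_snps:
        out.append(idx)
        row = rsid_to_row.get(idx.rsid)
        if row is None:
            logger.warning("index SNP %s absent from LD panel; not expanded", idx.rsid)
            continue
        near = (
            (panel["chrom"] == idx.chrom)
            & (panel["pos"] >= idx.pos - window)
            & (panel["pos"] <= idx.pos + window)
            & (panel["rsid"] != idx.rsid)
        )
        g_idx = dosages[row]
        for j in np.flatnonzero(near.to_numpy()):
            r2 = dosage_r2(g_idx, dosages[j])
            if np.isfinite(r2) and r2 > r2_min:
                out.append(
                    VariantRecord(
                        rsid=str(panel["rsid"].iloc[j]),
                        chrom=idx.chrom,
                        pos=int(panel["pos"].iloc[j]),
                        trait=idx.trait,
                        is_index=False,
                        r2_to_index=r2,
                        index_rsid=idx.rsid,
                    )
                )
    return out


def overlap_snps_enhancers(
    snps: list[VariantRecord],
    enhancer_diff: DifferentialResult,
    ann: RegulatoryAnnotation,
    treatment: str = "",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """SNPs falling inside enhancers that changed activity.

    Only enhancers significant at FDR < ``alpha`` are reported; a SNP is
    inside when ``start <= pos < end``. One row per (enhancer, SNP).
    """
    tab = enhancer_diff.table.set_index("feature_id")
    sig = tab[tab["direction"] != "ns"]
    rows = []
    for eid, iv in ann.enhancers:
        if eid not in sig.index:
            continue
        for v in snps:
            if iv.contains_point(v.chrom, v.pos):
                rows.append(
                    (eid, iv.chrom, iv.start, iv.end, sig.loc[eid, "direction"],
                     float(sig.loc[eid, "fdr"]), treatment, v.rsid, v.trait,
                     v.r2_to_index, v.is_index)
                )
    return pd.DataFrame(
        rows,
        columns=["enhancer_id", "chrom", "start", "end", "direction", "enhancer_fdr",
                 "treatment", "rsid", "trait", "r2_to_index", "is_index"],
    )


def link_targets(
    overlaps: pd.DataFrame,
    kept_pairs: pd.DataFrame,
    gene_diff: DifferentialResult,
    snps: list[VariantRecord] | None = None,
    treatment: str = "",
) -> list[TargetLink]:
    """Direction-concordant SNP -> enhancer -> gene links.

    A link is emitted iff a SNP-bearing regulated enhancer (``overlaps``)
    is connected by a kept interaction (``kept_pairs``) to a promoter whose
    gene is significant with the same direction in ``gene_diff``. Output is
    always a subset of overlaps x kept_pairs; multi-trait SNPs give one
    link per trait.
    """
    gd = gene_diff.table.set_index("feature_id")
    by_rsid = {} if snps is None else {(v.rsid, v.trait): v for v in snps}
    conn = kept_pairs[["enhancer_id", "bait_gene_id"]].drop_duplicates()
    merged = overlaps.merge(conn, on="enhancer_id", how="inner")
    links: list[TargetLink] = []
    for row in merged.itertuples(index=False):
        gene = row.bait_gene_id
        if gene not in gd.index:
            continue
        gdir = gd.loc[gene, "direction"]
        if gdir == "ns" or gdir != row.direction:
            continue
        variant = by_rsid.get((row.rsid, row.trait)) or VariantRecord(
            rsid=row.rsid, chrom=row.chrom, pos=int(row.start), trait=row.trait,
            is_index=bool(row.is_index), r2_to_index=float(row.r2_to_index),
        )
        links.append(
            TargetLink(
                variant=variant,
                enhancer_id=row.enhancer_id,
                gene_id=gene,
                enhancer_direction=row.direction,
                gene_direction=gdir,
                treatment=treatment or row.treatment,
                enhancer_fdr=float(row.enhancer_fdr),
                gene_fdr=float(gd.loc[gene, "fdr"]),
            )
        )
    return links


def links_frame(links: list[TargetLink]) -> pd.DataFrame:
    """Flatten target links to the TSV output schema."""
    return pd.DataFrame(
        [
            {
                "rsid": l.variant.rsid,
                "trait": l.variant.trait,
                "r2_to_index": l.variant.r2_to_index,
                "is_index": l.variant.is_index,
                "enhancer_id": l.enhancer_id,
                "gene_id": l.gene_id,
                "treatment": l.treatment,
                "direction": l.enhancer_direction,
                "enhancer_fdr": l.enhancer_fdr,
                "gene_fdr": l.gene_fdr,
            }
            for l in links
        ],
        columns=["rsid", "trait", "r2_to_index", "is_index", "enhancer_id", "gene_id",
                 "treatment", "direction", "enhancer_fdr", "gene_fdr"],
    )
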