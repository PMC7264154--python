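"""Promoter-capture Hi-C interaction filtering and promoter-group analysis.

Interaction tables are pandas DataFrames with one row per bait-fragment /
other-end-fragment pair and one count column per library (schema below).
Enhancers are widened to a fixed target width (10 kb by default) before
overlap with other-end fragments, promoter-enhancer pairs are filtered
against a distance-decay background (equal-occupancy binning of average
log2 CPM on log10 distance), and surviving pairs feed the differential
test and the ECDF/KS comparison of connected-promoter expression shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .counts import CountMatrix, DesignSpec, NormalizationFactors
from .differential import DifferentialResult, nb_differential
from .intervals import GenomicInterval
from .regulatory import RegulatoryAnnotation

logger = logging.getLogger(__name__)

#: required non-count columns of an interaction table
INTERACTION_COLUMNS = [
    "bait_gene_id",
    "chrom1", "start1", "end1",   # bait fragment
    "chrom2", "start2", "end2",   # other end
]

__all__ = [
    "InteractionRecord",
    "DistanceTrend",
    "widen_enhancer",
    "extract_promoter_enhancer_pairs",
    "fit_distance_trend",
    "filter_interactions",
    "differential_interactions",
    "interaction_stats",
    "assign_promoter_groups",
    "ecdf_ks_compare",
    "pair_distances",
    "pair_ave_log_cpm",
    "count_columns",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One bait-promoter / other-end fragment pair with per-library counts."""

    bait_gene_id: str
    bait_fragment: GenomicInterval
    other_end: GenomicInterval
    counts: tuple[int, ...]

    @property
    def distance(self) -> float:
        """Midpoint-to-midpoint distance; infinite for trans pairs."""
        if self.bait_fragment.chrom != self.other_end.chrom:
            return float("inf")
        return float(abs(self.bait_fragment.midpoint - self.other_end.midpoint))


@dataclass
class DistanceTrend:
    """Expected abundance (average log2 CPM) as a function of distance.

    Piecewise-linear in log10 distance between equal-occupancy bin centers;
    flat extrapolation beyond the observed range. Trans pairs are assigned
    the far-distance plateau.
    """

    log10_centers: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.expected)):
            raise ValueError("expected abundances must be finite")

    def expected_at(self, distance: np.ndarray) -> np.ndarray:
        distance = np.asarray(distance, float)
        out = np.empty(distance.shape)
        trans = ~np.isfinite(distance)
        out[trans] = self.expected[-1]
        with np.errstate(divide="ignore"):
            ld = np.log10(np.maximum(distance[~trans], 1.0))
        out[~trans] = np.interp(ld, self.log10_centers, self.expected)
        return out


def count_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("count_")]


def widen_enhancer(e: GenomicInterval, target_width: int = 10_000,
                   chrom_length: int | None = None) -> GenomicInterval:
    """Symmetric expansion about the midpoint to ``target_width`` bp.

    Intervals already at least that wide are returned unchanged; the
    result is truncated at 0 and at ``chrom_length`` when provided.
    """
    if e.width >= target_width:
        return e
    mid = e.midpoint
    start = max(0, mid - target_width // 2)
    end = start + target_width
    if chrom_length is not None and end > chrom_length:
        end = chrom_length
        start = max(0, end - target_width)
    return GenomicInterval(e.chrom, start, end)


def pair_distances(table: pd.DataFrame) -> np.ndarray:
    """Midpoint-to-midpoint fragment distance per row; inf for trans."""
    m1 = (table["start1"].to_numpy() + table["end1"].to_numpy()) // 2
    m2 = (table["start2"].to_numpy() + table["end2"].to_numpy()) // 2
    d = np.abs(m1 - m2).astype(float)
    d[(table["chrom1"] != table["chrom2"]).to_numpy()] = np.inf
    return d


def pair_ave_log_cpm(table: pd.DataFrame, prior: float = 2.0) -> np.ndarray:
    """Average abundance of each pair: log2 CPM of the mean count across
    libraries, at the mean library size."""
    counts = table[count_columns(table)].to_numpy(float)
    lib = counts.sum(axis=0)
    mean_lib = lib.mean()
    scaled = counts / lib * mean_lib
    return np.log2((scaled.mean(axis=1) + prior) / (mean_lib + 2 * prior) * 1e6)


def extract_promoter_enhancer_pairs(
    interactions: pd.DataFrame,
    ann: RegulatoryAnnotation,
    widen: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Pairs whose bait maps to a captured promoter and whose other end
    overlaps a widened enhancer.

    One output row per (gene, enhancer, fragment pair); an interaction
    touching several widened enhancers yields one row per enhancer.
    Widening is used only here, for linking: downstream activity
    quantification keeps the original enhancer intervals.
    """
    missing = [c for c in INTERACTION_COLUMNS if c not in interactions.columns]
    if missing:
        raise ValueError(f"interaction table lacks columns {missing}")
    known = set(ann.active_promoters)
    n_skipped = int((~interactions["bait_gene_id"].isin(known)).sum())
    if n_skipped:
        logger.info("skipping %d interactions with baits absent from annotation", n_skipped)
    inter = interactions[interactions["bait_gene_id"].isin(known)]

    wide = [
        (eid, widen_enhancer(iv, widen,
                             None if chrom_lengths is None else chrom_lengths.get(iv.chrom)))
        for eid, iv in ann.enhancers
    ]
    rows = []
    for chrom, sub in inter.groupby("chrom2", sort=False):
        cands = [(eid, w) for eid, w in wide if w.chrom == chrom]
        if not cands:
            continue
        ws = np.array([w.start for _, w in cands])
        we = np.array([w.end for _, w in cands])
        s2 = sub["start2"].to_numpy()[:, None]
        e2 = sub["end2"].to_numpy()[:, None]
        hits = (s2 < we[None, :]) & (ws[None, :] < e2)
        ii, jj = np.nonzero(hits)
        for i, j in zip(ii, jj):
            rows.append((sub.index[i], cands[j][0]))
    if not rows:
        out = inter.iloc[0:0].copy()
        out.insert(0, "enhancer_id", pd.Series(dtype=str))
        return out.reset_index(drop=True)
    idx, eids = zip(*rows)
    out = inter.loc[list(idx)].copy()
    out.insert(0, "enhancer_id", list(eids))
    out = out.sort_values(["bait_gene_id", "enhancer_id"], kind="mergesort")
    return out.reset_index(drop=True)


def fit_distance_trend(pairs: pd.DataFrame, n_bins: int = 50,
                       min_pairs: int = 50) -> DistanceTrend:
    """Distance-decay background from cis pairs.

    Bins cis pairs into ``n_bins`` equal-occupancy bins of log10 distance
    and records the mean average-log2-CPM per bin at the bin's mean log10
    distance; expectation at arbitrary distances is linear interpolation.
    """
    d = pair_distances(pairs)
    ab = pair_ave_log_cpm(pairs)
    cis = np.isfinite(d) & (d > 0)
    if cis.sum() < min_pairs:
        raise ValueError(f"need >= {min_pairs} cis pairs to fit a distance trend, "
                         f"got {int(cis.sum())}")
    ld, ab = np.log10(d[cis]), ab[cis]
    order = np.argsort(ld, kind="mergesort")
    ld, ab = ld[order], ab[order]
    n_bins = min(n_bins, max(2, ld.size // 10))
    edges = np.array_split(np.arange(ld.size), n_bins)
    centers = np.array([ld[ix].mean() for ix in edges])
    expected = np.array([ab[ix].mean() for ix in edges])
    # enforce strictly increasing centers for interpolation
    keep = np.concatenate([[True], np.diff(centers) > 1e-12])
    return DistanceTrend(centers[keep], expected[keep])


def filter_interactions(
    pairs: pd.DataFrame,
    trend: DistanceTrend,
    min_ave_cpm: float = 5.0,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Keep pairs with average CPM >= ``min_ave_cpm`` and abundance at
    least log2(``min_fold``) above the distance-decay expectation."""
    ab = pair_ave_log_cpm(pairs)
    excess = ab - trend.expected_at(pair_distances(pairs))
    keep = (ab >= np.log2(min_ave_cpm)) & (excess >= np.log2(min_fold))
    out = pairs[keep].copy()
    out["ave_log_cpm"] = ab[keep]
    out["log2_fold_over_expected"] = excess[keep]
    out["distance"] = pair_distances(pairs)[keep]
    return out.reset_index(drop=True)


def differential_interactions(
    pairs: pd.DataFrame,
    design: DesignSpec,
    nf: NormalizationFactors | None = None,
    alpha: float = 0.05,
    min_ave_cpm: float = 5.0,
) -> DifferentialResult:
    """NB differential test of interaction counts with the no-block design.

    Pairs with enough reads to test (average CPM >= ``min_ave_cpm``, the
    same bar as the general interaction filter) are tested; the design must
    not carry a block factor.
    """
    if design.block is not None:
        raise ValueError("differential interactions use the no-block design (~0 + group)")
    ccols = count_columns(pairs)
    ids = [
        f"{g}|{e}|{c1}:{s1}-{c2}:{s2}"
        for g, e, c1, s1, c2, s2 in zip(
            pairs["bait_gene_id"], pairs.get("enhancer_id", [""] * len(pairs)),
            pairs["chrom1"], pairs["start1"], pairs["chrom2"], pairs["start2"],
        )
    ]
    cm = CountMatrix(ids, list(ccols), pairs[ccols].to_numpy())
    ab = pair_ave_log_cpm(pairs)
    tested = ab >= np.log2(min_ave_cpm)
    res = nb_differential(
        cm, design, nf, alpha=alpha,
        min_cpm=0.0, min_samples=0,
    )
    table = res.table.copy()
    neutral = ~tested
    table.loc[neutral, ["logFC", "p_value", "fdr"]] = [0.0, 1.0, 1.0]
    table.loc[neutral, "direction"] = "ns"
    table.loc[neutral, "tested"] = False
    table["bait_gene_id"] = pairs["bait_gene_id"].to_numpy()
    if "enhancer_id" in pairs.columns:
        table["enhancer_id"] = pairs["enhancer_id"].to_numpy()
    return DifferentialResult(table=table, alpha=alpha)


def interaction_stats(kept: pd.DataFrame, ann: RegulatoryAnnotation) -> dict[str, float]:
    """Median distance, median links per promoter and coverage fractions."""
    if kept.empty:
        raise ValueError("no kept interactions")
    d = kept["distance"] if "distance" in kept.columns else pd.Series(pair_distances(kept))
    links = kept.groupby("bait_gene_id").size()
    n_prom = max(len(ann.active_promoters), 1)
    n_enh = max(len(ann.enhancers), 1)
    return {
        "median_distance": float(np.median(d[np.isfinite(d)])),
        "median_links_per_promoter": float(links.median()),
        "promoter_coverage": kept["bait_gene_id"].nunique() / n_prom,
        "enhancer_coverage": (
            kept["enhancer_id"].nunique() / n_enh if "enhancer_id" in kept.columns else 0.0
        ),
    }


def assign_promoter_groups(
    pairs: pd.DataFrame,
    enhancer_diff: DifferentialResult,
) -> pd.DataFrame:
    """Group each connected promoter by its enhancers' activity changes.

    'Up' iff >= 1 connected enhancer gained activity and none lost it;
    'Down' symmetric; 'Ambiguous' iff both; 'None' otherwise. Promoters
    with no connected enhancer do not appear.
    """
    dirs = enhancer_diff.directions()
    rows = []
    for gene, sub in pairs.groupby("bait_gene_id", sort=True):
        ed = dirs.reindex(sub["enhancer_id"].unique()).dropna()
        has_up, has_down = (ed == "up").any(), (ed == "down").any()
        if has_up and has_down:
            grp = "Ambiguous"
        elif has_up:
            grp = "Up"
        elif has_down:
            grp = "Down"
        else:
            grp = "None"
        rows.append((gene, grp))
    return pd.DataFrame(rows, columns=["gene_id", "group"])


def ecdf_ks_compare(
    groups: pd.DataFrame,
    gene_logfc: pd.Series,
    min_group: int = 3,
) -> pd.DataFrame:
    """Two-sample KS tests of gene logFC: Up vs None and Down vs None.

    Ambiguous promoters are excluded. Returns one row per comparison with
    the D statistic and p-value.
    """
    byg = groups.set_index("gene_id")["group"]
    out = []
    ref = gene_logfc.reindex(byg.index[byg == "None"]).dropna()
    for name in ("Up", "Down"):
        vals = gene_logfc.reindex(byg.index[byg == name]).dropna()
        if len(vals) < min_group or len(ref) < min_group:
            raise ValueError(
                f"group {name!r} vs 'None': need >= {min_group} genes per group "
                f"(got {len(vals)} and {len(ref)})"
            )
        ks = ks_2samp(vals.to_numpy(), ref.to_numpy())
        out.append((f"{name}_vs_None", float(ks.statistic), float(ks.pvalue),
                    len(vals), len(ref)))
    return pd.DataFrame(out, columns=["comparison", "D", "p_value", "n_group", "n_ref"])
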