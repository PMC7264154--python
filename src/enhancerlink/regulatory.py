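"""Rule-based classification of promoters and enhancers from histone-mark peaks.

Active promoters are RefSeq-style TSS windows (3 kb upstream / 1 kb
downstream by default) that contain an H3K4me3 consensus peak. Active
enhancers are H3K27ac consensus peaks that overlap an H3K4me1 peak and lie
outside every active-promoter window; H3K4me1-only peaks outside promoter
windows are classified as primed enhancers. The enhancer interval is the
H3K27ac peak itself — enhancer activity is subsequently quantified on
H3K27ac counts, the H3K4me1 overlap only gates eligibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval, TssRecord, overlaps_any, promoter_window

logger = logging.getLogger(__name__)

VALID_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3")

__all__ = [
    "PeakSet",
    "RegulatoryAnnotation",
    "define_active_promoters",
    "define_enhancers",
    "peak_overlap_fraction",
]


@dataclass
class PeakSet:
    """Consensus peaks for one histone mark."""

    mark: str
    peaks: list[tuple[str, GenomicInterval]]

    def __post_init__(self) -> None:
        if self.mark not in VALID_MARKS:
            raise ValueError(f"unknown mark {self.mark!r}, expected one of {VALID_MARKS}")
        ids = [pid for pid, _ in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError("peak ids must be unique within a peak set")

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_id": [pid for pid, _ in self.peaks],
                "chrom": [iv.chrom for _, iv in self.peaks],
                "start": [iv.start for _, iv in self.peaks],
                "end": [iv.end for _, iv in self.peaks],
            }
        )


@dataclass
class RegulatoryAnnotation:
    """Classified promoter windows and enhancer intervals.

    ``active_promoters`` maps gene_id to its promoter window; ``enhancers``
    and ``primed`` carry (id, interval) pairs. Invariant: no enhancer
    interval overlaps any active-promoter window.
    """

    active_promoters: dict[str, GenomicInterval]
    enhancers: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    primed: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    promoter_window_up: int = 3000
    promoter_window_down: int = 1000

    def __post_init__(self) -> None:
        if self.promoter_window_up <= 0 or self.promoter_window_down <= 0:
            raise ValueError("promoter window parameters must be > 0")
        ids = [eid for eid, _ in self.enhancers]
        if len(ids) != len(set(ids)):
            raise ValueError("enhancer ids must be unique")

    def enhancer_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "enhancer_id": [eid for eid, _ in self.enhancers],
                "chrom": [iv.chrom for _, iv in self.enhancers],
                "start": [iv.start for _, iv in self.enhancers],
                "end": [iv.end for _, iv in self.enhancers],
            }
        )

    def promoter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.active_promoters),
                "chrom": [iv.chrom for iv in self.active_promoters.values()],
                "start": [iv.start for iv in self.active_promoters.values()],
                "end": [iv.end for iv in self.active_promoters.values()],
            }
        )


def _peaks_frame(ps: PeakSet) -> pd.DataFrame:
    return ps.to_frame()


def define_active_promoters(
    tss_set: list[TssRecord],
    k4me3: PeakSet,
    up: int = 3000,
    down: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, GenomicInterval]:
    """Promoter windows containing at least one H3K4me3 peak.

    Returns only the windows of active promoters, keyed by gene id.
    """
    if k4me3.mark != "H3K4me3":
        raise ValueError(f"expected H3K4me3 peak set, got {k4me3.mark}")
    if not tss_set:
        logger.warning("empty TSS set: no active promoters defined")
        return {}
    windows = [
        promoter_window(
            t, up, down,
            chrom_length=None if chrom_lengths is None else chrom_lengths.get(t.chrom),
        )
        for t in tss_set
    ]
    wdf = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
        }
    )
    hit = overlaps_any(wdf, _peaks_frame(k4me3))
    return {t.gene_id: w for t, w, h in zip(tss_set, windows, hit) if h}


def define_enhancers(
    k27ac: PeakSet,
    k4me1: PeakSet,
    active_promoter_windows: dict[str, GenomicInterval],
    promoter_window_up: int = 3000,
    promoter_window_down: int = 1000,
) -> RegulatoryAnnotation:
    """Classify active and primed enhancers.

    Active enhancer: an H3K27ac peak overlapping >= 1 H3K4me1 peak and no
    active-promoter window (the enhancer keeps the H3K27ac peak id and
    interval; one enhancer per H3K27ac peak regardless of how many H3K4me1
    peaks it touches). Primed enhancer: an H3K4me1 peak overlapping no
    H3K27ac peak and no promoter window.
    """
    if k27ac.mark != "H3K27ac":
        raise ValueError(f"expected H3K27ac peak set, got {k27ac.mark}")
    if k4me1.mark != "H3K4me1":
        raise ValueError(f"expected H3K4me1 peak set, got {k4me1.mark}")

    prom_df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in active_promoter_windows.values()],
            "start": [w.start for w in active_promoter_windows.values()],
            "end": [w.end for w in active_promoter_windows.values()],
        }
    )
    k27_df, k4_df = _peaks_frame(k27ac), _peaks_frame(k4me1)

    k27_has_k4 = overlaps_any(k27_df, k4_df)
    k27_in_prom = overlaps_any(k27_df, prom_df)
    enhancers = [
        (pid, iv)
        for (pid, iv), has_k4, in_prom in zip(k27ac.peaks, k27_has_k4, k27_in_prom)
        if has_k4 and not in_prom
    ]

    k4_has_k27 = overlaps_any(k4_df, k27_df)
    k4_in_prom = overlaps_any(k4_df, prom_df)
    primed = [
        (pid, iv)
        for (pid, iv), has_k27, in_prom in zip(k4me1.peaks, k4_has_k27, k4_in_prom)
        if not has_k27 and not in_prom
    ]

    return RegulatoryAnnotation(
        active_promoters=dict(active_promoter_windows),
        enhancers=enhancers,
        primed=primed,
        promoter_window_up=promoter_window_up,
        promoter_window_down=promoter_window_down,
    )


def peak_overlap_fraction(query: PeakSet, subject: PeakSet) -> float:
    """Fraction of query peaks overlapping >= 1 subject peak by any amount."""
    if len(query) == 0:
        raise ValueError("overlap fraction undefined for an empty query peak set")
    hit = overlaps_any(_peaks_frame(query), _peaks_frame(subject))
    return float(hit.mean())
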