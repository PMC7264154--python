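"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
A TSS is the 0-based coordinate of the first transcribed base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TssRecord",
    "promoter_window",
    "intervals_overlap",
    "overlaps_any",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class TssRecord:
    """A gene's transcription start site with strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


def promoter_window(
    tss: TssRecord,
    up: int = 3000,
    down: int = 1000,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around a TSS.

    ``up`` bp upstream and ``down`` bp downstream of the TSS in the
    direction of transcription; on the minus strand the window is the
    mirror image of the plus-strand window about the TSS. The window is
    truncated at position 0 and, when given, at ``chrom_length``.
    """
    if up < 0 or down < 0:
        raise ValueError("window sizes must be non-negative")
    if up == 0 and down == 0:
        raise ValueError("window cannot be empty (up == down == 0)")
    if tss.strand == "+":
        start, end = tss.tss - up, tss.tss + down
    else:
        start, end = tss.tss - down, tss.tss + up
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(tss.chrom, start, end)


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the half-open intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Vectorised any-overlap test for interval tables.

    Both frames need columns ``chrom``, ``start``, ``end``. Returns a boolean
    array, one entry per query row, true iff the row overlaps at least one
    subject interval by any amount.
    """
    out = np.zeros(len(query), dtype=bool)
    if query.empty or subject.empty:
        return out
    for chrom, sub in subject.groupby("chrom", sort=False):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy()[:, None]
        qe = query.loc[mask, "end"].to_numpy()[:, None]
        ss = sub["start"].to_numpy()[None, :]
        se = sub["end"].to_numpy()[None, :]
        out[mask] |= ((qs < se) & (ss < qe)).any(axis=1)
    return out
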