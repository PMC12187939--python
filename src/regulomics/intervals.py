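"""Genomic interval primitives.

All coordinates are BED-convention: 0-based, half-open ``[start, end)``.
Touching intervals (``a.end == b.start``) do not overlap, matching bedtools
defaults. Strand is carried on intervals but ignored by overlap and distance
arithmetic; only promoter-window construction is strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start (bp).
    end : int
        0-based exclusive end (bp); ``end - start`` is the length.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A signal-carrying interval (ChIP peak, narrowPeak row)."""

    interval: GenomicInterval
    signal: float = 0.0
    qvalue: Optional[float] = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"negative peak signal: {self.signal}")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue outside [0,1]: {self.qvalue}")


@dataclass(frozen=True)
class Promoter:
    """A gene's transcription start site as a width-1 interval."""

    gene: str
    tss: GenomicInterval

    def __post_init__(self) -> None:
        if self.tss.length != 1:
            raise ValueError(f"promoter TSS must have width 1, got {self.tss.length}")

    def window(self, window_bp: int) -> GenomicInterval:
        """Symmetric ±window_bp window around the TSS, clipped at 0."""
        start = max(0, self.tss.start - window_bp)
        return GenomicInterval(self.tss.chrom, start, self.tss.start + window_bp,
                               self.tss.strand)


@dataclass(frozen=True)
class Link:
    """A paired-anchor chromatin contact with a contact-count score (CCscore).

    Anchors are stored canonically ordered by (chrom, start).
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    ccscore: float = 0.0
    pvalue: float = 1.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.ccscore < 0:
            raise ValueError(f"negative ccscore: {self.ccscore}")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"pvalue outside [0,1]: {self.pvalue}")
        a, b = self.anchor1, self.anchor2
        if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share ≥1 bp under half-open semantics."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def nearest_distance(
    query: GenomicInterval, subjects: Iterable[GenomicInterval]
) -> Optional[int]:
    """Gap in bp from ``query`` to the nearest same-chromosome subject.

    Returns 0 on any overlap and None when no subject shares the query's
    chromosome. The distance is the inter-interval gap, not a midpoint
    distance, matching GenomicRanges ``distanceToNearest``.
    """
    best: Optional[int] = None
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        if overlaps(query, s):
            return 0
        gap = s.start - query.end if s.start >= query.end else query.start - s.end
        if best is None or gap < best:
            best = gap
    return best


def overlaps_any(query: GenomicInterval, subjects: Sequence[GenomicInterval]) -> bool:
    """True iff ``query`` overlaps at least one subject."""
    return any(overlaps(query, s) for s in subjects)
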