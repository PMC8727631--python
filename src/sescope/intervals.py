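"""Genomic coordinate primitives.

All coordinates in this package are 0-based, half-open ``[start, end)``
(the BED convention). Overlap everywhere means any-overlap: two intervals
on the same chromosome overlap iff they share at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand, score and name."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} "
                "(start must be < end)"
            )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


@dataclass(frozen=True)
class TSS:
    """A transcription start site: single-base anchor of a gene."""

    gene_id: str
    chrom: str
    pos: int  # 0-based
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative TSS position for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of the *larger* requirement met: min over both intervals of
    overlap/length. Two intervals reciprocally overlap at fraction f iff the
    shared span covers at least f of each."""
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of any-overlapping (or bookended) intervals, per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def total_span(intervals: Sequence[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_overlapping(intervals))
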