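"""Genomic intervals in one fixed convention.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
Format readers convert at the boundary (GFF3 is 1-based closed on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .exceptions import ValidationError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}; "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
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


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals, merging any pair sharing >= 1 bp, per chromosome.

    Strand is dropped ('.'): merged regions are strand-agnostic consensus
    regions (the rule used to build the ATAC consensus peak set).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # >= 1 bp overlap
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


@dataclass
class IntervalIndex:
    """Overlap index over a fixed interval list (intervaltree-backed)."""

    intervals: Sequence[GenomicInterval]
    _trees: dict[str, IntervalTree] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._trees = {}
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, i
            )

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices of stored intervals sharing >= 1 bp with *query*."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(query.start, query.end))


def promoter_interval(
    tss: int,
    strand: str,
    chrom: str,
    upstream: int,
    downstream: int,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around a TSS.

    ``upstream`` bases extend toward the 5' side of the gene and
    ``downstream`` toward the 3' side; the TSS base itself is included.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("promoter window sizes must be non-negative")
    if strand == "-":
        start, end = tss - downstream, tss + upstream + 1
    else:
        start, end = tss - upstream, tss + downstream + 1
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(chrom, start, max(end, start + 1))
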