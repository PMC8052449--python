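"""Stranded genomic intervals and one-dimensional interval-set arithmetic.

Coordinates are BED-style throughout: 0-based, half-open, per chromosome.
The set operations work on plain (start, end) tuples and are used by the
conserved-intronic-region construction, where gene attribution must be
carried through subtraction and intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "merge_intervals",
    "subtract_intervals",
    "intersect_intervals",
    "complement_within",
    "group_by_chrom",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


Span = Tuple[int, int]


def merge_intervals(spans: Iterable[Span]) -> List[Span]:
    """Union of (start, end) spans as a sorted list of disjoint spans."""
    out: List[Span] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(spans: Sequence[Span], cut: Sequence[Span]) -> List[Span]:
    """Per-span subtraction of the union of ``cut`` from ``spans``."""
    cut = merge_intervals(cut)
    out: List[Span] = []
    for s, e in spans:
        pos = s
        for cs, ce in cut:
            if ce <= pos or cs >= e:
                continue
            if cs > pos:
                out.append((pos, cs))
            pos = max(pos, ce)
            if pos >= e:
                break
        if pos < e:
            out.append((pos, e))
    return out


def intersect_intervals(spans: Sequence[Span], other: Sequence[Span]) -> List[Span]:
    """Pairwise intersections of each span with the union of ``other``."""
    other = merge_intervals(other)
    out: List[Span] = []
    for s, e in spans:
        for os, oe in other:
            lo, hi = max(s, os), min(e, oe)
            if lo < hi:
                out.append((lo, hi))
    return out


def complement_within(window: Span, spans: Sequence[Span]) -> List[Span]:
    """Maximal sub-spans of ``window`` disjoint from the union of ``spans``."""
    return subtract_intervals([window], spans)


def group_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> Dict[str, List[GenomicInterval]]:
    out: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for lst in out.values():
        lst.sort()
    return out
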