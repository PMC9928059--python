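"""Coordinate-convention-safe genomic interval algebra.

Every positional quantity in the package lives in 0-based, half-open
(BED-native) coordinates.  Formats that use other conventions (GFF3 is
1-based, closed) are converted at the I/O boundary, never here.  Strand is
carried on :class:`GenomicInterval` but deliberately ignored by all overlap
logic: the locus procedures this package implements are strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "overlaps",
    "merge",
    "intersect_span",
    "contained_in",
    "crosses_boundary",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``.

    Parameters
    ----------
    chrom
        Chromosome name, compared as an exact string (no ``chr``-prefix
        normalization).
    start
        0-based inclusive start offset; must be ``>= 0``.
    end
        Exclusive end offset; must be ``> start``, so every interval has
        positive length.
    strand
        ``"+"``, ``"-"`` or ``"."`` (unstranded).  Carried for provenance
        only.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share at least one base.

    Half-open semantics: abutting intervals (``a.end == b.start``) do not
    overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge(xs: Iterable[GenomicInterval], max_gap: int = 0) -> list[GenomicInterval]:
    """Single-linkage merge of intervals whose gap is at most ``max_gap``.

    Two intervals on the same chromosome end up in one output interval
    whenever they are separated by ``max_gap`` bases or fewer (a gap exactly
    equal to the threshold merges).  Output is sorted by (chrom, start) and
    its members are pairwise separated by more than ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be non-negative, got {max_gap}")
    xs = sorted(xs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in xs:
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= max_gap:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect_span(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval | None:
    """The overlapping span of *a* and *b*, or ``None`` when disjoint."""
    if not overlaps(a, b):
        return None
    return GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))


def contained_in(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* lies entirely within *b* (equality counts)."""
    return a.chrom == b.chrom and b.start <= a.start and a.end <= b.end


def _check_domains(domains: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for ds in by_chrom.values():
        ds.sort(key=lambda iv: iv.start)
        for prev, cur in zip(ds, ds[1:]):
            if cur.start < prev.end:
                raise ValueError(f"overlapping domains: {prev} and {cur}")


def crosses_boundary(
    a: GenomicInterval, domains: Sequence[GenomicInterval]
) -> list[int]:
    """Domain borders that fall strictly inside *a*.

    ``domains`` must be non-overlapping.  Returns the sorted coordinates of
    every domain start or end with ``a.start < pos < a.end`` on the same
    chromosome; an interval that fits a domain exactly crosses nothing.
    """
    _check_domains(domains)
    hits: set[int] = set()
    for d in domains:
        if d.chrom != a.chrom:
            continue
        for pos in (d.start, d.end):
            if a.start < pos < a.end:
                hits.add(pos)
    return sorted(hits)
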