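"""Regulatory-element identification and super-enhancer stitching.

A candidate regulatory element is a TF peak (STAT5A by default) that was
called in both ChIP-seq replicates and carries H3K27ac acetylation
underneath.  Retained elements are scanned for the GAS consensus
(TTCNNNGAA) and closely spaced elements are stitched into super-enhancer
candidates ranked by total signal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval, overlaps

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryElement",
    "SuperEnhancerCandidate",
    "consensus_peaks",
    "filter_h3k27ac",
    "scan_gas",
    "count_gas_hits",
    "stitch_super_enhancers",
    "identify_elements",
]

_GAS_RE = re.compile("TTC[ACGT]{3}GAA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class RegulatoryElement:
    interval: GenomicInterval
    factor: str = "STAT5A"
    name: str = ""
    replicate_support: int = 2
    h3k27ac_supported: bool = True
    gas_hits: int = 0
    score: float = 0.0


@dataclass
class SuperEnhancerCandidate:
    interval: GenomicInterval
    constituents: list[RegulatoryElement] = field(default_factory=list)

    @property
    def total_signal(self) -> float:
        return sum(e.score for e in self.constituents)


def _as_sorted(peaks: pd.DataFrame, label: str) -> pd.DataFrame:
    srt = peaks.sort_values(["chrom", "start", "end"], kind="stable")
    if not srt.index.equals(peaks.index):
        logger.info("%s peaks were not coordinate-sorted; sorting internally", label)
    return srt.reset_index(drop=True)


def consensus_peaks(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Replicate-consensus peaks: rep1 peaks overlapping some rep2 peak.

    Overlap is >= 1 bp in half-open coordinates; retained peaks keep their
    rep1 coordinates (configurable union output is deliberately not the
    default: rep1-anchored output is deterministic and directly testable
    against the generator manifest).
    """
    rep1 = _as_sorted(rep1, "replicate 1")
    rep2 = _as_sorted(rep2, "replicate 2")
    keep = []
    by_chrom = {c: sub for c, sub in rep2.groupby("chrom")}
    for _, row in rep1.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            continue
        hit = ((sub["start"] < row["end"]) & (row["start"] < sub["end"])).any()
        if hit:
            keep.append(row)
    if not keep:
        return rep1.iloc[0:0].copy()
    return pd.DataFrame(keep).reset_index(drop=True)


def filter_h3k27ac(
    peaks: pd.DataFrame,
    broad: pd.DataFrame,
    factor: str = "STAT5A",
    min_overlap_fraction: float = 0.0,
) -> list[RegulatoryElement]:
    """Keep peaks with H3K27ac coverage underneath.

    The default criterion is >= 1 bp overlap with any broad acetylation
    region; ``min_overlap_fraction`` optionally requires that fraction of
    the TF peak to be covered by a single broad region.
    """
    out: list[RegulatoryElement] = []
    by_chrom = {c: sub for c, sub in broad.groupby("chrom")}
    for _, row in peaks.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            continue
        ov = (
            sub["end"].clip(upper=row["end"]) - sub["start"].clip(lower=row["start"])
        ).clip(lower=0)
        needed = max(1.0, min_overlap_fraction * (row["end"] - row["start"]))
        if (ov >= needed).any():
            out.append(
                RegulatoryElement(
                    interval=GenomicInterval(row["chrom"], int(row["start"]),
                                             int(row["end"])),
                    factor=factor,
                    name=str(row.get("name", "")),
                    replicate_support=2,
                    h3k27ac_supported=True,
                    score=float(row.get("score", 0.0)),
                )
            )
    return out


def count_gas_hits(sequence: str, start: int, end: int) -> int:
    """GAS consensus matches fully contained in ``[start, end)``.

    Both strands are scanned; because the consensus TTCNNNGAA is its own
    reverse complement as a pattern, a forward and a reverse hit at the same
    start describe the same site and are counted once.
    """
    if start < 0 or end > len(sequence) or end <= start:
        raise ValueError(f"element span [{start}, {end}) out of sequence bounds")
    window = sequence[start:end]
    fwd = {start + m.start() for m in _GAS_RE.finditer(window)}
    rc = window.translate(_COMPLEMENT)[::-1]
    n = end - start
    rev = {start + n - (m.start() + 9) for m in _GAS_RE.finditer(rc)}
    return len(fwd | rev)


def scan_gas(
    sequences: dict[str, str] | str, element: RegulatoryElement
) -> int:
    """Count GAS consensus hits within one element and record them on it."""
    seq = sequences[element.interval.chrom] if isinstance(sequences, dict) else sequences
    hits = count_gas_hits(seq, element.interval.start, element.interval.end)
    element.gas_hits = hits
    return hits


def stitch_super_enhancers(
    elements: list[RegulatoryElement],
    stitch_gap: int = 12_500,
    min_constituents: int = 3,
) -> list[SuperEnhancerCandidate]:
    """Single-linkage stitching of elements into super-enhancer candidates.

    Elements on one chromosome whose inter-element gap is at most
    ``stitch_gap`` join one cluster; clusters with at least
    ``min_constituents`` members become candidates, ranked by summed
    constituent signal (descending).
    """
    if min_constituents < 2:
        raise ValueError("min_constituents must be at least 2")
    if stitch_gap < 0:
        raise ValueError("stitch_gap must be non-negative")
    ordered = sorted(elements, key=lambda e: (e.interval.chrom, e.interval.start))
    clusters: list[list[RegulatoryElement]] = []
    for el in ordered:
        if (
            clusters
            and el.interval.chrom == clusters[-1][-1].interval.chrom
            and el.interval.start - max(e.interval.end for e in clusters[-1])
            <= stitch_gap
        ):
            clusters[-1].append(el)
        else:
            clusters.append([el])
    cands = [
        SuperEnhancerCandidate(
            interval=GenomicInterval(
                c[0].interval.chrom,
                min(e.interval.start for e in c),
                max(e.interval.end for e in c),
            ),
            constituents=c,
        )
        for c in clusters
        if len(c) >= min_constituents
    ]
    cands.sort(key=lambda s: -s.total_signal)
    return cands


def identify_elements(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    broad: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    factor: str = "STAT5A",
    min_overlap_fraction: float = 0.0,
) -> list[RegulatoryElement]:
    """Full element stage: replicate consensus, H3K27ac filter, GAS scan."""
    cons = consensus_peaks(rep1, rep2)
    els = filter_h3k27ac(cons, broad, factor=factor,
                         min_overlap_fraction=min_overlap_fraction)
    if sequences is not None:
        for el in els:
            scan_gas(sequences, el)
    return els
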