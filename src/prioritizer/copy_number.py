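"""Gene-level copy-number calls from SEG segmentation, and fraction of genome altered.

A gene's copy state is derived from the log2 ratio of its overlapping
segments (length-weighted mean over the overlapped bases by default, or the
most-deleted-segment minimum).  Thresholds follow the GISTIC settings used
for the arrays this pipeline mirrors: amplification at +0.8 and single-copy
deletion at -0.6 log2.  "Deep deletion" (homozygous loss) has no printed
bound in that setting; the default -1.3 corresponds to fewer than one copy
in a diploid background and is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from math import nan
from typing import Sequence

from .variant_io import GeneInterval, Segment

__all__ = [
    "CopyCall",
    "CopyThresholds",
    "GeneCopyCall",
    "gene_copy_call",
    "fraction_genome_altered",
]


class CopyCall(str, Enum):
    AMP = "AMP"
    NEUTRAL = "NEUTRAL"
    LOSS = "LOSS"
    DEEP_DEL = "DEEP_DEL"


@dataclass(frozen=True)
class CopyThresholds:
    amp: float = 0.8
    loss: float = -0.6
    deep_del: float = -1.3

    def __post_init__(self) -> None:
        if not (self.deep_del < self.loss < 0 < self.amp):
            raise ValueError(f"need deep_del < loss < 0 < amp, got {self}")

    def call(self, seg_mean: float) -> CopyCall:
        if seg_mean >= self.amp:
            return CopyCall.AMP
        if seg_mean <= self.deep_del:
            return CopyCall.DEEP_DEL
        if seg_mean <= self.loss:
            return CopyCall.LOSS
        return CopyCall.NEUTRAL


@dataclass(frozen=True)
class GeneCopyCall:
    sample_id: str
    gene: str
    seg_mean: float  # nan when no segment overlaps the gene
    call: CopyCall


def gene_copy_call(
    segments: Sequence[Segment],
    gene_interval: GeneInterval,
    thresholds: CopyThresholds = CopyThresholds(),
    gene_summary: str = "weighted_mean",
) -> GeneCopyCall:
    """Call one gene's copy state from one sample's segments.

    The gene value is the base-length-weighted mean of overlapping segment
    means (``gene_summary="min"`` takes the most-deleted overlapping
    segment instead).  A gene overlapped by zero bases is NEUTRAL with a
    warning, not an error.
    """
    if gene_summary not in ("weighted_mean", "min"):
        raise ValueError("gene_summary must be 'weighted_mean' or 'min'")
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else ""

    overlaps: list[tuple[int, float]] = []
    for seg in segments:
        if seg.chrom != gene_interval.chrom:
            continue
        lo = max(seg.start, gene_interval.start)
        hi = min(seg.end, gene_interval.end)
        if lo <= hi:
            overlaps.append((hi - lo + 1, seg.seg_mean))
    if not overlaps:
        warnings.warn(
            f"gene {gene_interval.gene} overlapped by no segment in sample "
            f"{sample_id or '<unknown>'}; calling NEUTRAL",
            stacklevel=2,
        )
        return GeneCopyCall(sample_id, gene_interval.gene, nan, CopyCall.NEUTRAL)

    if gene_summary == "weighted_mean":
        total = sum(length for length, _ in overlaps)
        value = sum(length * mean for length, mean in overlaps) / total
    else:
        value = min(mean for _, mean in overlaps)
    return GeneCopyCall(sample_id, gene_interval.gene, value, thresholds.call(value))


def fraction_genome_altered(
    segments: Sequence[Segment], fga_threshold: float = 0.2
) -> float:
    """FGA: fraction of segmented bases with |log2 ratio| >= threshold."""
    total = sum(s.length for s in segments)
    if total == 0:
        raise ValueError("zero total segmented length")
    altered = sum(s.length for s in segments if abs(s.seg_mean) >= fga_threshold)
    return altered / total
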