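"""Two-hit (biallelic inactivation) classification and cohort frequencies.

A gene in a tumor is TWO_HIT when both alleles show evidence of
loss-of-function: homozygous loss (deep deletion), homozygous mutation, or a
heterozygous mutation combined with copy-number loss of the second allele.
A single mutation with neutral copy number, or loss without mutation, is
ONE_HIT; otherwise WT.

Zygosity is inferred from tumor VAF: a variant at VAF >= 0.7 (default) is
treated as homozygous — the bound tolerates purity/contamination while
excluding balanced heterozygotes.  Two distinct functional variants in one
gene default to homozygous-equivalent (compound biallelic assumption;
phasing is unavailable), switchable off.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .copy_number import CopyCall
from .variant_io import VariantRecord

__all__ = [
    "Zygosity",
    "Mechanism",
    "AlterationStatus",
    "ZygosityConfig",
    "AlterationCall",
    "classify_zygosity",
    "classify_two_hit",
    "cohort_alteration_frequency",
]


class Zygosity(str, Enum):
    NONE = "NONE"
    HET = "HET"
    HOM = "HOM"


class Mechanism(str, Enum):
    DEEP_DELETION = "DEEP_DELETION"
    HOMOZYGOUS_MUTATION = "HOMOZYGOUS_MUTATION"
    HET_MUTATION_PLUS_LOSS = "HET_MUTATION_PLUS_LOSS"
    MUTATION_ONLY = "MUTATION_ONLY"
    LOSS_ONLY = "LOSS_ONLY"


TWO_HIT_MECHANISMS = frozenset(
    {Mechanism.DEEP_DELETION, Mechanism.HOMOZYGOUS_MUTATION, Mechanism.HET_MUTATION_PLUS_LOSS}
)


class AlterationStatus(str, Enum):
    WT = "WT"
    ONE_HIT = "ONE_HIT"
    TWO_HIT = "TWO_HIT"


@dataclass(frozen=True)
class ZygosityConfig:
    homozygous_vaf_min: float = 0.7
    compound_het_is_hom: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.homozygous_vaf_min <= 1:
            raise ValueError("homozygous_vaf_min must be in (0.5, 1]")


@dataclass(frozen=True)
class AlterationCall:
    sample_id: str
    gene: str
    status: AlterationStatus
    mechanisms: frozenset


def classify_zygosity(
    variants: Sequence[VariantRecord],
    copy_call: CopyCall = CopyCall.NEUTRAL,
    zcfg: ZygosityConfig = ZygosityConfig(),
) -> Zygosity:
    """Infer mutation zygosity for one gene in one sample.

    HOM when any variant reaches the homozygous VAF bound, or (by default)
    when two or more distinct functional variants hit the gene (compound
    configuration).  HET for any remaining mutation; NONE otherwise.
    ``copy_call`` is accepted for interface symmetry but plays no role in
    the VAF-based rule.
    """
    if not variants:
        return Zygosity.NONE
    if any(v.tumor_vaf >= zcfg.homozygous_vaf_min for v in variants):
        return Zygosity.HOM
    if zcfg.compound_het_is_hom and len({v.key for v in variants}) >= 2:
        return Zygosity.HOM
    return Zygosity.HET


def classify_two_hit(
    zygosity: Zygosity,
    copy_call: CopyCall,
    sample_id: str = "",
    gene: str = "",
) -> AlterationCall:
    """Integrate zygosity and copy state into WT/ONE_HIT/TWO_HIT.

    "Loss" for the het-mutation-plus-loss mechanism means copy call LOSS or
    DEEP_DEL.  Mechanisms accumulate (a deep deletion plus a homozygous
    mutation records both).
    """
    mechanisms: set[Mechanism] = set()
    if copy_call is CopyCall.DEEP_DEL:
        mechanisms.add(Mechanism.DEEP_DELETION)
    if zygosity is Zygosity.HOM:
        mechanisms.add(Mechanism.HOMOZYGOUS_MUTATION)
    if zygosity is Zygosity.HET and copy_call in (CopyCall.LOSS, CopyCall.DEEP_DEL):
        mechanisms.add(Mechanism.HET_MUTATION_PLUS_LOSS)
    if not mechanisms:
        if zygosity is Zygosity.HET:
            mechanisms.add(Mechanism.MUTATION_ONLY)
        elif copy_call is CopyCall.LOSS:
            mechanisms.add(Mechanism.LOSS_ONLY)

    if mechanisms & TWO_HIT_MECHANISMS:
        status = AlterationStatus.TWO_HIT
    elif mechanisms:
        status = AlterationStatus.ONE_HIT
    else:
        status = AlterationStatus.WT
    return AlterationCall(sample_id, gene, status, frozenset(mechanisms))


def cohort_alteration_frequency(
    calls: Iterable[AlterationCall],
    gene: str,
    statuses: frozenset = frozenset({AlterationStatus.TWO_HIT}),
) -> tuple[int, int, float]:
    """Cohort frequency of the given alteration statuses for one gene.

    Returns ``(count, total, percentage)`` with the percentage on the 0-100
    scale, unrounded; display rounding is the caller's concern.  Expects one
    call per (sample, gene).
    """
    gene_calls = [c for c in calls if c.gene == gene]
    total = len(gene_calls)
    if total == 0:
        raise ValueError(f"no alteration calls for gene {gene}")
    seen = set()
    for c in gene_calls:
        if c.sample_id in seen:
            raise ValueError(f"duplicate alteration call for sample {c.sample_id}, gene {gene}")
        seen.add(c.sample_id)
    count = sum(1 for c in gene_calls if c.status in statuses)
    return count, total, 100.0 * count / total
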