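"""Multi-caller consensus and the panel of normals.

Tumor variants are kept when called by at least two of the three callers;
matched-normal variants are kept when called by any one caller.  The panel of
normals is the cohort-wide union of normal consensus keys: a variant seen in
any normal control — not just the matched pair — is treated as
germline/artifactual everywhere (``normal_scope`` switches to matched-only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variant_io import Tissue, VariantKey, VariantRecord

__all__ = ["ConsensusSet", "build_consensus", "build_normal_panel"]

MIN_CALLERS_TUMOR = 2
MIN_CALLERS_NORMAL = 1


@dataclass
class ConsensusSet:
    """Per-sample consensus variants with merged caller support."""

    sample_id: str
    tissue: Tissue
    variants: dict[VariantKey, VariantRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[VariantKey]:
        return set(self.variants)


def build_consensus(
    per_caller_records: Sequence[VariantRecord],
    tissue: Tissue,
    min_callers_tumor: int = MIN_CALLERS_TUMOR,
    min_callers_normal: int = MIN_CALLERS_NORMAL,
) -> ConsensusSet:
    """Merge per-caller records for one sample into a consensus set.

    Per key the caller sets are unioned; a key is retained iff its caller
    count meets the tissue's threshold (defaults: 2 for tumors, 1 for
    normals).  Caller genotype/quality fields play no role — only presence.
    Order-independent: permuting the input yields an identical set.
    """
    if not per_caller_records:
        return ConsensusSet(sample_id="", tissue=tissue)
    sample_ids = {r.sample_id for r in per_caller_records}
    tissues = {r.tissue for r in per_caller_records}
    if len(sample_ids) != 1 or tissues != {tissue}:
        raise ValueError(
            f"records must share one sample_id and tissue={tissue}; "
            f"got samples={sorted(sample_ids)} tissues={sorted(t.value for t in tissues)}"
        )
    sample_id = sample_ids.pop()

    merged: dict[VariantKey, frozenset] = {}
    for rec in per_caller_records:
        merged[rec.key] = merged.get(rec.key, frozenset()) | rec.callers

    n_callers = len(set().union(*merged.values())) if merged else 0
    if n_callers > 3:
        warnings.warn(
            f"{n_callers} distinct callers seen; thresholds are absolute counts",
            stacklevel=2,
        )

    threshold = min_callers_tumor if tissue is Tissue.TUMOR else min_callers_normal
    variants = {
        key: VariantRecord(key=key, sample_id=sample_id, tissue=tissue, callers=callers)
        for key, callers in merged.items()
        if len(callers) >= threshold
    }
    return ConsensusSet(sample_id=sample_id, tissue=tissue, variants=variants)


def build_normal_panel(normal_consensus_sets: Iterable[ConsensusSet]) -> set[VariantKey]:
    """Union of variant keys over all normal controls in the cohort."""
    panel: set[VariantKey] = set()
    for cs in normal_consensus_sets:
        if cs.tissue is not Tissue.NORMAL:
            raise ValueError(f"panel input must be NORMAL tissue, got {cs.tissue}")
        panel |= cs.keys()
    return panel
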