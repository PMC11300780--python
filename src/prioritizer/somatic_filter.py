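"""Somatic read-support and population-frequency filters with audit traces.

Four rules, applied in print order per variant with matched-normal read
counts from the recount table:

1. ``NORMAL_VAF``  — normal VAF of 5% or more (inclusive);
2. ``ZERO_ALT``    — no tumor alt reads but more than 20 tumor ref reads
   (strict);
3. ``VAF_RATIO``   — tumor VAF strictly less than twice the normal VAF;
4. ``POPFREQ``     — maximum healthy-population allele frequency strictly
   above 1%.

A variant failing any of the three read-support rules in any sample is
blacklisted cohort-wide (two-pass semantics).  POPFREQ is key-intrinsic and
is not propagated (it fires identically everywhere).  A zero-depth normal
defines normal VAF = 0, so the ratio rule can never fire there.

Every removal is recorded as a :class:`FilterTrace`; per-stage survivor
counts are exactly reconstructible from the traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

from .consensus import ConsensusSet, build_normal_panel
from .variant_io import ReadCounts, VariantKey, VariantRecord

__all__ = [
    "Stage",
    "SomaticFilterConfig",
    "FilterTrace",
    "PASS",
    "filter_normal_panel",
    "filter_read_support",
    "propagate_blacklist",
    "filter_population_frequency",
    "run_somatic_filters",
]

PASS = "PASS"

#: Read-support rules whose failures propagate cohort-wide.
BLACKLISTABLE_RULES = ("NORMAL_VAF", "ZERO_ALT", "VAF_RATIO")


class Stage(str, Enum):
    NORMAL_PANEL = "NORMAL_PANEL"
    MISSING_COUNTS = "MISSING_COUNTS"
    NORMAL_VAF = "NORMAL_VAF"
    ZERO_ALT = "ZERO_ALT"
    VAF_RATIO = "VAF_RATIO"
    BLACKLIST = "BLACKLIST"
    POPFREQ = "POPFREQ"
    REGION = "REGION"
    SILENT = "SILENT"
    UNEXPRESSED = "UNEXPRESSED"
    PREDICTOR_VOTE = "PREDICTOR_VOTE"


@dataclass(frozen=True)
class SomaticFilterConfig:
    max_normal_vaf: float = 0.05
    min_ref_reads_for_zero_alt: int = 20
    tumor_to_normal_vaf_ratio: float = 2.0
    max_population_freq: float = 0.01

    def __post_init__(self) -> None:
        if min(self.max_normal_vaf, self.min_ref_reads_for_zero_alt, self.max_population_freq) <= 0:
            raise ValueError("all thresholds must be > 0")
        if self.tumor_to_normal_vaf_ratio < 1:
            raise ValueError("tumor_to_normal_vaf_ratio must be >= 1")


@dataclass(frozen=True)
class FilterTrace:
    """Audit record of one variant removal event."""

    key: VariantKey
    sample_id: str
    stage: Stage
    detail: str = ""


def filter_normal_panel(
    tumor_set: ConsensusSet, panel: set[VariantKey]
) -> tuple[list[VariantRecord], list[FilterTrace]]:
    """Drop tumor variants present in the panel of normals."""
    retained, traces = [], []
    for key in sorted(tumor_set.variants):
        rec = tumor_set.variants[key]
        if key in panel:
            traces.append(
                FilterTrace(key, tumor_set.sample_id, Stage.NORMAL_PANEL, "in normal panel")
            )
        else:
            retained.append(rec)
    return retained, traces


def filter_read_support(record: VariantRecord, cfg: SomaticFilterConfig) -> str:
    """Evaluate the three read-support rules in print order.

    Returns ``"PASS"`` or the identifier of the first firing rule.  All four
    read counts must be present (callers handle missing counts separately).
    """
    if not record.has_counts:
        raise ValueError(f"record {record.key} lacks read counts")
    normal_vaf = record.normal_vaf
    tumor_vaf = record.tumor_vaf
    if normal_vaf >= cfg.max_normal_vaf:
        return Stage.NORMAL_VAF.value
    if record.tumor_alt_reads == 0 and record.tumor_ref_reads > cfg.min_ref_reads_for_zero_alt:
        return Stage.ZERO_ALT.value
    if tumor_vaf < cfg.tumor_to_normal_vaf_ratio * normal_vaf:
        return Stage.VAF_RATIO.value
    return PASS


def propagate_blacklist(
    per_sample_verdicts: Mapping[str, Mapping[VariantKey, str]],
) -> tuple[dict[str, set[VariantKey]], list[FilterTrace]]:
    """Cohort-wide propagation: a key failing a read-support rule anywhere is
    removed everywhere.

    Input is the full two-pass verdict map ``sample -> key -> verdict``
    (verdicts from :func:`filter_read_support`, or ``MISSING_COUNTS``).
    Returns retained keys per sample plus traces; in the sample where a key
    failed it keeps its original stage, elsewhere stage ``BLACKLIST``.
    """
    blacklist: set[VariantKey] = set()
    for verdicts in per_sample_verdicts.values():
        for key, verdict in verdicts.items():
            if verdict in BLACKLISTABLE_RULES:
                blacklist.add(key)

    retained: dict[str, set[VariantKey]] = {}
    traces: list[FilterTrace] = []
    for sample_id, verdicts in per_sample_verdicts.items():
        kept: set[VariantKey] = set()
        for key in sorted(verdicts):
            verdict = verdicts[key]
            if verdict in BLACKLISTABLE_RULES:
                traces.append(FilterTrace(key, sample_id, Stage(verdict), "read-support rule"))
            elif verdict == Stage.MISSING_COUNTS.value:
                traces.append(
                    FilterTrace(key, sample_id, Stage.MISSING_COUNTS, "absent from counts table")
                )
            elif key in blacklist:
                traces.append(
                    FilterTrace(key, sample_id, Stage.BLACKLIST, "failed read support elsewhere")
                )
            else:
                kept.add(key)
        retained[sample_id] = kept
    return retained, traces


def filter_population_frequency(
    pop_freq_max: Optional[float], cfg: SomaticFilterConfig
) -> str:
    """Remove common polymorphisms: PopFreqMax strictly above the threshold.

    A missing PopFreqMax retains the variant (the rule cannot fire).
    """
    if pop_freq_max is None:
        return PASS
    if not 0 <= pop_freq_max <= 1:
        raise ValueError(f"pop_freq_max {pop_freq_max} outside [0, 1]")
    if pop_freq_max > cfg.max_population_freq:
        return Stage.POPFREQ.value
    return PASS


def run_somatic_filters(
    tumor_sets: Mapping[str, ConsensusSet],
    panel,
    counts: Mapping[tuple[str, VariantKey], ReadCounts],
    pop_freq_max: Mapping[VariantKey, Optional[float]],
    cfg: SomaticFilterConfig = SomaticFilterConfig(),
) -> tuple[dict[str, list[VariantRecord]], list[FilterTrace]]:
    """Run the full somatic cascade: panel → read support (two-pass with
    cohort blacklist) → population frequency.

    ``panel`` is either one cohort-wide key set or, for matched-only
    subtraction, a mapping ``sample_id -> key set``.  Returns retained
    records (with counts attached) per sample, plus all traces.  Count
    conservation holds at every stage: ``|input| = |retained| + |traces|``
    per sample.
    """
    all_traces: list[FilterTrace] = []

    # Stage 1: panel of normals.
    post_panel: dict[str, dict[VariantKey, VariantRecord]] = {}
    for sample_id, tumor_set in tumor_sets.items():
        sample_panel = panel.get(sample_id, set()) if isinstance(panel, Mapping) else panel
        retained, traces = filter_normal_panel(tumor_set, sample_panel)
        all_traces.extend(traces)
        post_panel[sample_id] = {r.key: r for r in retained}

    # Stage 2: read-support verdicts for every sample first (two-pass).
    verdicts: dict[str, dict[VariantKey, str]] = {}
    with_counts: dict[str, dict[VariantKey, VariantRecord]] = {}
    for sample_id, recs in post_panel.items():
        verdicts[sample_id] = {}
        with_counts[sample_id] = {}
        for key, rec in recs.items():
            c = counts.get((sample_id, key))
            if c is None:
                verdicts[sample_id][key] = Stage.MISSING_COUNTS.value
                with_counts[sample_id][key] = rec
            else:
                rec = rec.with_counts(c)
                with_counts[sample_id][key] = rec
                verdicts[sample_id][key] = filter_read_support(rec, cfg)

    retained_keys, traces = propagate_blacklist(verdicts)
    all_traces.extend(traces)

    # Stage 3: population frequency (key-intrinsic, no propagation needed).
    retained: dict[str, list[VariantRecord]] = {}
    for sample_id, keys in retained_keys.items():
        kept = []
        for key in sorted(keys):
            verdict = filter_population_frequency(pop_freq_max.get(key), cfg)
            if verdict == PASS:
                kept.append(with_counts[sample_id][key])
            else:
                all_traces.append(
                    FilterTrace(key, sample_id, Stage.POPFREQ, "population frequency > threshold")
                )
        retained[sample_id] = kept
    return retained, all_traces
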