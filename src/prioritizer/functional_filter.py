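"""Functional-consequence filtering of somatic variants.

Four stages in fixed order:

1. ``REGION``         — keep only protein-coding or splice-site variants;
2. ``SILENT``         — drop synonymous variants unless SPIDEX flags them as
   spliceogenic (|DPSI z| >= 2);
3. ``UNEXPRESSED``    — drop variants in genes not expressed in the tumor
   type;
4. ``PREDICTOR_VOTE`` — drop variants that at least half of the available
   deleteriousness predictors (SIFT, LRT, MutationTaster, MutationAssessor,
   FATHMM, MetaSVM) call tolerated, unless the variant is an indel or is
   SPIDEX-rescued.

Ties in the vote count toward removal; MISSING verdicts are excluded from
the denominator by default (``vote_denominator="all"`` keeps all six).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .somatic_filter import PASS, FilterTrace, Stage
from .variant_io import VariantKey, VariantRecord, normalize_variant

__all__ = [
    "RegionClass",
    "EffectClass",
    "Verdict",
    "PREDICTORS",
    "AnnotationRecord",
    "FunctionalFilterConfig",
    "filter_region",
    "filter_silent",
    "filter_expression",
    "predictor_vote",
    "run_functional_cascade",
    "read_annotation_table",
    "write_annotation_table",
]

PREDICTORS = ("SIFT", "LRT", "MutationTaster", "MutationAssessor", "FATHMM", "MetaSVM")

CODING_OR_SPLICE = frozenset({"EXONIC", "SPLICING", "EXONIC_SPLICING"})

INDEL_EFFECTS = frozenset({"FRAMESHIFT_INDEL", "INFRAME_INDEL"})


class RegionClass(str, Enum):
    EXONIC = "EXONIC"
    SPLICING = "SPLICING"
    EXONIC_SPLICING = "EXONIC_SPLICING"
    UTR = "UTR"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"
    NCRNA = "NCRNA"
    OTHER = "OTHER"


class EffectClass(str, Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    SILENT = "SILENT"
    FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
    INFRAME_INDEL = "INFRAME_INDEL"
    STOPLOSS = "STOPLOSS"
    SPLICE = "SPLICE"
    UNKNOWN = "UNKNOWN"


class Verdict(str, Enum):
    DELETERIOUS = "D"
    TOLERATED = "T"
    MISSING = "."


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant functional context from an ANNOVAR-style table."""

    key: VariantKey
    gene: str
    region_class: RegionClass
    effect_class: EffectClass
    predictor_verdicts: Mapping[str, Verdict] = field(
        default_factory=lambda: {p: Verdict.MISSING for p in PREDICTORS}
    )
    spidex_dpsi_z: Optional[float] = None
    pop_freq_max: Optional[float] = None

    def __post_init__(self) -> None:
        if set(self.predictor_verdicts) != set(PREDICTORS):
            raise ValueError(
                f"predictor_verdicts must key exactly {PREDICTORS}, "
                f"got {sorted(self.predictor_verdicts)}"
            )
        if self.effect_class.value in INDEL_EFFECTS and not self.key.is_indel:
            raise ValueError(
                f"{self.key}: effect {self.effect_class.value} requires unequal allele lengths"
            )


@dataclass
class FunctionalFilterConfig:
    spidex_z_threshold: float = 2.0
    expressed_genes: frozenset = frozenset()
    min_predictors_for_vote: int = 1
    vote_denominator: str = "available"  # or "all"
    case_insensitive_genes: bool = False
    exempt_truncating: bool = False  # exempt NONSENSE/SPLICE from the vote

    def __post_init__(self) -> None:
        if self.spidex_z_threshold <= 0:
            raise ValueError("spidex_z_threshold must be > 0")
        if self.vote_denominator not in ("available", "all"):
            raise ValueError("vote_denominator must be 'available' or 'all'")
        if self.case_insensitive_genes:
            self.expressed_genes = frozenset(g.upper() for g in self.expressed_genes)


def _spidex_rescued(ann: AnnotationRecord, cfg: FunctionalFilterConfig) -> bool:
    return ann.spidex_dpsi_z is not None and abs(ann.spidex_dpsi_z) >= cfg.spidex_z_threshold


def filter_region(ann: AnnotationRecord) -> str:
    """Keep only protein-coding or splice-site variants."""
    if ann.region_class.value in CODING_OR_SPLICE:
        return PASS
    return Stage.REGION.value


def filter_silent(ann: AnnotationRecord, cfg: FunctionalFilterConfig) -> str:
    """Drop synonymous variants without a spliceogenic SPIDEX rescue."""
    if ann.effect_class is EffectClass.SILENT and not _spidex_rescued(ann, cfg):
        return Stage.SILENT.value
    return PASS


def filter_expression(ann: AnnotationRecord, cfg: FunctionalFilterConfig) -> str:
    """Drop variants in genes not expressed in this tumor type."""
    if not cfg.expressed_genes:
        raise ValueError("expressed_genes is empty; this would remove every variant")
    gene = ann.gene.upper() if cfg.case_insensitive_genes else ann.gene
    if gene in cfg.expressed_genes:
        return PASS
    return Stage.UNEXPRESSED.value


def predictor_vote(ann: AnnotationRecord, cfg: FunctionalFilterConfig) -> str:
    """Majority vote over deleteriousness predictors, with overrides.

    Retained outright when the variant is an indel or SPIDEX-rescued
    (and optionally when truncating, off by default).  Otherwise with
    A = predictors in the denominator and T = TOLERATED verdicts, the
    variant is removed iff ``A >= min_predictors_for_vote`` and
    ``T >= ceil(A/2)`` — "at least half call it tolerable".
    """
    if ann.effect_class.value in INDEL_EFFECTS or _spidex_rescued(ann, cfg):
        return PASS
    if cfg.exempt_truncating and ann.effect_class in (EffectClass.NONSENSE, EffectClass.SPLICE):
        return PASS
    verdicts = [ann.predictor_verdicts[p] for p in PREDICTORS]
    if cfg.vote_denominator == "available":
        available = sum(1 for v in verdicts if v is not Verdict.MISSING)
    else:
        available = len(PREDICTORS)
    tolerated = sum(1 for v in verdicts if v is Verdict.TOLERATED)
    if available >= cfg.min_predictors_for_vote and tolerated >= math.ceil(available / 2):
        return Stage.PREDICTOR_VOTE.value
    return PASS


def run_functional_cascade(
    records: Mapping[str, Sequence[VariantRecord]],
    annotations: Mapping[VariantKey, AnnotationRecord],
    cfg: FunctionalFilterConfig,
) -> tuple[dict[str, list[VariantRecord]], list[FilterTrace]]:
    """Apply region → silent → expression → predictor vote, in order.

    Every somatic variant must be annotated; missing keys abort with the
    full offending list.
    """
    missing = sorted(
        {r.key for recs in records.values() for r in recs} - set(annotations)
    )
    if missing:
        raise ValueError(
            f"{len(missing)} somatic variant(s) lack annotation: "
            + ", ".join(str(k) for k in missing[:10])
            + ("…" if len(missing) > 10 else "")
        )

    stages = (
        ("REGION", lambda ann: filter_region(ann)),
        ("SILENT", lambda ann: filter_silent(ann, cfg)),
        ("UNEXPRESSED", lambda ann: filter_expression(ann, cfg)),
        ("PREDICTOR_VOTE", lambda ann: predictor_vote(ann, cfg)),
    )
    retained: dict[str, list[VariantRecord]] = {}
    traces: list[FilterTrace] = []
    for sample_id, recs in records.items():
        kept = []
        for rec in sorted(recs, key=lambda r: r.key):
            ann = annotations[rec.key]
            for stage_name, rule in stages:
                verdict = rule(ann)
                if verdict != PASS:
                    traces.append(FilterTrace(rec.key, sample_id, Stage(verdict), ann.gene))
                    break
            else:
                kept.append(rec)
        retained[sample_id] = kept
    return retained, traces


# ---------------------------------------------------------------------------
# Annotation table I/O (one column per predictor, verdict letters D/T/.)
# ---------------------------------------------------------------------------

_ANN_FIXED = ["chrom", "pos", "ref", "alt", "gene", "region", "effect"]
_ANN_TAIL = ["spidex_dpsi_z", "pop_freq_max"]


def read_annotation_table(path) -> dict[VariantKey, AnnotationRecord]:
    """Read the ANNOVAR-style annotation TSV keyed by normalized variant."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    required = _ANN_FIXED + list(PREDICTORS) + _ANN_TAIL
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out: dict[VariantKey, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        key = normalize_variant(
            VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        )
        verdicts = {p: Verdict(getattr(row, p)) for p in PREDICTORS}
        z = getattr(row, "spidex_dpsi_z")
        pf = getattr(row, "pop_freq_max")
        out[key] = AnnotationRecord(
            key=key,
            gene=str(row.gene),
            region_class=RegionClass(str(row.region)),
            effect_class=EffectClass(str(row.effect)),
            predictor_verdicts=verdicts,
            spidex_dpsi_z=None if z in (".", "") else float(z),
            pop_freq_max=None if pf in (".", "") else float(pf),
        )
    return out


def write_annotation_table(annotations: Mapping[VariantKey, AnnotationRecord], path) -> None:
    """Write annotations in the schema :func:`read_annotation_table` expects."""
    rows = []
    for key in sorted(annotations):
        a = annotations[key]
        row = {
            "chrom": key.chrom,
            "pos": key.pos,
            "ref": key.ref,
            "alt": key.alt,
            "gene": a.gene,
            "region": a.region_class.value,
            "effect": a.effect_class.value,
        }
        for p in PREDICTORS:
            row[p] = a.predictor_verdicts[p].value
        row["spidex_dpsi_z"] = "." if a.spidex_dpsi_z is None else repr(a.spidex_dpsi_z)
        row["pop_freq_max"] = "." if a.pop_freq_max is None else repr(a.pop_freq_max)
        rows.append(row)
    pd.DataFrame(rows, columns=_ANN_FIXED + list(PREDICTORS) + _ANN_TAIL).to_csv(
        path, sep="\t", index=False
    )
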