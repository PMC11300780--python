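"""Readers/writers for the external formats and canonical variant normalization.

Every downstream stage operates on one in-memory representation: a
:class:`VariantKey` (normalized ``chrom, pos, ref, alt``) carried inside a
:class:`VariantRecord` together with caller support and tumor/normal read
counts.  Coordinates are 1-based inclusive everywhere internally (VCF-native);
BED is converted at the boundary.

Chromosome names are compared as verbatim strings; no silent harmonization of
``chr`` prefixes is performed (``strip_chr_prefix`` on the readers opts in).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "Tissue",
    "CALLERS",
    "VariantKey",
    "ReadCounts",
    "VariantRecord",
    "Segment",
    "GeneInterval",
    "VcfParseError",
    "normalize_variant",
    "read_caller_vcf",
    "read_counts_table",
    "read_seg",
    "read_gene_bed",
    "write_maf_like",
    "read_maf_like",
]

#: Caller identifiers recognised by the consensus stage.
CALLERS = ("bcftools", "varscan", "freebayes")

_BASES = frozenset("ACGTN")


class Tissue(str, Enum):
    TUMOR = "TUMOR"
    NORMAL = "NORMAL"


class VcfParseError(ValueError):
    """Raised for a structurally malformed VCF data line."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized variant identity: ``(chrom, pos, ref, alt)``.

    ``pos`` is the 1-based position of the first reference base.  Keys are
    totally ordered by ``(chrom, pos, ref, alt)`` with chromosomes compared
    as verbatim strings.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class ReadCounts:
    """Tumor/normal ref/alt read counts for one (sample, variant)."""

    tumor_ref: int
    tumor_alt: int
    normal_ref: int
    normal_alt: int

    def __post_init__(self) -> None:
        for name in ("tumor_ref", "tumor_alt", "normal_ref", "normal_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative read count {name}={getattr(self, name)}")

    @property
    def tumor_vaf(self) -> float:
        d = self.tumor_ref + self.tumor_alt
        return self.tumor_alt / d if d else 0.0

    @property
    def normal_vaf(self) -> float:
        d = self.normal_ref + self.normal_alt
        return self.normal_alt / d if d else 0.0


@dataclass
class VariantRecord:
    """A variant observed in one sample, with caller support and read counts."""

    key: VariantKey
    sample_id: str
    tissue: Tissue
    callers: frozenset = frozenset()
    tumor_ref_reads: Optional[int] = None
    tumor_alt_reads: Optional[int] = None
    normal_ref_reads: Optional[int] = None
    normal_alt_reads: Optional[int] = None
    status: str = "PASS"
    removal_rule: Optional[str] = None

    @property
    def tumor_vaf(self) -> float:
        d = (self.tumor_ref_reads or 0) + (self.tumor_alt_reads or 0)
        return (self.tumor_alt_reads or 0) / d if d else 0.0

    @property
    def normal_vaf(self) -> float:
        d = (self.normal_ref_reads or 0) + (self.normal_alt_reads or 0)
        return (self.normal_alt_reads or 0) / d if d else 0.0

    @property
    def has_counts(self) -> bool:
        return None not in (
            self.tumor_ref_reads,
            self.tumor_alt_reads,
            self.normal_ref_reads,
            self.normal_alt_reads,
        )

    def with_counts(self, counts: ReadCounts) -> "VariantRecord":
        return replace(
            self,
            tumor_ref_reads=counts.tumor_ref,
            tumor_alt_reads=counts.tumor_alt,
            normal_ref_reads=counts.normal_ref,
            normal_alt_reads=counts.normal_alt,
        )


@dataclass(frozen=True)
class Segment:
    """One copy-number segment (1-based inclusive coordinates, log2 ratio mean)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    seg_mean: float
    n_markers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneInterval:
    """Spanning genomic interval of one gene symbol (1-based inclusive)."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene interval start > end: {self}")


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

ReferenceContext = Callable[[str, int, int], str]
"""``(chrom, start, end) -> bases`` with 1-based inclusive coordinates."""


def normalize_variant(
    key: VariantKey, reference_context: Optional[ReferenceContext] = None
) -> VariantKey:
    """Canonicalize a variant: trim shared suffix, then prefix, left-align indels.

    The shared suffix is trimmed first, then the shared prefix with ``pos``
    advanced accordingly; at most a single anchor base is kept for indels.
    When ``reference_context`` is supplied, indels are additionally
    left-aligned to their 5'-most equivalent position.  The operation is
    idempotent.

    Raises ``ValueError`` when ref equals alt, or when trimming would consume
    an allele entirely with no reference available to recover an anchor base.
    """
    chrom, pos, ref, alt = key.chrom, key.pos, key.ref, key.alt
    if ref == alt:
        raise ValueError(f"ref == alt at {chrom}:{pos}")

    if reference_context is None:
        # Suffix then prefix trimming only, keeping >= 1 base on each side.
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        if not ref or not alt:
            raise ValueError(
                f"cannot normalize {key}: allele emptied and no reference supplied"
            )
        return VariantKey(chrom, pos, ref, alt)

    # With a reference: full left-alignment (vt-style).
    while True:
        if ref and alt and ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
            ref, alt = ref[:-1], alt[:-1]
        elif not ref or not alt:
            if pos <= 1:
                raise ValueError(f"cannot left-align {key} past position 1")
            base = reference_context(chrom, pos - 1, pos - 1)
            ref, alt = base + ref, base + alt
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _validate_vcf_lines(path: Path) -> None:
    """Structural pre-check so malformed data lines fail loudly with a line number.

    htslib coerces an unparsable POS to 1 with only a logged warning, which
    would silently corrupt variant identity downstream.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated fields"
                )
            if not fields[1].isdigit():
                raise VcfParseError(
                    f"{path}: line {lineno}: POS {fields[1]!r} is not an integer"
                )
            if not fields[3] or not fields[4]:
                raise VcfParseError(f"{path}: line {lineno}: empty REF or ALT")


def read_caller_vcf(
    path,
    caller: str,
    sample_id: str,
    tissue: Tissue,
    reference_context: Optional[ReferenceContext] = None,
) -> list[VariantRecord]:
    """Read one caller's VCF into normalized, sorted :class:`VariantRecord` s.

    Multi-allelic rows are split into one record per alternate allele; every
    returned record carries ``callers={caller}``.  Unknown contigs are passed
    through verbatim (not an error).
    """
    path = Path(path)
    _validate_vcf_lines(path)
    records: list[VariantRecord] = []
    with warnings.catch_warnings():
        # htslib warns about contigs missing from the header; harmless here.
        warnings.simplefilter("ignore")
        vcf = VCF(str(path))
        for v in vcf:
            for alt in v.ALT:
                if alt in (".", "*") or alt.startswith("<"):
                    continue  # symbolic / spanning-deletion alleles carry no key
                key = normalize_variant(
                    VariantKey(v.CHROM, v.POS, v.REF, alt), reference_context
                )
                records.append(
                    VariantRecord(
                        key=key,
                        sample_id=sample_id,
                        tissue=tissue,
                        callers=frozenset({caller}),
                    )
                )
        vcf.close()
    records.sort(key=lambda r: r.key)
    return records


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

_COUNTS_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "tumor_ref",
    "tumor_alt",
    "normal_ref",
    "normal_alt",
]


def read_counts_table(path) -> dict[tuple[str, VariantKey], ReadCounts]:
    """Read the per-variant read-count (recount) table.

    Tab-delimited with header ``sample chrom pos ref alt tumor_ref tumor_alt
    normal_ref normal_alt``.  Keys are normalized on load; duplicate
    (sample, key) rows and negative counts are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in _COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out: dict[tuple[str, VariantKey], ReadCounts] = {}
    for row in df.itertuples(index=False):
        key = normalize_variant(
            VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        )
        ident = (str(row.sample), key)
        if ident in out:
            raise ValueError(f"{path}: duplicate counts row for {row.sample} {key}")
        out[ident] = ReadCounts(
            int(row.tumor_ref), int(row.tumor_alt), int(row.normal_ref), int(row.normal_alt)
        )
    return out


def read_seg(path) -> list[Segment]:
    """Read a SEG segmentation file (sample, chrom, start, end, [n_markers], seg_mean).

    Overlapping segments within one (sample, chrom) are an input error; the
    offending rows are listed in the exception.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"sample", "chrom", "start", "end", "seg_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    has_markers = "n_markers" in df.columns
    segments = [
        Segment(
            sample_id=str(r.sample),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            seg_mean=float(r.seg_mean),
            n_markers=int(r.n_markers) if has_markers else None,
        )
        for r in df.itertuples(index=False)
    ]
    by_group: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        by_group.setdefault((s.sample_id, s.chrom), []).append(s)
    offending = []
    for group in by_group.values():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                offending.append((a, b))
    if offending:
        lines = "; ".join(f"{a} overlaps {b}" for a, b in offending)
        raise ValueError(f"{path}: overlapping segments: {lines}")
    return segments


def read_gene_bed(path) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open on disk).

    Coordinates convert to the 1-based inclusive internal convention
    (start+1).  Multi-interval genes collapse to their spanning interval.
    """
    raw: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 4 columns")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) >= 6 else "."
            raw.setdefault(gene, []).append((chrom, start + 1, end, strand))
    intervals = []
    for gene, pieces in raw.items():
        chroms = {p[0] for p in pieces}
        if len(chroms) > 1:
            raise ValueError(f"{path}: gene {gene} spans chromosomes {sorted(chroms)}")
        intervals.append(
            GeneInterval(
                gene=gene,
                chrom=pieces[0][0],
                start=min(p[1] for p in pieces),
                end=max(p[2] for p in pieces),
                strand=pieces[0][3],
            )
        )
    return intervals


# ---------------------------------------------------------------------------
# MAF-like output
# ---------------------------------------------------------------------------

_MAF_COLUMNS = [
    "sample",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "effect",
    "callers",
    "tumor_ref",
    "tumor_alt",
    "normal_ref",
    "normal_alt",
    "tumor_vaf",
    "normal_vaf",
    "filter_provenance",
]


def write_maf_like(
    rows: Iterable[Mapping[str, object]], path
) -> None:
    """Write the retained-variant table as a MAF-like TSV.

    One row per retained functional variant; expects mappings with the
    columns ``sample gene chrom pos ref alt effect callers tumor_ref
    tumor_alt normal_ref normal_alt tumor_vaf normal_vaf filter_provenance``.
    Floats are serialized with ``repr`` so a re-read is bit-exact.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MAF_COLUMNS)
        for row in rows:
            w.writerow(
                [repr(row[c]) if isinstance(row[c], float) else row[c] for c in _MAF_COLUMNS]
            )


def read_maf_like(path) -> list[dict[str, object]]:
    """Re-read a MAF-like TSV written by :func:`write_maf_like`."""
    out = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            rec: dict[str, object] = dict(row)
            for col in ("pos", "tumor_ref", "tumor_alt", "normal_ref", "normal_alt"):
                rec[col] = int(rec[col])
            for col in ("tumor_vaf", "normal_vaf"):
                rec[col] = float(rec[col])
            out.append(rec)
    return out


def records_to_maf_rows(
    records: Sequence[VariantRecord],
    gene_of: Mapping[VariantKey, str],
    effect_of: Mapping[VariantKey, str],
) -> list[dict[str, object]]:
    """Assemble MAF-like rows from retained records plus annotation lookups."""
    rows = []
    for r in sorted(records, key=lambda r: (r.sample_id, r.key)):
        rows.append(
            {
                "sample": r.sample_id,
                "gene": gene_of.get(r.key, "."),
                "chrom": r.key.chrom,
                "pos": r.key.pos,
                "ref": r.key.ref,
                "alt": r.key.alt,
                "effect": effect_of.get(r.key, "."),
                "callers": ",".join(sorted(r.callers)),
                "tumor_ref": r.tumor_ref_reads or 0,
                "tumor_alt": r.tumor_alt_reads or 0,
                "normal_ref": r.normal_ref_reads or 0,
                "normal_alt": r.normal_alt_reads or 0,
                "tumor_vaf": r.tumor_vaf,
                "normal_vaf": r.normal_vaf,
                "filter_provenance": r.status,
            }
        )
    return rows
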