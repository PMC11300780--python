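"""Truth-labelled synthetic tumor/normal cohort generator.

Emulates the study design this pipeline targets: a panel of tumor/normal
pairs (default 15) exome-called by three variant callers, with planted
somatic and germline variants, binomial read counts at configurable depth,
per-caller detection error, ANNOVAR-style annotations consistent with the
planted effect classes, and copy-number profiles containing engineered
one-hit and two-hit tumor-suppressor configurations (including a 6q-like
deleted region harbouring the designated tumor-suppressor gene).

The synthetic genome is 6 chromosomes of 50 Mb carrying 1,998 genes of
10 kb every 150 kb.  Designated genes (the engineered candidates and the
two-hit tumor suppressor) receive only engineered variants, so the truth
labels stay exact; background somatic variants avoid them.

Every emitted variant is traceable to exactly one truth record.  All
randomness flows from a single seed with per-sample substreams, so adding a
sample does not perturb earlier samples' draws and a fixed seed yields a
byte-identical file tree.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .functional_filter import (
    PREDICTORS,
    AnnotationRecord,
    EffectClass,
    RegionClass,
    Verdict,
    write_annotation_table,
)
from .twohit import AlterationStatus, Mechanism
from .variant_io import CALLERS, GeneInterval, Segment, VariantKey

__all__ = [
    "CallerProfile",
    "CnEvent",
    "CohortSpec",
    "VariantTruth",
    "TruthLabels",
    "CohortPaths",
    "generate_cohort",
    "expected_recovery",
    "RecoveryExpectation",
    "default_gene_catalog",
]

# Synthetic genome layout.
CHROMS = tuple(f"chr{i}" for i in range(1, 7))
CHROM_LENGTH = 50_000_000
GENES_PER_CHROM = 333
GENE_LENGTH = 10_000
GENE_SPACING = 150_000

ORIGIN_SOMATIC = "SOMATIC"
ORIGIN_GERMLINE = "GERMLINE"
ORIGIN_CALLER_FP = "CALLER_FP"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CODING_REGIONS = {"EXONIC", "SPLICING", "EXONIC_SPLICING"}


def default_gene_catalog() -> list[GeneInterval]:
    """1,998 genes (G0001..G1998) laid out deterministically on 6 chromosomes."""
    genes = []
    idx = 1
    for chrom in CHROMS:
        for j in range(GENES_PER_CHROM):
            start = 100_001 + j * GENE_SPACING
            genes.append(
                GeneInterval(
                    gene=f"G{idx:04d}",
                    chrom=chrom,
                    start=start,
                    end=start + GENE_LENGTH - 1,
                    strand="+",
                )
            )
            idx += 1
    return genes


@dataclass(frozen=True)
class CallerProfile:
    sensitivity: float
    false_positives_per_sample: int

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.false_positives_per_sample < 0:
            raise ValueError("false_positives_per_sample must be >= 0")


@dataclass(frozen=True)
class CnEvent:
    """An engineered copy-number event applied to a subset of samples."""

    chrom: str
    start: int
    end: int
    seg_mean: float
    sample_indices: tuple[int, ...]


def _default_caller_profiles() -> dict[str, CallerProfile]:
    return {
        "bcftools": CallerProfile(0.95, 20),
        "varscan": CallerProfile(0.90, 20),
        "freebayes": CallerProfile(0.85, 20),
    }


def _default_effect_mix() -> dict[str, float]:
    # ~60% of somatic variants land in coding/splice territory, matching a
    # mean of ~120 coding variants per tumor at 200 somatic draws.
    return {
        "NONCODING": 0.40,
        "MISSENSE": 0.27,
        "SILENT": 0.18,
        "NONSENSE": 0.04,
        "FRAMESHIFT_INDEL": 0.05,
        "INFRAME_INDEL": 0.02,
        "SPLICE": 0.04,
    }


def _default_spectrum_mix() -> dict[str, float]:
    # C>T-heavy, C>A-poor: a never-smoker-like spectrum.
    return {"C>A": 0.08, "C>G": 0.08, "C>T": 0.35, "T>A": 0.12, "T>C": 0.25, "T>G": 0.12}


# Default engineered candidate genes, chosen away from the CN events below
# (asserted in CohortSpec.validate).  The designated two-hit tumor
# suppressor G1800 sits inside the 6q-like deleted region.
_DEFAULT_CANDIDATES = (
    "G0050",
    "G0140",
    "G0420",
    "G0760",
    "G1100",
    "G1430",
    "G1700",
    "G1800",
)
_DEFAULT_TSG = "G1800"
_DEFAULT_CENSUS = ("G0050", "G0420")

# 6q-like single-copy deletion: chr6:10,000,001-30,000,000 (covers G1800,
# which spans chr6:20,200,001-20,210,000).
_SIXQ = (10_000_001, 30_000_000)
# Focal homozygous deletion around G1800.
_TSG_DEEPDEL = (20_150_001, 20_250_000)


def _default_cn_events() -> list[CnEvent]:
    return [
        CnEvent("chr6", *_TSG_DEEPDEL, -1.5, (0, 1)),
        CnEvent("chr6", *_SIXQ, -0.8, (4, 5, 7, 8, 9)),
        CnEvent("chr1", 1_000_001, 3_000_000, 1.0, (10, 11)),
    ]


def _default_twohit_plan() -> dict[int, Mechanism]:
    return {
        0: Mechanism.DEEP_DELETION,
        1: Mechanism.DEEP_DELETION,
        2: Mechanism.HOMOZYGOUS_MUTATION,
        3: Mechanism.HOMOZYGOUS_MUTATION,
        4: Mechanism.HET_MUTATION_PLUS_LOSS,
        5: Mechanism.HET_MUTATION_PLUS_LOSS,
        6: Mechanism.MUTATION_ONLY,
        7: Mechanism.LOSS_ONLY,
    }


@dataclass
class CohortSpec:
    """Generator configuration; the defaults define the emulated study."""

    n_pairs: int = 15
    somatic_per_tumor_mean: float = 200.0
    somatic_per_tumor_dispersion: float = 10.0  # negative-binomial size
    germline_pool_size: int = 800
    germline_per_sample: int = 400
    depth_tumor: float = 100.0
    depth_normal: float = 100.0
    somatic_vaf_alpha: float = 2.0
    somatic_vaf_beta: float = 5.0
    min_detectable_vaf: float = 0.15
    caller_profiles: dict[str, CallerProfile] = field(default_factory=_default_caller_profiles)
    effect_mix: dict[str, float] = field(default_factory=_default_effect_mix)
    silent_spliceogenic_rate: float = 0.10
    predictor_concordance: float = 0.90
    predictor_missing_rate: float = 0.10
    popfreq_contaminant_rate: float = 0.10  # germline sites with pop freq > 1%
    somatic_popfreq_contaminant_rate: float = 0.02
    expressed_fraction: float = 0.80
    spectrum_mix: dict[str, float] = field(default_factory=_default_spectrum_mix)
    genes: list[GeneInterval] = field(default_factory=default_gene_catalog)
    candidate_genes: tuple[str, ...] = _DEFAULT_CANDIDATES
    tsg_gene: str = _DEFAULT_TSG
    census_genes: tuple[str, ...] = _DEFAULT_CENSUS
    cn_events: list[CnEvent] = field(default_factory=_default_cn_events)
    twohit_plan: dict[int, Mechanism] = field(default_factory=_default_twohit_plan)
    het_plant_vaf: float = 0.35
    hom_plant_vaf: float = 0.90
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for name in (
            "silent_spliceogenic_rate",
            "predictor_concordance",
            "predictor_missing_rate",
            "popfreq_contaminant_rate",
            "somatic_popfreq_contaminant_rate",
            "expressed_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.effect_mix.values()) - 1) > 1e-9:
            raise ValueError("effect_mix must sum to 1")
        if abs(sum(self.spectrum_mix.values()) - 1) > 1e-9:
            raise ValueError("spectrum_mix must sum to 1")
        by_name = {g.gene: g for g in self.genes}
        if self.tsg_gene not in by_name:
            raise ValueError(f"tsg_gene {self.tsg_gene} not in catalog")
        for g in self.candidate_genes:
            if g not in by_name:
                raise ValueError(f"candidate gene {g} not in catalog")
        # Designated genes other than the tumor suppressor must sit outside
        # every engineered CN event, so their truth status stays exact.
        for gname in self.candidate_genes:
            if gname == self.tsg_gene:
                continue
            g = by_name[gname]
            for ev in self.cn_events:
                if ev.chrom == g.chrom and not (g.end < ev.start or g.start > ev.end):
                    raise ValueError(f"candidate {gname} overlaps CN event {ev}")
        for idx in self.twohit_plan:
            if not 0 <= idx < self.n_pairs:
                raise ValueError(f"twohit_plan sample index {idx} out of range")

    def sample_id(self, idx: int) -> str:
        return f"S{idx + 1:02d}"


@dataclass(frozen=True)
class VariantTruth:
    """Ground truth for one emitted variant occurrence."""

    sample_id: str
    key: VariantKey
    origin: str  # SOMATIC | GERMLINE | CALLER_FP
    gene: str  # "." when intergenic
    region: str
    effect: str
    deleterious: bool
    spliceogenic: bool
    planted_vaf: float
    pop_freq_max: Optional[float]
    functional: bool  # expected to survive the full cascade (see docs)


@dataclass
class TruthLabels:
    variants: list[VariantTruth]
    gene_status: dict[tuple[str, str], AlterationStatus]
    gene_mechanism: dict[tuple[str, str], frozenset]
    expressed_genes: frozenset

    def keys_for(self, sample_id: str, origin: Optional[str] = None) -> set[VariantKey]:
        return {
            v.key
            for v in self.variants
            if v.sample_id == sample_id and (origin is None or v.origin == origin)
        }

    def functional_keys(self, sample_id: str) -> set[VariantKey]:
        return {
            v.key for v in self.variants if v.sample_id == sample_id and v.functional
        }


@dataclass(frozen=True)
class CohortPaths:
    outdir: Path
    vcf_dir: Path
    counts: Path
    annotations: Path
    expressed_genes: Path
    seg: Path
    bed: Path
    external_counts: Path
    census: Path
    gene_sets: Path
    capture_counts: Path
    truth_variants: Path
    truth_gene_status: Path

    def vcf(self, sample_id: str, tissue: str, caller: str) -> Path:
        return self.vcf_dir / f"{sample_id}_{tissue.lower()}_{caller}.vcf"


# ---------------------------------------------------------------------------
# Draw helpers
# ---------------------------------------------------------------------------


def _draw_snv_alleles(rng: np.random.Generator, spectrum: Mapping[str, float]) -> tuple[str, str]:
    classes = sorted(spectrum)
    probs = np.array([spectrum[c] for c in classes])
    cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
    ref, alt = cls.split(">")
    if rng.random() < 0.5:  # purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _draw_indel_alleles(rng: np.random.Generator, inframe: bool) -> tuple[str, str]:
    n = 3 if inframe else int(rng.integers(1, 3))
    if not inframe and n % 3 == 0:
        n = 1
    anchor = "ACGT"[rng.integers(4)]
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
    if rng.random() < 0.5:
        return anchor + seq, anchor  # deletion
    return anchor, anchor + seq  # insertion


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # Negative binomial parameterized by mean and size (dispersion).
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


class _Generator:
    def __init__(self, spec: CohortSpec):
        spec.validate()
        self.spec = spec
        self.genes = spec.genes
        self.by_name = {g.gene: g for g in self.genes}
        self.designated = frozenset(spec.candidate_genes) | {spec.tsg_gene}
        self.background_genes = [g for g in self.genes if g.gene not in self.designated]
        self.annotations: dict[VariantKey, AnnotationRecord] = {}
        self.truth_variants: list[VariantTruth] = []
        self.counts_rows: list[tuple] = []
        self.capture_rows: list[tuple] = []
        self.calls: dict[tuple[str, str, str], list[VariantKey]] = {}
        self.segments: list[Segment] = []
        self.gene_status: dict[tuple[str, str], AlterationStatus] = {}
        self.gene_mechanism: dict[tuple[str, str], frozenset] = {}

        root = np.random.default_rng([spec.seed, 0])
        self.expressed = self._draw_expressed(root)
        self.germline_pool = self._build_germline_pool(np.random.default_rng([spec.seed, 1]))
        self.external_counts = self._draw_external_counts(np.random.default_rng([spec.seed, 2]))
        self.gene_sets = self._build_gene_sets(np.random.default_rng([spec.seed, 3]))

    # -- cohort-level structures -------------------------------------------

    def _draw_expressed(self, rng: np.random.Generator) -> frozenset:
        expressed = {
            g.gene for g in self.genes if rng.random() < self.spec.expressed_fraction
        }
        expressed |= self.designated  # engineered genes are always expressed
        return frozenset(expressed)

    def _draw_external_counts(self, rng: np.random.Generator) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.genes:
            if g.gene in self.designated:
                counts[g.gene] = int(rng.integers(3, 31))
            elif rng.random() < 0.3:
                counts[g.gene] = int(rng.integers(1, 3))
        return counts

    def _build_gene_sets(self, rng: np.random.Generator) -> dict[str, list[str]]:
        names = [g.gene for g in self.genes]
        sets: dict[str, list[str]] = {}
        # One term deliberately covering most designated genes, so per-sample
        # enrichment of candidate genes has a recurrent signal.
        core = sorted(self.designated)[:6]
        filler = [n for n in names if n not in self.designated]
        sets["SET_GENOME_STABILITY"] = sorted(
            core + list(rng.choice(filler, size=30, replace=False))
        )
        for i in range(7):
            sets[f"SET_{i + 1:02d}"] = sorted(
                rng.choice(names, size=int(rng.integers(20, 60)), replace=False)
            )
        return sets

    def _build_germline_pool(self, rng: np.random.Generator) -> list[dict]:
        pool = []
        positions: set[tuple[str, int]] = set()
        for _ in range(self.spec.germline_pool_size):
            key, gene, region, effect = self._draw_site(rng, allow_designated=False)
            while (key.chrom, key.pos) in positions:
                key, gene, region, effect = self._draw_site(rng, allow_designated=False)
            positions.add((key.chrom, key.pos))
            if rng.random() < self.spec.popfreq_contaminant_rate:
                pf: Optional[float] = float(rng.uniform(0.02, 0.5))
            elif rng.random() < 0.5:
                pf = float(rng.uniform(0.0, 0.01))
            else:
                pf = None
            deleterious = effect in ("NONSENSE", "FRAMESHIFT_INDEL") or (
                effect == "MISSENSE" and rng.random() < 0.2
            )
            self._annotate(rng, key, gene, region, effect, deleterious, spliceogenic=False, pop=pf)
            pool.append(
                {"key": key, "gene": gene, "region": region, "effect": effect,
                 "deleterious": deleterious, "pop": pf}
            )
        return pool

    # -- site drawing -------------------------------------------------------

    def _draw_site(
        self, rng: np.random.Generator, allow_designated: bool, effect: Optional[str] = None
    ) -> tuple[VariantKey, str, str, str]:
        """Draw (key, gene, region, effect) for one background variant."""
        if effect is None:
            mix = self.spec.effect_mix
            cats = sorted(mix)
            probs = np.array([mix[c] for c in cats])
            effect = cats[rng.choice(len(cats), p=probs / probs.sum())]
        if effect == "NONCODING":
            region = ("INTRONIC", "UTR", "INTERGENIC", "NCRNA")[
                rng.choice(4, p=[0.5, 0.2, 0.2, 0.1])
            ]
            chrom = CHROMS[rng.integers(len(CHROMS))]
            pos = int(rng.integers(1, CHROM_LENGTH))
            gene = "."
            eff_out = "UNKNOWN"
        else:
            pool = self.genes if allow_designated else self.background_genes
            g = pool[rng.integers(len(pool))]
            chrom = g.chrom
            pos = int(rng.integers(g.start, g.end + 1))
            gene = g.gene
            region = "SPLICING" if effect == "SPLICE" else "EXONIC"
            eff_out = effect
        if effect in ("FRAMESHIFT_INDEL", "INFRAME_INDEL"):
            ref, alt = _draw_indel_alleles(rng, inframe=(effect == "INFRAME_INDEL"))
        else:
            ref, alt = _draw_snv_alleles(rng, self.spec.spectrum_mix)
        return VariantKey(chrom, pos, ref, alt), gene, region, eff_out

    def _annotate(
        self,
        rng: np.random.Generator,
        key: VariantKey,
        gene: str,
        region: str,
        effect: str,
        deleterious: bool,
        spliceogenic: bool,
        pop: Optional[float],
    ) -> Optional[float]:
        """Build an AnnotationRecord consistent with planted truth; returns z."""
        if key in self.annotations:
            return self.annotations[key].spidex_dpsi_z
        spec = self.spec
        if key.is_indel:
            verdicts = {p: Verdict.MISSING for p in PREDICTORS}
        else:
            verdicts = {}
            for p in PREDICTORS:
                if rng.random() < spec.predictor_missing_rate:
                    verdicts[p] = Verdict.MISSING
                else:
                    correct = rng.random() < spec.predictor_concordance
                    says_d = deleterious if correct else not deleterious
                    verdicts[p] = Verdict.DELETERIOUS if says_d else Verdict.TOLERATED
        if spliceogenic:
            z: Optional[float] = float(rng.uniform(2.0, 4.0) * (1 if rng.random() < 0.5 else -1))
        elif rng.random() < 0.5:
            z = float(np.clip(rng.normal(0, 0.8), -1.9, 1.9))
        else:
            z = None
        self.annotations[key] = AnnotationRecord(
            key=key,
            gene=gene,
            region_class=RegionClass(region),
            effect_class=EffectClass(effect if effect != "NONCODING" else "UNKNOWN"),
            predictor_verdicts=verdicts,
            spidex_dpsi_z=z,
            pop_freq_max=pop,
        )
        return z

    # -- per-sample generation ---------------------------------------------

    def _functional_flag(
        self, region: str, effect: str, gene: str, deleterious: bool,
        z: Optional[float], pop: Optional[float],
    ) -> bool:
        """Expected survival of the full cascade, from planted truth.

        Mirrors the filter definitions; exact only when the predictor
        concordance is 1 and the missing rate 0 (no-noise specs).
        """
        if region not in _CODING_REGIONS:
            return False
        if gene != "." and gene not in self.expressed:
            return False
        if pop is not None and pop > 0.01:
            return False
        rescued = z is not None and abs(z) >= 2.0
        if effect in ("FRAMESHIFT_INDEL", "INFRAME_INDEL"):
            return True
        if effect == "SILENT":
            return rescued
        return rescued or deleterious

    def _plant_somatic(
        self,
        rng: np.random.Generator,
        sample_id: str,
        used: set[tuple[str, int]],
        key: VariantKey,
        gene: str,
        region: str,
        effect: str,
        deleterious: bool,
        spliceogenic: bool,
        vaf: float,
        pop: Optional[float],
    ) -> VariantTruth:
        z = self._annotate(rng, key, gene, region, effect, deleterious, spliceogenic, pop)
        truth = VariantTruth(
            sample_id=sample_id,
            key=key,
            origin=ORIGIN_SOMATIC,
            gene=gene,
            region=region,
            effect=effect,
            deleterious=deleterious,
            spliceogenic=spliceogenic,
            planted_vaf=vaf,
            pop_freq_max=pop,
            functional=self._functional_flag(region, effect, gene, deleterious, z, pop),
        )
        self.truth_variants.append(truth)
        used.add((key.chrom, key.pos))
        return truth

    def _generate_sample(self, idx: int) -> None:
        spec = self.spec
        sample_id = spec.sample_id(idx)
        rng = np.random.default_rng([spec.seed, 1000 + idx])
        used: set[tuple[str, int]] = set()
        somatic: list[VariantTruth] = []

        # Germline draw from the population pool (first, so somatic draws
        # cannot collide with this sample's germline positions).
        n_germ = min(spec.germline_per_sample, len(self.germline_pool))
        picks = rng.choice(len(self.germline_pool), size=n_germ, replace=False)
        germline: list[VariantTruth] = []
        for i in sorted(picks):
            site = self.germline_pool[i]
            used.add((site["key"].chrom, site["key"].pos))
            truth = VariantTruth(
                sample_id=sample_id,
                key=site["key"],
                origin=ORIGIN_GERMLINE,
                gene=site["gene"],
                region=site["region"],
                effect=site["effect"],
                deleterious=site["deleterious"],
                spliceogenic=False,
                planted_vaf=0.5,
                pop_freq_max=site["pop"],
                functional=False,
            )
            self.truth_variants.append(truth)
            germline.append(truth)

        # Background somatic variants (never in designated genes).
        n_somatic = _nb_draw(rng, spec.somatic_per_tumor_mean, spec.somatic_per_tumor_dispersion)
        for _ in range(n_somatic):
            key, gene, region, effect = self._draw_site(rng, allow_designated=False)
            while (key.chrom, key.pos) in used:
                key, gene, region, effect = self._draw_site(rng, allow_designated=False)
            vaf = spec.min_detectable_vaf + (1 - spec.min_detectable_vaf) * float(
                rng.beta(spec.somatic_vaf_alpha, spec.somatic_vaf_beta)
            )
            spliceogenic = effect == "SPLICE" or (
                effect == "SILENT" and rng.random() < spec.silent_spliceogenic_rate
            )
            deleterious = effect in ("NONSENSE", "FRAMESHIFT_INDEL", "SPLICE") or (
                effect == "MISSENSE" and rng.random() < 0.5
            )
            pop: Optional[float] = None
            if rng.random() < spec.somatic_popfreq_contaminant_rate:
                pop = float(rng.uniform(0.02, 0.5))
            somatic.append(
                self._plant_somatic(
                    rng, sample_id, used, key, gene, region, effect,
                    deleterious, spliceogenic, vaf, pop,
                )
            )

        # Engineered recurrent variants in candidate genes (3 samples each),
        # skipping the tumor suppressor which follows the two-hit plan.
        ordinary = [g for g in spec.candidate_genes if g != spec.tsg_gene]
        for j, gname in enumerate(ordinary):
            if idx in {(2 * j + k) % spec.n_pairs for k in range(3)}:
                somatic.append(self._plant_engineered_mutation(
                    rng, sample_id, used, gname, "MISSENSE", spec.het_plant_vaf
                ))

        # Two-hit plan for the designated tumor suppressor.
        plan = spec.twohit_plan.get(idx)
        if plan is Mechanism.HOMOZYGOUS_MUTATION:
            somatic.append(self._plant_engineered_mutation(
                rng, sample_id, used, spec.tsg_gene, "NONSENSE", spec.hom_plant_vaf
            ))
        elif plan in (Mechanism.HET_MUTATION_PLUS_LOSS, Mechanism.MUTATION_ONLY):
            somatic.append(self._plant_engineered_mutation(
                rng, sample_id, used, spec.tsg_gene, "MISSENSE", spec.het_plant_vaf
            ))

        self._emit_counts_and_calls(rng, idx, sample_id, somatic, germline, used)
        self._emit_segments(idx, sample_id, rng)
        self._emit_capture(rng, sample_id, somatic)

    def _plant_engineered_mutation(
        self, rng, sample_id: str, used: set, gname: str, effect: str, vaf: float
    ) -> VariantTruth:
        g = self.by_name[gname]
        while True:
            pos = int(rng.integers(g.start, g.end + 1))
            if (g.chrom, pos) not in used:
                break
        ref, alt = _draw_snv_alleles(rng, self.spec.spectrum_mix)
        key = VariantKey(g.chrom, pos, ref, alt)
        return self._plant_somatic(
            rng, sample_id, used, key, gname, "EXONIC", effect,
            deleterious=True, spliceogenic=False, vaf=vaf, pop=None,
        )

    def _compute_gene_truth(self) -> None:
        """Expected alteration status per (sample, designated gene).

        Derived from planted configurations: engineered CN events (designated
        genes are fully inside or fully outside each event by construction)
        and planted mutation VAFs, pushed through the two-hit truth table.
        """
        from .copy_number import CopyCall, CopyThresholds
        from .twohit import Zygosity, classify_two_hit

        thresholds = CopyThresholds()
        spec = self.spec
        planted: dict[tuple[str, str], list[float]] = {}
        for v in self.truth_variants:
            if v.origin == ORIGIN_SOMATIC and v.gene in self.designated:
                planted.setdefault((v.sample_id, v.gene), []).append(v.planted_vaf)
        for idx in range(spec.n_pairs):
            sid = spec.sample_id(idx)
            for gname in sorted(self.designated):
                g = self.by_name[gname]
                copy = CopyCall.NEUTRAL
                for ev in spec.cn_events:
                    if (
                        idx in ev.sample_indices
                        and ev.chrom == g.chrom
                        and ev.start <= g.start
                        and g.end <= ev.end
                    ):
                        copy = thresholds.call(ev.seg_mean)
                vafs = planted.get((sid, gname), [])
                if any(v >= 0.7 for v in vafs) or len(vafs) >= 2:
                    zyg = Zygosity.HOM
                elif vafs:
                    zyg = Zygosity.HET
                else:
                    zyg = Zygosity.NONE
                call = classify_two_hit(zyg, copy, sid, gname)
                self.gene_status[(sid, gname)] = call.status
                self.gene_mechanism[(sid, gname)] = call.mechanisms

    def _emit_counts_and_calls(
        self, rng, idx: int, sample_id: str,
        somatic: Sequence[VariantTruth], germline: Sequence[VariantTruth],
        used: set[tuple[str, int]],
    ) -> None:
        spec = self.spec

        def depth(mean: float) -> int:
            return max(int(rng.poisson(mean)), 1)

        counts: dict[VariantKey, tuple[int, int, int, int]] = {}
        for v in somatic:
            dt, dn = depth(spec.depth_tumor), depth(spec.depth_normal)
            alt_t = int(rng.binomial(dt, v.planted_vaf))
            counts[v.key] = (dt - alt_t, alt_t, dn, 0)
        for v in germline:
            dt, dn = depth(spec.depth_tumor), depth(spec.depth_normal)
            alt_t = int(rng.binomial(dt, 0.5))
            alt_n = int(rng.binomial(dn, 0.5))
            counts[v.key] = (dt - alt_t, alt_t, dn - alt_n, alt_n)

        tumor_present = [v.key for v in somatic] + [v.key for v in germline]
        normal_present = [v.key for v in germline]
        for caller in CALLERS:
            profile = spec.caller_profiles[caller]
            t_calls = [k for k in tumor_present if rng.random() < profile.sensitivity]
            n_calls = [k for k in normal_present if rng.random() < profile.sensitivity]
            for tissue, calls in (("TUMOR", t_calls), ("NORMAL", n_calls)):
                fps = []
                for _ in range(profile.false_positives_per_sample):
                    while True:
                        chrom = CHROMS[rng.integers(len(CHROMS))]
                        pos = int(rng.integers(1, CHROM_LENGTH))
                        if (chrom, pos) not in used:
                            break
                    used.add((chrom, pos))
                    ref, alt = _draw_snv_alleles(rng, spec.spectrum_mix)
                    key = VariantKey(chrom, pos, ref, alt)
                    self._annotate(
                        rng, key, ".", "INTERGENIC", "UNKNOWN",
                        deleterious=False, spliceogenic=False, pop=None,
                    )
                    self.truth_variants.append(
                        VariantTruth(
                            sample_id=sample_id, key=key, origin=ORIGIN_CALLER_FP,
                            gene=".", region="INTERGENIC", effect="UNKNOWN",
                            deleterious=False, spliceogenic=False, planted_vaf=0.0,
                            pop_freq_max=None, functional=False,
                        )
                    )
                    dt, dn = depth(spec.depth_tumor), depth(spec.depth_normal)
                    alt_t = int(rng.binomial(dt, 0.005))
                    counts[key] = (dt - alt_t, alt_t, dn, 0)
                    fps.append(key)
                self.calls[(sample_id, tissue, caller)] = sorted(calls + fps)

        for key in sorted(counts):
            tr, ta, nr, na = counts[key]
            self.counts_rows.append(
                (sample_id, key.chrom, key.pos, key.ref, key.alt, tr, ta, nr, na)
            )

    def _emit_segments(self, idx: int, sample_id: str, rng: np.random.Generator) -> None:
        events = [ev for ev in self.spec.cn_events if idx in ev.sample_indices]
        for chrom in CHROMS:
            chrom_events = sorted(
                (ev for ev in events if ev.chrom == chrom), key=lambda e: e.start
            )
            for a, b in zip(chrom_events, chrom_events[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping CN events for sample {sample_id}: {a}, {b}")
            cursor = 1
            pieces: list[tuple[int, int, float]] = []
            for ev in chrom_events:
                if cursor < ev.start:
                    pieces.append((cursor, ev.start - 1, float(rng.normal(0, 0.05))))
                pieces.append((ev.start, ev.end, ev.seg_mean))
                cursor = ev.end + 1
            if cursor <= CHROM_LENGTH:
                pieces.append((cursor, CHROM_LENGTH, float(rng.normal(0, 0.05))))
            for start, end, mean in pieces:
                self.segments.append(
                    Segment(sample_id=sample_id, chrom=chrom, start=start, end=end,
                            seg_mean=round(mean, 4), n_markers=max((end - start) // 10_000, 1))
                )

    def _emit_capture(self, rng, sample_id: str, somatic: Sequence[VariantTruth]) -> None:
        # Orthogonal capture recount over the designated gene panel.
        for v in somatic:
            if v.gene in self.designated:
                d = max(int(rng.poisson(150)), 1)
                alt = int(rng.binomial(d, v.planted_vaf))
                self.capture_rows.append(
                    (sample_id, v.key.chrom, v.key.pos, v.key.ref, v.key.alt, d - alt, alt)
                )

    # -- output -------------------------------------------------------------

    def run(self, outdir: Path) -> tuple[CohortPaths, TruthLabels]:
        spec = self.spec
        for idx in range(spec.n_pairs):
            self._generate_sample(idx)
        self._compute_gene_truth()

        outdir = Path(outdir)
        vcf_dir = outdir / "vcf"
        vcf_dir.mkdir(parents=True, exist_ok=True)
        paths = CohortPaths(
            outdir=outdir,
            vcf_dir=vcf_dir,
            counts=outdir / "counts.tsv",
            annotations=outdir / "annotations.tsv",
            expressed_genes=outdir / "expressed_genes.txt",
            seg=outdir / "cohort.seg",
            bed=outdir / "genes.bed",
            external_counts=outdir / "external_counts.tsv",
            census=outdir / "census.txt",
            gene_sets=outdir / "gene_sets.gmt",
            capture_counts=outdir / "capture_counts.tsv",
            truth_variants=outdir / "truth_variants.tsv",
            truth_gene_status=outdir / "truth_gene_status.tsv",
        )

        for (sample_id, tissue, caller), keys in sorted(self.calls.items()):
            self._write_vcf(paths.vcf(sample_id, tissue, caller), keys)
        self._write_tsv(
            paths.counts,
            ["sample", "chrom", "pos", "ref", "alt", "tumor_ref", "tumor_alt",
             "normal_ref", "normal_alt"],
            self.counts_rows,
        )
        write_annotation_table(self.annotations, paths.annotations)
        paths.expressed_genes.write_text("".join(f"{g}\n" for g in sorted(self.expressed)))
        self._write_tsv(
            paths.seg,
            ["sample", "chrom", "start", "end", "n_markers", "seg_mean"],
            [(s.sample_id, s.chrom, s.start, s.end, s.n_markers, s.seg_mean)
             for s in self.segments],
        )
        with open(paths.bed, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene}\t0\t{g.strand}\n")
        self._write_tsv(
            paths.external_counts, ["gene", "n_mutated"],
            sorted(self.external_counts.items()),
        )
        paths.census.write_text("".join(f"{g}\n" for g in sorted(spec.census_genes)))
        with open(paths.gene_sets, "w") as fh:
            for term in sorted(self.gene_sets):
                genes = "\t".join(self.gene_sets[term])
                fh.write(f"{term}\tsynthetic gene set\t{genes}\n")
        self._write_tsv(
            paths.capture_counts,
            ["sample", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"],
            self.capture_rows,
        )
        self._write_tsv(
            paths.truth_variants,
            ["sample", "chrom", "pos", "ref", "alt", "origin", "gene", "region",
             "effect", "deleterious", "spliceogenic", "planted_vaf", "pop_freq_max",
             "functional"],
            [(v.sample_id, v.key.chrom, v.key.pos, v.key.ref, v.key.alt, v.origin,
              v.gene, v.region, v.effect, int(v.deleterious), int(v.spliceogenic),
              repr(v.planted_vaf),
              "." if v.pop_freq_max is None else repr(v.pop_freq_max),
              int(v.functional))
             for v in self.truth_variants],
        )
        self._write_tsv(
            paths.truth_gene_status,
            ["sample", "gene", "status", "mechanisms"],
            [(s, g, self.gene_status[(s, g)].value,
              ",".join(sorted(m.value for m in self.gene_mechanism[(s, g)])))
             for (s, g) in sorted(self.gene_status)],
        )
        truth = TruthLabels(
            variants=self.truth_variants,
            gene_status=self.gene_status,
            gene_mechanism=self.gene_mechanism,
            expressed_genes=self.expressed,
        )
        return paths, truth

    @staticmethod
    def _write_vcf(path: Path, keys: Sequence[VariantKey]) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=prioritizer-synthetic\n")
            for chrom in CHROMS:
                fh.write(f"##contig=<ID={chrom},length={CHROM_LENGTH}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for key in sorted(keys):
                fh.write(f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\n")

    @staticmethod
    def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(header)
            w.writerows(rows)


def generate_cohort(spec: CohortSpec, outdir) -> tuple[CohortPaths, TruthLabels]:
    """Generate a complete truth-labelled cohort file tree under ``outdir``.

    Emits per-sample per-caller VCFs for both tissues, the recount table,
    the annotation table, the expressed-gene list, SEG segmentation, the
    gene BED, the external-cohort mutation counts, census and gene-set
    files, an orthogonal capture recount, and the truth labels.  Fixed seed
    implies a byte-identical file tree.
    """
    return _Generator(spec).run(Path(outdir))


# ---------------------------------------------------------------------------
# Closed-form recovery expectations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryExpectation:
    """Analytic per-stage expectations for a spec's caller error model."""

    per_variant_consensus_prob: float  # P(>= 2 of 3 callers detect)
    per_variant_normal_detect_prob: float  # P(>= 1 of 3 callers detect)
    expected_tumor_consensus_per_sample: float

    def consensus_mean_sd(self, n_planted: int) -> tuple[float, float]:
        """Mean and SD of the number of planted variants reaching consensus."""
        p = self.per_variant_consensus_prob
        return n_planted * p, float(np.sqrt(n_planted * p * (1 - p)))


def expected_recovery(spec: CohortSpec) -> RecoveryExpectation:
    """Closed-form detection probabilities implied by the caller profiles.

    With per-caller sensitivities s_i, a variant reaches tumor consensus
    with probability P(>=2 detect) = sum_i s_j s_k (1-s_i) + s_1 s_2 s_3
    and appears in a normal with P(>=1) = 1 - prod(1-s_i).
    """
    s = [spec.caller_profiles[c].sensitivity for c in CALLERS]
    p_all = s[0] * s[1] * s[2]
    p_exactly_two = (
        s[0] * s[1] * (1 - s[2])
        + s[0] * s[2] * (1 - s[1])
        + s[1] * s[2] * (1 - s[0])
    )
    p2 = p_exactly_two + p_all
    p1 = 1 - (1 - s[0]) * (1 - s[1]) * (1 - s[2])
    expected_present = spec.somatic_per_tumor_mean + spec.germline_per_sample
    return RecoveryExpectation(
        per_variant_consensus_prob=p2,
        per_variant_normal_detect_prob=p1,
        expected_tumor_consensus_per_sample=expected_present * p2,
    )
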