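"""End-to-end orchestration: ingest → consensus → somatic → functional →
candidates → copy number → two-hit → summaries, with a machine-readable
run report.

The pipeline is fully deterministic given its inputs; the configured seed is
only echoed into the report for provenance.  Any stage error aborts with the
stage name; per-stage survivor counts in the report satisfy conservation
(ingested consensus = final survivors + traces).
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import consensus as cns
from . import variant_io as vio
from .copy_number import CopyThresholds, fraction_genome_altered, gene_copy_call
from .functional_filter import (
    FunctionalFilterConfig,
    read_annotation_table,
    run_functional_cascade,
)
from .recurrence import (
    enrich_per_sample,
    read_external_counts,
    read_gene_list,
    read_gmt,
    select_candidates,
)
from .somatic_filter import SomaticFilterConfig, run_somatic_filters
from .summaries import burden_table, mutation_spectrum, validation_rate
from .twohit import (
    AlterationStatus,
    ZygosityConfig,
    classify_two_hit,
    classify_zygosity,
    cohort_alteration_frequency,
)
from .variant_io import Tissue

__all__ = ["RunConfig", "run_all", "PipelineError"]

log = logging.getLogger("prioritizer")

_VCF_NAME = re.compile(r"^(?P<sample>.+)_(?P<tissue>tumor|normal)_(?P<caller>[a-z0-9]+)\.vcf$")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full pipeline configuration (YAML-loadable, echoed into the report)."""

    vcf_dir: str
    counts: str
    annotations: str
    expressed_genes: str
    seg: str
    bed: str
    external_counts: str
    census: Optional[str] = None
    gene_sets: Optional[str] = None
    capture_counts: Optional[str] = None

    min_callers_tumor: int = 2
    min_callers_normal: int = 1
    normal_scope: str = "cohort"  # or "matched"

    max_normal_vaf: float = 0.05
    min_ref_reads_for_zero_alt: int = 20
    tumor_to_normal_vaf_ratio: float = 2.0
    max_population_freq: float = 0.01

    spidex_z_threshold: float = 2.0
    min_predictors_for_vote: int = 1
    vote_denominator: str = "available"

    cohort_min: int = 2
    external_min: int = 3
    enrichment_alpha: float = 0.05
    min_recurrent_samples: int = 3

    amp_threshold: float = 0.8
    loss_threshold: float = -0.6
    deep_del_threshold: float = -1.3
    gene_summary: str = "weighted_mean"
    fga_threshold: float = 0.2

    homozygous_vaf_min: float = 0.7
    compound_het_is_hom: bool = True

    territory_mb: float = 38.0
    validation_min_alt_fraction: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def somatic_config(self) -> SomaticFilterConfig:
        return SomaticFilterConfig(
            max_normal_vaf=self.max_normal_vaf,
            min_ref_reads_for_zero_alt=self.min_ref_reads_for_zero_alt,
            tumor_to_normal_vaf_ratio=self.tumor_to_normal_vaf_ratio,
            max_population_freq=self.max_population_freq,
        )

    def copy_thresholds(self) -> CopyThresholds:
        return CopyThresholds(
            amp=self.amp_threshold, loss=self.loss_threshold, deep_del=self.deep_del_threshold
        )


def _discover_vcfs(vcf_dir: Path) -> dict[tuple[str, Tissue, str], Path]:
    found = {}
    for path in sorted(vcf_dir.glob("*.vcf")):
        m = _VCF_NAME.match(path.name)
        if not m:
            continue
        tissue = Tissue.TUMOR if m.group("tissue") == "tumor" else Tissue.NORMAL
        found[(m.group("sample"), tissue, m.group("caller"))] = path
    if not found:
        raise PipelineError("ingest", f"no VCFs matching <sample>_<tissue>_<caller>.vcf in {vcf_dir}")
    return found


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write the run report plus result tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}
    t0 = time.time()

    def stage_done(name: str, **info) -> None:
        report["stages"][name] = info
        log.info("stage %-12s done in %.1fs %s", name, time.time() - t0, info)

    # ---- ingest -----------------------------------------------------------
    try:
        vcfs = _discover_vcfs(Path(config.vcf_dir))
        per_sample_tissue: dict[tuple[str, Tissue], list] = {}
        for (sample, tissue, caller), path in vcfs.items():
            records = vio.read_caller_vcf(path, caller, sample, tissue)
            per_sample_tissue.setdefault((sample, tissue), []).extend(records)
        counts = vio.read_counts_table(config.counts)
        annotations = read_annotation_table(config.annotations)
        expressed = read_gene_list(config.expressed_genes)
        segments = vio.read_seg(config.seg)
        gene_intervals = {g.gene: g for g in vio.read_gene_bed(config.bed)}
        external = read_external_counts(config.external_counts)
        census = read_gene_list(config.census) if config.census else frozenset()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc
    samples = sorted({s for s, t in per_sample_tissue if t is Tissue.TUMOR})
    stage_done("ingest", n_samples=len(samples), n_vcfs=len(vcfs),
               n_count_rows=len(counts), n_annotations=len(annotations))

    # ---- consensus --------------------------------------------------------
    try:
        tumor_sets = {
            s: cns.build_consensus(
                per_sample_tissue[(s, Tissue.TUMOR)], Tissue.TUMOR,
                config.min_callers_tumor, config.min_callers_normal,
            )
            for s in samples
        }
        normal_sets = {
            s: cns.build_consensus(
                recs, Tissue.NORMAL, config.min_callers_tumor, config.min_callers_normal
            )
            for (s, t), recs in per_sample_tissue.items()
            if t is Tissue.NORMAL
        }
        if config.normal_scope == "cohort":
            panel = cns.build_normal_panel(normal_sets.values())
        else:
            panel = {s: ns.keys() for s, ns in normal_sets.items()}
    except Exception as exc:
        raise PipelineError("consensus", str(exc)) from exc
    consensus_counts = {s: len(tumor_sets[s]) for s in samples}
    stage_done("consensus", per_sample=consensus_counts,
               panel_size=len(panel) if isinstance(panel, set) else sum(map(len, panel.values())))

    # ---- somatic filtering ------------------------------------------------
    try:
        pop_freq = {k: a.pop_freq_max for k, a in annotations.items()}
        somatic, somatic_traces = run_somatic_filters(
            tumor_sets, panel, counts, pop_freq, config.somatic_config()
        )
    except Exception as exc:
        raise PipelineError("somatic", str(exc)) from exc
    somatic_counts = {s: len(somatic[s]) for s in samples}
    trace_by_stage: dict[str, int] = {}
    for t in somatic_traces:
        trace_by_stage[t.stage.value] = trace_by_stage.get(t.stage.value, 0) + 1
    stage_done("somatic", per_sample=somatic_counts, removed_by_stage=trace_by_stage,
               total=sum(somatic_counts.values()))

    # ---- functional filtering ---------------------------------------------
    try:
        fcfg = FunctionalFilterConfig(
            spidex_z_threshold=config.spidex_z_threshold,
            expressed_genes=frozenset(expressed),
            min_predictors_for_vote=config.min_predictors_for_vote,
            vote_denominator=config.vote_denominator,
        )
        functional, functional_traces = run_functional_cascade(somatic, annotations, fcfg)
    except Exception as exc:
        raise PipelineError("functional", str(exc)) from exc
    functional_counts = {s: len(functional[s]) for s in samples}
    ftrace_by_stage: dict[str, int] = {}
    for t in functional_traces:
        ftrace_by_stage[t.stage.value] = ftrace_by_stage.get(t.stage.value, 0) + 1
    stage_done("functional", per_sample=functional_counts, removed_by_stage=ftrace_by_stage,
               total=sum(functional_counts.values()))

    # ---- candidate selection + enrichment ---------------------------------
    try:
        per_sample_genes = {
            s: {annotations[r.key].gene for r in functional[s] if annotations[r.key].gene != "."}
            for s in samples
        }
        recurrences = select_candidates(
            per_sample_genes, external, config.cohort_min, config.external_min, census
        )
        candidates = [r.gene for r in recurrences if r.is_candidate]
        novel = [r.gene for r in recurrences if r.is_candidate and not r.is_known_driver]
        recurrent_terms: list[str] = []
        if config.gene_sets:
            gene_sets = read_gmt(config.gene_sets)
            novel_set = set(novel)
            per_sample_novel = {
                s: genes & novel_set for s, genes in per_sample_genes.items()
            }
            _, recurrent_terms, _ = enrich_per_sample(
                per_sample_novel, gene_sets, frozenset(expressed),
                config.enrichment_alpha, config.min_recurrent_samples,
            )
    except Exception as exc:
        raise PipelineError("candidates", str(exc)) from exc
    stage_done("candidates", n_recurrent_genes=sum(1 for r in recurrences
                                                   if r.cohort_mutated_samples >= config.cohort_min),
               candidates=candidates, novel=novel, recurrent_terms=recurrent_terms)

    # ---- copy number ------------------------------------------------------
    try:
        thresholds = config.copy_thresholds()
        seg_by_sample: dict[str, list] = {}
        for seg in segments:
            seg_by_sample.setdefault(seg.sample_id, []).append(seg)
        copy_calls = {}
        for s in samples:
            for gene in candidates:
                interval = gene_intervals.get(gene)
                if interval is None:
                    continue
                copy_calls[(s, gene)] = gene_copy_call(
                    seg_by_sample.get(s, []), interval, thresholds, config.gene_summary
                )
        fga = {
            s: fraction_genome_altered(seg_by_sample[s], config.fga_threshold)
            for s in samples
            if seg_by_sample.get(s)
        }
    except Exception as exc:
        raise PipelineError("cnv", str(exc)) from exc
    stage_done("cnv", n_gene_calls=len(copy_calls),
               mean_fga=sum(fga.values()) / len(fga) if fga else None)

    # ---- two-hit integration ----------------------------------------------
    try:
        zcfg = ZygosityConfig(
            homozygous_vaf_min=config.homozygous_vaf_min,
            compound_het_is_hom=config.compound_het_is_hom,
        )
        alteration_calls = []
        for s in samples:
            by_gene: dict[str, list] = {}
            for rec in functional[s]:
                gene = annotations[rec.key].gene
                if gene in candidates:
                    by_gene.setdefault(gene, []).append(rec)
            for gene in candidates:
                if (s, gene) not in copy_calls:
                    continue
                copy = copy_calls[(s, gene)].call
                zyg = classify_zygosity(by_gene.get(gene, []), copy, zcfg)
                alteration_calls.append(classify_two_hit(zyg, copy, s, gene))
        frequencies = {}
        for gene in candidates:
            if not any(c.gene == gene for c in alteration_calls):
                continue
            n2, total, pct2 = cohort_alteration_frequency(
                alteration_calls, gene, frozenset({AlterationStatus.TWO_HIT})
            )
            n_any, _, pct_any = cohort_alteration_frequency(
                alteration_calls, gene,
                frozenset({AlterationStatus.TWO_HIT, AlterationStatus.ONE_HIT}),
            )
            frequencies[gene] = {
                "two_hit": n2, "any_alteration": n_any, "total": total,
                "two_hit_pct": round(pct2, 1), "any_alteration_pct": round(pct_any, 1),
            }
    except Exception as exc:
        raise PipelineError("twohit", str(exc)) from exc
    stage_done("twohit", frequencies=frequencies)

    # ---- summaries --------------------------------------------------------
    try:
        burdens = burden_table(
            somatic, functional, functional_traces, config.territory_mb, fga
        )
        snv_keys = [
            r.key for recs in somatic.values() for r in recs if r.key.is_snv
        ]
        spectrum_counts, spectrum_fractions = mutation_spectrum(snv_keys)
        validation: Optional[dict] = None
        if config.capture_counts:
            import pandas as pd

            cap_df = pd.read_csv(config.capture_counts, sep="\t", dtype={"chrom": str})
            capture = {
                (str(r.sample), vio.VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))):
                    (int(r.ref_reads), int(r.alt_reads))
                for r in cap_df.itertuples(index=False)
            }
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                rates, med = validation_rate(
                    {s: [r.key for r in functional[s]] for s in samples},
                    capture, config.validation_min_alt_fraction,
                )
            validation = {"per_sample": rates, "median": med}
    except Exception as exc:
        raise PipelineError("summaries", str(exc)) from exc

    n = len(samples)
    coding = sorted(b.coding_variants for b in burdens)
    func_counts = sorted(b.functional_variants for b in burdens)
    report["summary"] = {
        "n_samples": n,
        "total_somatic": sum(somatic_counts.values()),
        "mean_coding_variants": sum(coding) / n if n else 0.0,
        "median_functional_variants": (
            (func_counts[(n - 1) // 2] + func_counts[n // 2]) / 2 if n else 0.0
        ),
        "mutation_spectrum_fractions": spectrum_fractions,
        "validation": validation,
    }
    stage_done("summaries", **{k: v for k, v in report["summary"].items()
                               if k != "mutation_spectrum_fractions"})

    # ---- outputs ----------------------------------------------------------
    gene_of = {k: a.gene for k, a in annotations.items()}
    effect_of = {k: a.effect_class.value for k, a in annotations.items()}
    all_functional = [r for s in samples for r in functional[s]]
    vio.write_maf_like(vio.records_to_maf_rows(all_functional, gene_of, effect_of),
                       out_dir / "functional_variants.tsv")
    with open(out_dir / "filter_traces.tsv", "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\tstage\tdetail\n")
        for t in somatic_traces + functional_traces:
            fh.write(f"{t.sample_id}\t{t.key.chrom}\t{t.key.pos}\t{t.key.ref}\t"
                     f"{t.key.alt}\t{t.stage.value}\t{t.detail}\n")
    with open(out_dir / "gene_copy_calls.tsv", "w") as fh:
        fh.write("sample\tgene\tseg_mean\tcall\n")
        for (s, gene), call in sorted(copy_calls.items()):
            fh.write(f"{s}\t{gene}\t{call.seg_mean:.4f}\t{call.call.value}\n")
    with open(out_dir / "alteration_matrix.tsv", "w") as fh:
        fh.write("sample\tgene\tstatus\tmechanisms\n")
        for c in alteration_calls:
            mechs = ",".join(sorted(m.value for m in c.mechanisms))
            fh.write(f"{c.sample_id}\t{c.gene}\t{c.status.value}\t{mechs}\n")

    report["alteration_calls"] = [
        {"sample": c.sample_id, "gene": c.gene, "status": c.status.value,
         "mechanisms": sorted(m.value for m in c.mechanisms)}
        for c in alteration_calls
    ]
    report["burden"] = [asdict(b) for b in burdens]
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
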