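"""Candidate-gene nomination by recurrence, and hypergeometric GO enrichment.

A gene becomes a candidate when it carries functional mutations in at least
``cohort_min`` cohort samples (default 2) and in at least ``external_min``
samples of an external reference cohort (default 3, the TCGA cross-check).
Candidates present in the supplied census list are flagged as known drivers;
the remainder are the novel candidates.

Per-sample enrichment tests each gene-set term with the upper-tail
hypergeometric probability; terms enriched in ``min_recurrent_samples`` or
more samples are reported as recurrently enriched.  Nominal p <= alpha with
no multiple-testing correction is the default (BH-FDR available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneRecurrence",
    "EnrichmentResult",
    "select_candidates",
    "hypergeom_upper_tail",
    "enrich_per_sample",
    "read_gmt",
    "read_gene_list",
    "read_external_counts",
]

COHORT_MIN = 2
EXTERNAL_MIN = 3


@dataclass(frozen=True)
class GeneRecurrence:
    gene: str
    cohort_mutated_samples: int
    external_mutated_samples: int
    is_candidate: bool
    is_known_driver: bool


@dataclass(frozen=True)
class EnrichmentResult:
    sample_id: str
    term_id: str
    term_size: int  # K: term members in the universe
    sample_gene_count: int  # n: draws
    overlap: int  # k
    universe_size: int  # N
    p_value: float


def select_candidates(
    per_sample_genes: Mapping[str, Iterable[str]],
    external_counts: Mapping[str, int],
    cohort_min: int = COHORT_MIN,
    external_min: int = EXTERNAL_MIN,
    known_driver_list: frozenset = frozenset(),
) -> list[GeneRecurrence]:
    """Nominate candidate genes by in-cohort and external recurrence.

    ``per_sample_genes`` maps each sample to the genes carrying retained
    functional variants; a sample counts once per gene regardless of variant
    multiplicity.  Genes absent from ``external_counts`` count 0 externally.
    """
    cohort_counts: dict[str, int] = {}
    for genes in per_sample_genes.values():
        for gene in set(genes):
            cohort_counts[gene] = cohort_counts.get(gene, 0) + 1
    out = []
    for gene in sorted(cohort_counts):
        n_cohort = cohort_counts[gene]
        n_external = int(external_counts.get(gene, 0))
        is_candidate = n_cohort >= cohort_min and n_external >= external_min
        out.append(
            GeneRecurrence(
                gene=gene,
                cohort_mutated_samples=n_cohort,
                external_mutated_samples=n_external,
                is_candidate=is_candidate,
                is_known_driver=is_candidate and gene in known_driver_list,
            )
        )
    return out


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n).

    Computed through stable log-gamma machinery; exact tail summation is the
    test oracle.  Bounds: 0 <= k <= min(K, n) <= N.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich_per_sample(
    per_sample_genes: Mapping[str, Iterable[str]],
    gene_sets: Mapping[str, frozenset],
    universe: frozenset,
    alpha: float = 0.05,
    min_recurrent_samples: int = 3,
    bh_fdr: bool = False,
) -> tuple[list[EnrichmentResult], list[str], pd.DataFrame]:
    """Hypergeometric gene-set enrichment per sample, plus cross-sample recurrence.

    Returns (all per-sample results, term ids enriched in
    ``min_recurrent_samples`` or more samples, gene x term membership matrix
    restricted to the tested genes).  With ``bh_fdr`` the significance call
    uses Benjamini-Hochberg adjusted p-values within each sample.
    """
    if not universe:
        raise ValueError("empty gene universe")
    N = len(universe)
    results: list[EnrichmentResult] = []
    enriched_in: dict[str, set[str]] = {}
    tested_genes: set[str] = set()
    for sample_id in sorted(per_sample_genes):
        sample_genes = set(per_sample_genes[sample_id]) & universe
        tested_genes |= sample_genes
        n = len(sample_genes)
        sample_results = []
        for term_id in sorted(gene_sets):
            members = gene_sets[term_id] & universe
            K = len(members)
            if K == 0:
                continue
            k = len(sample_genes & members)
            p = hypergeom_upper_tail(k, K, n, N)
            sample_results.append(
                EnrichmentResult(sample_id, term_id, K, n, k, N, p)
            )
        if bh_fdr and sample_results:
            from statsmodels.stats.multitest import multipletests

            signif = multipletests([r.p_value for r in sample_results], alpha, "fdr_bh")[0]
        else:
            signif = [r.p_value <= alpha for r in sample_results]
        for r, sig in zip(sample_results, signif):
            if sig:
                enriched_in.setdefault(r.term_id, set()).add(sample_id)
        results.extend(sample_results)

    recurrent = sorted(
        t for t, samples in enriched_in.items() if len(samples) >= min_recurrent_samples
    )
    genes = sorted(tested_genes)
    membership = pd.DataFrame(
        {t: [g in gene_sets[t] for g in genes] for t in sorted(gene_sets)},
        index=genes,
        dtype=bool,
    )
    return results, recurrent, membership


# ---------------------------------------------------------------------------
# Small-format readers
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, frozenset]:
    """Read GMT gene sets: ``term <tab> description <tab> gene...`` per line."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs term, description, genes")
            sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    return sets


def read_gene_list(path) -> frozenset:
    """Read a newline-delimited gene symbol list (census, expressed genes...)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def read_external_counts(path) -> dict[str, int]:
    """Read the external-cohort per-gene mutated-sample counts (gene, n_mutated)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "n_mutated"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns gene, n_mutated")
    return {str(r.gene): int(r.n_mutated) for r in df.itertuples(index=False)}
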