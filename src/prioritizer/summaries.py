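"""Cohort-level descriptive statistics and group comparisons.

Per-tumor mutation burdens (counts, TMB, FGA), the six-class pyrimidine
mutation spectrum, the capture-panel validation rate, and a one-tailed
Mann-Whitney (rank-sum) comparison for burden differences between gene-status
groups (exact by enumeration with mid-rank ties for small groups, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import mannwhitneyu, rankdata

from .somatic_filter import FilterTrace, Stage
from .variant_io import VariantKey, VariantRecord

__all__ = [
    "BurdenRow",
    "burden_table",
    "mutation_spectrum",
    "SPECTRUM_CLASSES",
    "validation_rate",
    "rank_sum_one_tailed",
]

#: Pyrimidine-reference SNV classes (purine-reference SNVs are complemented).
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Exact rank-sum enumeration up to this pooled size; normal approx beyond.
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class BurdenRow:
    sample_id: str
    coding_variants: int
    functional_variants: int
    mutation_count: int
    tmb: float  # mutations per megabase of callable territory
    fga: float


def burden_table(
    somatic: Mapping[str, Sequence[VariantRecord]],
    functional: Mapping[str, Sequence[VariantRecord]],
    traces: Sequence[FilterTrace],
    territory_mb: float = 38.0,
    fga: Optional[Mapping[str, float]] = None,
) -> list[BurdenRow]:
    """Per-sample burden metrics from the cascade's retained sets and traces.

    ``mutation_count`` counts somatic-filter survivors; ``coding_variants``
    counts survivors of the region filter (somatic minus REGION removals);
    ``functional_variants`` counts final cascade survivors.  TMB divides the
    mutation count by the callable territory in Mb (default 38, a typical
    exome callable size).
    """
    if territory_mb <= 0:
        raise ValueError("territory_mb must be > 0")
    region_removed: dict[str, int] = {}
    for t in traces:
        if t.stage is Stage.REGION:
            region_removed[t.sample_id] = region_removed.get(t.sample_id, 0) + 1
    rows = []
    for sample_id in sorted(somatic):
        n_somatic = len(somatic[sample_id])
        rows.append(
            BurdenRow(
                sample_id=sample_id,
                coding_variants=n_somatic - region_removed.get(sample_id, 0),
                functional_variants=len(functional.get(sample_id, [])),
                mutation_count=n_somatic,
                tmb=n_somatic / territory_mb,
                fga=(fga or {}).get(sample_id, 0.0),
            )
        )
    return rows


def mutation_spectrum(
    keys: Iterable[VariantKey],
) -> tuple[dict[str, int], dict[str, float]]:
    """Classify SNVs into the six pyrimidine-reference substitution classes.

    Indels must be excluded by the caller; purine-reference SNVs (G/A) are
    reverse-complemented so e.g. G>T counts as C>A.  Returns (counts,
    fractions); fractions sum to 1 over non-empty input.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    total = 0
    for key in keys:
        if not key.is_snv:
            raise ValueError(f"{key}: spectrum classification requires SNVs only")
        ref, alt = key.ref.upper(), key.alt.upper()
        if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            raise ValueError(f"{key}: non-ACGT allele")
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
        total += 1
    fractions = {c: (counts[c] / total if total else 0.0) for c in SPECTRUM_CLASSES}
    return counts, fractions


def validation_rate(
    candidates: Mapping[str, Iterable[VariantKey]],
    capture_counts: Mapping[tuple[str, VariantKey], tuple[int, int]],
    min_alt_fraction: float = 0.05,
) -> tuple[dict[str, float], float]:
    """Per-sample validation rates against an orthogonal capture recount.

    Only variants with a capture recount entry enter a sample's denominator
    (the capture panel covers a subset of genes/samples).  A variant is
    validated when alt reads make up ``min_alt_fraction`` or more of its
    capture reads.  Returns per-sample rates and their cohort median;
    samples with nothing assessed are excluded from the median with a
    warning.
    """
    rates: dict[str, float] = {}
    for sample_id in sorted(candidates):
        assessed = validated = 0
        for key in candidates[sample_id]:
            entry = capture_counts.get((sample_id, key))
            if entry is None:
                continue
            ref, alt = entry
            assessed += 1
            depth = ref + alt
            if depth > 0 and alt / depth >= min_alt_fraction:
                validated += 1
        if assessed == 0:
            warnings.warn(
                f"sample {sample_id}: no captured variants to assess; excluded from median",
                stacklevel=2,
            )
            continue
        rates[sample_id] = validated / assessed
    if not rates:
        raise ValueError("no sample had assessable variants")
    return rates, median(rates.values())


def rank_sum_one_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "less",
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U test of group_a against group_b.

    ``alternative="less"`` tests whether group_a tends to be smaller than
    group_b; ``"greater"`` the reverse.  Returns (U, p) where U counts
    (a > b) pairs with ties at half weight.  Exact p by enumeration of all
    rank assignments (mid-rank ties) when the pooled size is at most 20;
    tie-corrected normal approximation with continuity correction otherwise.
    A fully degenerate comparison (every value identical) reports p = 1 with
    a warning.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    a, b = list(map(float, group_a)), list(map(float, group_b))
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = len(a), len(b)

    u_a = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)

    if len(set(a) | set(b)) == 1:
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return u_a, 1.0

    if n_a + n_b <= EXACT_RANKSUM_MAX_N:
        ranks = rankdata(a + b)  # mid-ranks
        observed = float(ranks[:n_a].sum())
        at_least = at_most = total = 0
        eps = 1e-9
        for subset in combinations(range(n_a + n_b), n_a):
            s = float(sum(ranks[i] for i in subset))
            total += 1
            if s <= observed + eps:
                at_most += 1
            if s >= observed - eps:
                at_least += 1
        p = (at_most if alternative == "less" else at_least) / total
        return u_a, p

    res = mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return u_a, float(res.pvalue)
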