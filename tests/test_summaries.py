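"""Burden metrics, mutation spectrum, validation rate, one-tailed rank-sum test."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prioritizer.somatic_filter import FilterTrace, Stage
from prioritizer.summaries import (
    SPECTRUM_CLASSES,
    burden_table,
    mutation_spectrum,
    rank_sum_one_tailed,
    validation_rate,
)
from prioritizer.variant_io import Tissue, VariantKey, VariantRecord

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rec(sample, pos):
    return VariantRecord(
        key=VariantKey("chr1", pos, "C", "T"), sample_id=sample, tissue=Tissue.TUMOR,
        callers=frozenset({"bcftools", "varscan"}),
    )


# --- burden ----------------------------------------------------------------


def test_burden_counts_per_stage():
    somatic = {"S1": [rec("S1", p) for p in range(1, 11)], "S2": []}
    functional = {"S1": [rec("S1", p) for p in range(1, 4)], "S2": []}
    traces = [
        FilterTrace(VariantKey("chr1", p, "C", "T"), "S1", Stage.REGION) for p in (90, 91, 92, 93)
    ]
    rows = {b.sample_id: b for b in burden_table(somatic, functional, traces, territory_mb=2.0)}
    s1 = rows["S1"]
    assert (s1.mutation_count, s1.coding_variants, s1.functional_variants) == (10, 6, 3)
    assert s1.tmb == pytest.approx(5.0)
    s2 = rows["S2"]
    assert (s2.mutation_count, s2.coding_variants, s2.functional_variants) == (0, 0, 0)
    with pytest.raises(ValueError):
        burden_table(somatic, functional, traces, territory_mb=0)


# --- spectrum --------------------------------------------------------------


def test_spectrum_complements_purine_reference():
    keys = [
        VariantKey("chr1", 1, "G", "T"),  # -> C>A
        VariantKey("chr1", 2, "C", "T"),  # -> C>T
        VariantKey("chr1", 3, "A", "G"),  # -> T>C
    ]
    counts, fractions = mutation_spectrum(keys)
    assert counts["C>A"] == 1 and counts["C>T"] == 1 and counts["T>C"] == 1
    assert sum(fractions.values()) == pytest.approx(1.0)


def test_spectrum_rejects_indels_and_non_acgt():
    with pytest.raises(ValueError):
        mutation_spectrum([VariantKey("chr1", 1, "CA", "C")])
    with pytest.raises(ValueError):
        mutation_spectrum([VariantKey("chr1", 1, "N", "T")])


@given(
    snvs=st.lists(
        st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")).filter(
            lambda p: p[0] != p[1]
        ),
        min_size=1,
        max_size=50,
    )
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_spectrum_strand_complement_invariant(snvs):
    keys = [VariantKey("chr1", i + 1, r, a) for i, (r, a) in enumerate(snvs)]
    flipped = [VariantKey("chr1", i + 1, COMP[r], COMP[a]) for i, (r, a) in enumerate(snvs)]
    assert mutation_spectrum(keys)[0] == mutation_spectrum(flipped)[0]
    assert sum(mutation_spectrum(keys)[1].values()) == pytest.approx(1.0)
    assert set(mutation_spectrum(keys)[0]) == set(SPECTRUM_CLASSES)


# --- validation rate -------------------------------------------------------


def test_validation_rate_boundary_and_median():
    k = {i: VariantKey("chr1", i, "C", "T") for i in range(1, 8)}
    candidates = {
        "S1": [k[1], k[2]],
        "S2": [k[3], k[4]],
        "S3": [k[5], k[6], k[7]],
    }
    capture = {
        ("S1", k[1]): (94, 6),   # 6% >= 5% -> validated
        ("S1", k[2]): (96, 4),   # 4% -> not validated
        ("S2", k[3]): (50, 50),
        ("S2", k[4]): (60, 40),
        ("S3", k[5]): (10, 90),
        ("S3", k[6]): (100, 0),
        # k[7] not captured -> excluded from S3's denominator
    }
    rates, med = validation_rate(candidates, capture)
    assert rates == {"S1": 0.5, "S2": 1.0, "S3": 0.5}
    assert med == 0.5


def test_validation_rate_excludes_unassessed_samples():
    key = VariantKey("chr1", 1, "C", "T")
    with pytest.warns(UserWarning, match="no captured variants"):
        rates, med = validation_rate(
            {"S1": [key], "S2": [key]}, {("S1", key): (90, 10)}
        )
    assert rates == {"S1": 1.0} and med == 1.0


def test_validation_rate_order_invariant():
    k = {i: VariantKey("chr1", i, "C", "T") for i in (1, 2)}
    capture = {("S1", k[1]): (90, 10), ("S1", k[2]): (99, 1)}
    a = validation_rate({"S1": [k[1], k[2]]}, capture)
    b = validation_rate({"S1": [k[2], k[1]]}, capture)
    assert a == b


# --- one-tailed rank-sum ---------------------------------------------------


def enumeration_oracle(a, b, alternative):
    """Independent oracle: enumerate every assignment of the pooled values to
    group A positions; compare pairwise-win statistics directly."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(xs, ys):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys)

    observed = u_stat(a, b)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = u_stat(ga, gb)
        total += 1
        if alternative == "less" and u <= observed + 1e-9:
            hits += 1
        if alternative == "greater" and u >= observed - 1e-9:
            hits += 1
    return hits / total


def test_rank_sum_printed_example():
    u, p = rank_sum_one_tailed([1, 2, 3], [4, 5, 6], "less")
    assert u == 0.0
    assert p == pytest.approx(1 / 20)


def test_rank_sum_symmetries():
    a, b = [1.0, 2.0, 5.0, 7.0], [3.0, 4.0, 6.0, 8.0]
    _, p_less = rank_sum_one_tailed(a, b, "less")
    _, p_mirror = rank_sum_one_tailed(b, a, "greater")
    assert p_less == pytest.approx(p_mirror)
    _, p_same = rank_sum_one_tailed(a, a, "less")
    assert p_same >= 0.5


def test_rank_sum_degenerate_identical_values():
    with pytest.warns(UserWarning, match="identical"):
        _, p = rank_sum_one_tailed([2.0, 2.0], [2.0, 2.0, 2.0], "less")
    assert p == 1.0


def test_rank_sum_exact_matches_enumeration_with_ties():
    rng = np.random.default_rng(42)
    for trial in range(25):
        n_a = int(rng.integers(2, 7))
        n_b = int(rng.integers(2, 13 - n_a))
        a = list(rng.integers(0, 5, size=n_a).astype(float))
        b = list(rng.integers(0, 5, size=n_b).astype(float))
        if len(set(a) | set(b)) == 1:
            continue
        for alternative in ("less", "greater"):
            _, p = rank_sum_one_tailed(a, b, alternative)
            assert p == pytest.approx(
                enumeration_oracle(a, b, alternative), abs=1e-12
            ), (a, b, alternative)


def test_rank_sum_large_samples_use_tie_corrected_normal():
    rng = np.random.default_rng(7)
    a = list(rng.normal(0, 1, size=30))
    b = list(rng.normal(1, 1, size=30))
    u, p = rank_sum_one_tailed(a, b, "less")
    assert 0 < p < 0.05  # strong shift detected
    _, p_wrong_tail = rank_sum_one_tailed(a, b, "greater")
    assert p_wrong_tail > 0.5
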