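"""Functional-consequence cascade: region, silent/SPIDEX, expression, vote."""

from itertools import product

import pytest

from prioritizer.functional_filter import (
    PREDICTORS,
    AnnotationRecord,
    EffectClass,
    FunctionalFilterConfig,
    RegionClass,
    Verdict,
    filter_expression,
    filter_region,
    filter_silent,
    predictor_vote,
    read_annotation_table,
    run_functional_cascade,
    write_annotation_table,
)
from prioritizer.somatic_filter import PASS, Stage
from prioritizer.variant_io import Tissue, VariantKey, VariantRecord

CFG = FunctionalFilterConfig(expressed_genes=frozenset({"GENEA", "GENEB"}))


def ann(
    region=RegionClass.EXONIC,
    effect=EffectClass.MISSENSE,
    verdicts=None,
    z=None,
    gene="GENEA",
    pos=100,
    ref="C",
    alt="T",
):
    vmap = {p: Verdict.MISSING for p in PREDICTORS}
    if verdicts:
        for p, v in zip(PREDICTORS, verdicts):
            vmap[p] = Verdict(v)
    return AnnotationRecord(
        key=VariantKey("chr1", pos, ref, alt),
        gene=gene,
        region_class=region,
        effect_class=effect,
        predictor_verdicts=vmap,
        spidex_dpsi_z=z,
    )


# --- individual rules ------------------------------------------------------


@pytest.mark.parametrize(
    "region, verdict",
    [
        (RegionClass.INTRONIC, Stage.REGION.value),
        (RegionClass.SPLICING, PASS),
        (RegionClass.EXONIC_SPLICING, PASS),
        (RegionClass.UTR, Stage.REGION.value),
        (RegionClass.INTERGENIC, Stage.REGION.value),
    ],
)
def test_region_keeps_coding_and_splice_only(region, verdict):
    assert filter_region(ann(region=region)) == verdict


@pytest.mark.parametrize(
    "effect, z, verdict",
    [
        (EffectClass.SILENT, 1.5, Stage.SILENT.value),
        (EffectClass.SILENT, None, Stage.SILENT.value),
        (EffectClass.SILENT, -2.3, PASS),  # |z| >= 2 splicing rescue
        (EffectClass.SILENT, 2.0, PASS),  # inclusive bound
        (EffectClass.MISSENSE, None, PASS),  # rule scope: silent only
    ],
)
def test_silent_rule_with_spidex_rescue(effect, z, verdict):
    assert filter_silent(ann(effect=effect, z=z), CFG) == verdict


def test_expression_rule_exact_match_and_empty_set_error():
    assert filter_expression(ann(gene="GENEA"), CFG) == PASS
    assert filter_expression(ann(gene="OTHER"), CFG) == Stage.UNEXPRESSED.value
    assert filter_expression(ann(gene="genea"), CFG) == Stage.UNEXPRESSED.value
    ci = FunctionalFilterConfig(expressed_genes=frozenset({"GENEA"}), case_insensitive_genes=True)
    assert filter_expression(ann(gene="genea"), ci) == PASS
    with pytest.raises(ValueError):
        filter_expression(ann(), FunctionalFilterConfig(expressed_genes=frozenset()))


# --- predictor vote: printed examples + exhaustive oracle ------------------


@pytest.mark.parametrize(
    "verdicts, expected",
    [
        ("DDDTTT", Stage.PREDICTOR_VOTE.value),  # T=3 = ceil(6/2) -> removed
        ("DDDDTT", PASS),  # T=2 < 3 -> retained
        ("DT....", Stage.PREDICTOR_VOTE.value),  # A=2, T=1 >= ceil(2/2) -> removed
        ("......", PASS),  # no evidence -> retained
    ],
)
def test_vote_printed_examples(verdicts, expected):
    assert predictor_vote(ann(verdicts=verdicts), CFG) == expected


def test_vote_indel_and_spidex_overrides():
    fs = ann(effect=EffectClass.FRAMESHIFT_INDEL, verdicts="TTTTTT", ref="CA", alt="C")
    assert predictor_vote(fs, CFG) == PASS
    rescued = ann(verdicts="TTTTTT", z=2.0)
    assert predictor_vote(rescued, CFG) == PASS


def test_vote_matches_brute_force_oracle_over_all_verdict_vectors():
    """All 3^6 verdict vectors x override flags against a direct evaluation
    of the printed rule: removed iff no override, >=1 available verdict and
    2*T >= A (at least half tolerable)."""
    for verdicts in product("DT.", repeat=6):
        vstr = "".join(verdicts)
        available = sum(1 for v in verdicts if v != ".")
        tolerated = verdicts.count("T")
        for indel, rescued in product([False, True], repeat=2):
            if indel:
                a = ann(
                    effect=EffectClass.FRAMESHIFT_INDEL, verdicts=vstr,
                    z=2.5 if rescued else None, ref="CA", alt="C",
                )
            else:
                a = ann(verdicts=vstr, z=2.5 if rescued else None)
            oracle_removed = (
                not indel and not rescued and available >= 1 and 2 * tolerated >= available
            )
            got = predictor_vote(a, CFG)
            assert (got != PASS) == oracle_removed, (vstr, indel, rescued)


def test_vote_all_denominator_option():
    cfg = FunctionalFilterConfig(
        expressed_genes=frozenset({"GENEA"}), vote_denominator="all"
    )
    # one T among five missing: available denominator removes, full keeps
    assert predictor_vote(ann(verdicts="T....."), CFG) != PASS
    assert predictor_vote(ann(verdicts="T....."), cfg) == PASS


# --- cascade ---------------------------------------------------------------


def rec(pos, ref="C", alt="T"):
    return VariantRecord(
        key=VariantKey("chr1", pos, ref, alt), sample_id="S1", tissue=Tissue.TUMOR,
        callers=frozenset({"bcftools", "varscan"}),
    )


def test_cascade_order_unexpressed_beats_spidex_rescue():
    # a SILENT variant with z=2.5 in an unexpressed gene dies at UNEXPRESSED,
    # not at SILENT: the rescue applies but the expression filter follows
    annotations = {
        VariantKey("chr1", 100, "C", "T"): ann(
            effect=EffectClass.SILENT, z=2.5, gene="OTHER", pos=100
        )
    }
    retained, traces = run_functional_cascade({"S1": [rec(100)]}, annotations, CFG)
    assert retained["S1"] == []
    assert [t.stage for t in traces] == [Stage.UNEXPRESSED]


def test_cascade_survivor_and_empty_input():
    annotations = {VariantKey("chr1", 100, "C", "T"): ann(verdicts="DDDDTT", pos=100)}
    retained, traces = run_functional_cascade({"S1": [rec(100)]}, annotations, CFG)
    assert [r.key.pos for r in retained["S1"]] == [100] and traces == []
    retained, traces = run_functional_cascade({"S1": []}, {}, CFG)
    assert retained == {"S1": []} and traces == []


def test_cascade_missing_annotation_lists_keys():
    with pytest.raises(ValueError, match="chr1:100"):
        run_functional_cascade({"S1": [rec(100)]}, {}, CFG)


def test_cascade_counts_reconstruct_from_traces():
    annotations = {
        VariantKey("chr1", p, "C", "T"): a
        for p, a in [
            (1, ann(region=RegionClass.INTRONIC, pos=1)),
            (2, ann(effect=EffectClass.SILENT, pos=2)),
            (3, ann(gene="OTHER", pos=3)),
            (4, ann(verdicts="TTTTTT", pos=4)),
            (5, ann(verdicts="DDDDDD", pos=5)),
        ]
    }
    records = {"S1": [rec(p) for p in range(1, 6)]}
    retained, traces = run_functional_cascade(records, annotations, CFG)
    assert len(retained["S1"]) + len(traces) == 5
    assert [t.stage for t in sorted(traces, key=lambda t: t.key.pos)] == [
        Stage.REGION, Stage.SILENT, Stage.UNEXPRESSED, Stage.PREDICTOR_VOTE,
    ]


# --- annotation table round-trip -------------------------------------------


def test_annotation_table_round_trip(tmp_path):
    annotations = {
        VariantKey("chr1", 100, "C", "T"): ann(verdicts="DDT.T.", z=1.25, pos=100),
        VariantKey("chr1", 5, "CA", "C"): ann(
            effect=EffectClass.FRAMESHIFT_INDEL, gene="GENEB", pos=5, ref="CA", alt="C"
        ),
    }
    path = tmp_path / "ann.tsv"
    write_annotation_table(annotations, path)
    assert read_annotation_table(path) == annotations
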