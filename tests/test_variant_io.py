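"""Variant normalization and format round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prioritizer.variant_io import (
    GeneInterval,
    Tissue,
    VariantKey,
    VcfParseError,
    normalize_variant,
    read_caller_vcf,
    read_counts_table,
    read_gene_bed,
    read_maf_like,
    read_seg,
    write_maf_like,
)

# --- normalization ---------------------------------------------------------


@pytest.mark.parametrize(
    "raw, expected",
    [
        (("chr1", 100, "AT", "AG"), ("chr1", 101, "T", "G")),  # prefix trim
        (("chr1", 100, "AT", "AC"), ("chr1", 101, "T", "C")),
        (("chr6", 50, "C", "T"), ("chr6", 50, "C", "T")),  # already canonical
        (("chr1", 100, "CTT", "CT"), ("chr1", 100, "CT", "C")),  # suffix then anchor
    ],
)
def test_normalize_trims_shared_bases(raw, expected):
    assert normalize_variant(VariantKey(*raw)) == VariantKey(*expected)


def test_normalize_rejects_identical_alleles():
    with pytest.raises(ValueError):
        normalize_variant(VariantKey("chr1", 100, "G", "G"))


def _left_align_oracle(seq, pos, ref, alt):
    """Exhaustively shift a single-base anchored deletion across the printed
    local context; the minimal-position representation producing the same
    edited sequence is the canonical one."""
    edited = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    reps = []
    for p in range(1, len(seq)):
        r = seq[p - 1 : p + 1]
        a = r[0]
        if seq[: p - 1] + a + seq[p + 1 :] == edited:
            reps.append((p, r, a))
    return min(reps)


def test_normalize_left_aligns_deletion_in_homopolymer():
    # reference: T A C C C C T...  (A at position 10, C-run at 11..14)
    seq = "T" * 9 + "ACCCC" + "T" * 6

    def ctx(chrom, start, end):
        return seq[start - 1 : end]

    got = normalize_variant(VariantKey("chr1", 12, "CC", "C"), ctx)
    p, r, a = _left_align_oracle(seq, 12, "CC", "C")
    assert (got.pos, got.ref, got.alt) == (p, r, a) == (10, "AC", "A")


def test_normalize_left_align_is_idempotent_with_reference():
    seq = "GGGGATATATCCCC"

    def ctx(chrom, start, end):
        return seq[start - 1 : end]

    key = normalize_variant(VariantKey("chr1", 9, "ATA", "A"), ctx)
    assert normalize_variant(key, ctx) == key


@given(
    chrom=st.sampled_from(["chr1", "chrX"]),
    pos=st.integers(min_value=5, max_value=1000),
    core_ref=st.text(alphabet="ACGT", min_size=1, max_size=4),
    core_alt=st.text(alphabet="ACGT", min_size=1, max_size=4),
    flank=st.text(alphabet="ACGT", min_size=0, max_size=3),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_normalize_idempotent_without_reference(chrom, pos, core_ref, core_alt, flank):
    if core_ref == core_alt:
        return
    key = VariantKey(chrom, pos, flank + core_ref + flank, flank + core_alt + flank)
    try:
        once = normalize_variant(key)
    except ValueError:
        return  # alleles collapse entirely; rejected without a reference
    assert normalize_variant(once) == once
    # no shared prefix/suffix beyond the indel anchor remains
    if len(once.ref) > 1 and len(once.alt) > 1:
        assert once.ref[0] != once.alt[0]
        assert once.ref[-1] != once.alt[-1]


# --- VCF reading -----------------------------------------------------------


def _write(path, text):
    path.write_text(text)
    return path


VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def test_read_vcf_splits_multiallelic_and_normalizes(tmp_path):
    vcf = _write(tmp_path / "a.vcf", VCF_HEADER + "chr1\t100\t.\tAT\tAG,AC\t.\t.\t.\n")
    records = read_caller_vcf(vcf, "bcftools", "S1", Tissue.TUMOR)
    assert [r.key for r in records] == [
        VariantKey("chr1", 101, "T", "C"),
        VariantKey("chr1", 101, "T", "G"),
    ]
    assert all(r.callers == frozenset({"bcftools"}) for r in records)


def test_read_vcf_split_is_allele_order_independent(tmp_path):
    a = _write(tmp_path / "a.vcf", VCF_HEADER + "chr1\t100\t.\tAT\tAG,AC\t.\t.\t.\n")
    b = _write(tmp_path / "b.vcf", VCF_HEADER + "chr1\t100\t.\tAT\tAC,AG\t.\t.\t.\n")
    keys = lambda p: [r.key for r in read_caller_vcf(p, "varscan", "S1", Tissue.TUMOR)]
    assert keys(a) == keys(b)


def test_read_vcf_identity_and_empty(tmp_path):
    vcf = _write(tmp_path / "a.vcf", VCF_HEADER + "chr6\t50\t.\tC\tT\t.\t.\t.\n")
    (rec,) = read_caller_vcf(vcf, "varscan", "S1", Tissue.TUMOR)
    assert rec.key == VariantKey("chr6", 50, "C", "T")
    assert rec.callers == frozenset({"varscan"})
    empty = _write(tmp_path / "e.vcf", VCF_HEADER)
    assert read_caller_vcf(empty, "varscan", "S1", Tissue.TUMOR) == []


def test_read_vcf_malformed_line_names_line_number(tmp_path):
    vcf = _write(tmp_path / "bad.vcf", VCF_HEADER + "chr1\tXYZ\t.\tA\tT\t.\t.\t.\n")
    with pytest.raises(VcfParseError, match="line 3"):
        read_caller_vcf(vcf, "bcftools", "S1", Tissue.TUMOR)


# --- counts table ----------------------------------------------------------

COUNTS_HEADER = "sample\tchrom\tpos\tref\talt\ttumor_ref\ttumor_alt\tnormal_ref\tnormal_alt\n"


def test_read_counts_table_vafs_and_zero_depth(tmp_path):
    path = _write(
        tmp_path / "c.tsv",
        COUNTS_HEADER
        + "S1\tchr6\t100\tC\tT\t90\t10\t100\t0\n"
        + "S1\tchr6\t200\tC\tT\t0\t0\t0\t0\n",
    )
    counts = read_counts_table(path)
    c = counts[("S1", VariantKey("chr6", 100, "C", "T"))]
    assert c.tumor_vaf == pytest.approx(0.10) and c.normal_vaf == 0.0
    zero = counts[("S1", VariantKey("chr6", 200, "C", "T"))]
    assert zero.tumor_vaf == 0.0  # depth-0 accepted; downstream rules decide


def test_read_counts_table_rejects_duplicates_and_negatives(tmp_path):
    dup = _write(
        tmp_path / "dup.tsv",
        COUNTS_HEADER + "S1\tchr6\t100\tC\tT\t1\t1\t1\t1\nS1\tchr6\t100\tC\tT\t2\t2\t2\t2\n",
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_counts_table(dup)
    neg = _write(tmp_path / "neg.tsv", COUNTS_HEADER + "S1\tchr6\t100\tC\tT\t-1\t1\t1\t1\n")
    with pytest.raises(ValueError, match="negative"):
        read_counts_table(neg)
    short = _write(tmp_path / "short.tsv", "sample\tchrom\tpos\n")
    with pytest.raises(ValueError, match="missing column"):
        read_counts_table(short)


# --- SEG / BED -------------------------------------------------------------

SEG_HEADER = "sample\tchrom\tstart\tend\tseg_mean\n"


def test_read_seg_rejects_overlap_listing_rows(tmp_path):
    path = _write(
        tmp_path / "o.seg",
        SEG_HEADER + "S1\tchr6\t1\t10\t-1.4\nS1\tchr6\t5\t20\t0\n",
    )
    with pytest.raises(ValueError, match="overlap"):
        read_seg(path)


def test_read_seg_allows_adjacent_segments(tmp_path):
    path = _write(tmp_path / "a.seg", SEG_HEADER + "S1\tchr6\t1\t10\t-1.4\nS1\tchr6\t11\t20\t0\n")
    segs = read_seg(path)
    assert [s.start for s in segs] == [1, 11]


def test_read_gene_bed_converts_coordinates_and_collapses(tmp_path):
    path = _write(
        tmp_path / "g.bed",
        "chr6\t1000\t2000\tSHPRH\n" + "chr6\t3000\t4000\tSHPRH\n" + "chr1\t0\t100\tTP53\t0\t-\n",
    )
    intervals = {g.gene: g for g in read_gene_bed(path)}
    assert intervals["SHPRH"] == GeneInterval("SHPRH", "chr6", 1001, 4000, ".")
    assert (intervals["TP53"].start, intervals["TP53"].end) == (1, 100)
    assert read_gene_bed(_write(tmp_path / "e.bed", "")) == []


# --- MAF-like round-trip ---------------------------------------------------


def test_maf_like_round_trip_is_exact(tmp_path):
    rows = [
        {
            "sample": "S1", "gene": "G0001", "chrom": "chr1", "pos": 123,
            "ref": "C", "alt": "T", "effect": "MISSENSE", "callers": "bcftools,varscan",
            "tumor_ref": 80, "tumor_alt": 20, "normal_ref": 99, "normal_alt": 1,
            "tumor_vaf": 0.2, "normal_vaf": 0.01, "filter_provenance": "PASS",
        },
        {
            "sample": "S2", "gene": "G0002", "chrom": "chr2", "pos": 7,
            "ref": "AT", "alt": "A", "effect": "FRAMESHIFT_INDEL", "callers": "freebayes",
            "tumor_ref": 10, "tumor_alt": 3, "normal_ref": 12, "normal_alt": 0,
            "tumor_vaf": 3 / 13, "normal_vaf": 0.0, "filter_provenance": "PASS",
        },
    ]
    path = tmp_path / "m.tsv"
    write_maf_like(rows, path)
    assert read_maf_like(path) == rows
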