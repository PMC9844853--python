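"""Interval algebra, genome queries, annotation and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cistromics.genome_model import (
    DETable,
    Genome,
    GenomicInterval,
    IntervalSet,
    MalformedRecordError,
    PWM,
    SNPRecord,
    TSSMap,
    gc_content,
    mask_base,
    nearest_tss,
    overlap_count,
    read_intervals,
    read_pwm,
    read_snps_vcf,
    write_intervals,
    write_pwm,
    write_snps_vcf,
)
from conftest import random_interval_set


# ---------------------------------------------------------------------------
# Interval validity
# ---------------------------------------------------------------------------

def test_interval_invariants_enforced():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 10, summit=10)
    iv = GenomicInterval("chr1", 10, 30, summit=5)
    assert iv.anchor == 15
    assert GenomicInterval("chr1", 10, 30).anchor == 20


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

@st.composite
def interval_strategy(draw):
    start = draw(st.integers(0, 10_000))
    length = draw(st.integers(1, 500))
    summit = draw(st.one_of(st.none(), st.integers(0, length - 1)))
    return GenomicInterval(
        contig=draw(st.sampled_from(["chr1", "chr2", "scaffold_9"])),
        start=start,
        end=start + length,
        strand=draw(st.sampled_from(["+", "-", "."])),
        score=draw(st.one_of(st.none(), st.floats(-100, 100, allow_nan=False))),
        summit=summit,
    )


@given(st.lists(interval_strategy(), max_size=30), st.sampled_from(["bed", "tsv"]))
def test_interval_round_trip(tmp_path_factory, intervals, fmt):
    """write_intervals then read_intervals reproduces every field exactly."""
    path = tmp_path_factory.mktemp("io") / f"peaks.{fmt}"
    s = IntervalSet("peaks", intervals)
    write_intervals(s, path, fmt)
    back = read_intervals(path, fmt)
    assert list(back) == list(s)


def test_empty_file_and_empty_set(tmp_path):
    path = tmp_path / "empty.bed"
    path.write_text("")
    assert len(read_intervals(path, "bed")) == 0
    write_intervals(IntervalSet("none"), tmp_path / "out.tsv", "tsv")
    assert len(read_intervals(tmp_path / "out.tsv", "tsv")) == 0


def test_bed_three_lines(tmp_path):
    path = tmp_path / "three.bed"
    path.write_text("chr1\t0\t100\nchr1\t50\t150\nchr2\t10\t20\n")
    s = read_intervals(path, "bed")
    assert len(s) == 3
    assert s[0] == GenomicInterval("chr1", 0, 100)
    out = tmp_path / "rt.bed"
    write_intervals(s, out, "bed")
    assert list(read_intervals(out, "bed")) == list(s)


def test_tsv_one_based_conversion(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("contig\tstart\tend\nchr1\t1\t100\n")
    s = read_intervals(path, "tsv")
    assert (s[0].start, s[0].end) == (0, 100)


def test_malformed_lines_name_line_number(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t0\t100\nchr1\t200\t100\n")
    with pytest.raises(MalformedRecordError, match=":2"):
        read_intervals(path, "bed")
    path.write_text("chr1\t0\n")
    with pytest.raises(MalformedRecordError, match=":1"):
        read_intervals(path, "bed")


def test_snp_vcf_round_trip(tmp_path):
    snps = [SNPRecord("rs1", "chr1", 99, "C", "T"), SNPRecord("rs2", "chr2", 0, "A", "G")]
    path = tmp_path / "snps.vcf"
    write_snps_vcf(snps, path)
    assert read_snps_vcf(path) == snps


def test_fasta_round_trip(tmp_path, toy_genome):
    path = tmp_path / "g.fa"
    toy_genome.to_fasta(path)
    back = Genome.from_fasta(path)
    assert back.contigs == toy_genome.contigs


# ---------------------------------------------------------------------------
# overlap_count
# ---------------------------------------------------------------------------

def brute_force_overlap(a, b, min_bp=1):
    hits = []
    for iv in a:
        for jv in b:
            if iv.contig == jv.contig and min(iv.end, jv.end) - max(iv.start, jv.start) >= min_bp:
                hits.append(iv)
                break
    return len(hits), hits


def test_overlap_disjoint_contigs():
    a = IntervalSet("a", [GenomicInterval("chr1", 0, 100)])
    b = IntervalSet("b", [GenomicInterval("chr2", 0, 100)])
    assert overlap_count(a, b)[0] == 0


def test_overlap_min_bp_validation():
    a = IntervalSet("a", [GenomicInterval("chr1", 0, 100)])
    with pytest.raises(ValueError):
        overlap_count(a, a, min_bp=0)


@pytest.mark.parametrize("min_bp", [1, 5, 30])
def test_overlap_matches_brute_force(min_bp):
    """Query-side overlap equals an all-pairs scan on 100 random instances."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        a = random_interval_set(rng, int(rng.integers(0, 50)), name="a")
        b = random_interval_set(rng, int(rng.integers(0, 50)), name="b")
        n_expect, hits_expect = brute_force_overlap(a, b, min_bp)
        n_got, hits_got = overlap_count(a, b, min_bp=min_bp)
        assert n_got == n_expect
        assert hits_got == hits_expect
        assert n_got <= len(a)


def test_overlap_counts_query_side_once():
    a = IntervalSet("a", [GenomicInterval("chr1", 0, 100)])
    b = IntervalSet("b", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 50, 60)])
    assert overlap_count(a, b)[0] == 1  # one a-interval, two b hits
    assert overlap_count(b, a)[0] == 2  # asymmetric from the other side


# ---------------------------------------------------------------------------
# nearest_tss
# ---------------------------------------------------------------------------

def brute_force_nearest(iv, tss):
    best = None
    for gene, (contig, pos, _s) in sorted(tss.items()):
        if contig != iv.contig:
            continue
        d = abs(iv.anchor - pos)
        if best is None or d < best[1] or (d == best[1] and gene < best[0]):
            best = (gene, d)
    return best


def test_nearest_tss_exact_hit(toy_tss):
    peaks = IntervalSet("p", [GenomicInterval("chr1", 90, 110)])  # midpoint 100
    out = nearest_tss(peaks, toy_tss)
    assert out.loc[0, "gene"] == "geneA"
    assert out.loc[0, "distance"] == 0


def test_nearest_tss_matches_brute_force(toy_tss):
    rng = np.random.default_rng(1)
    for _ in range(100):
        peaks = random_interval_set(rng, 20, max_pos=4800)
        out = nearest_tss(peaks, toy_tss)
        for i, iv in enumerate(peaks):
            gene, dist = brute_force_nearest(iv, toy_tss)
            assert out.loc[i, "gene"] == gene
            assert out.loc[i, "distance"] == dist


def test_nearest_tss_order_invariant_and_tie_break():
    tss_fwd = TSSMap({"gB": ("chr1", 200, "+"), "gA": ("chr1", 100, "+")})
    tss_rev = TSSMap({"gA": ("chr1", 100, "+"), "gB": ("chr1", 200, "+")})
    peaks = IntervalSet("p", [GenomicInterval("chr1", 140, 160)])  # midpoint 150, tie
    out_f = nearest_tss(peaks, tss_fwd)
    out_r = nearest_tss(peaks, tss_rev)
    assert out_f.loc[0, "gene"] == out_r.loc[0, "gene"] == "gA"  # lexicographic


def test_nearest_tss_flags_contig_without_tss(toy_tss):
    peaks = IntervalSet("p", [GenomicInterval("chrM", 0, 10)])
    out = nearest_tss(peaks, toy_tss)
    assert len(out) == 1
    assert out.loc[0, "gene"] is None
    assert np.isnan(out.loc[0, "distance"])


# ---------------------------------------------------------------------------
# gc_content / mask_base
# ---------------------------------------------------------------------------

def test_gc_content_basic_cases():
    g = Genome({"c": "GGGGACGTNNNN"})
    assert gc_content(g, GenomicInterval("c", 0, 4)) == 1.0
    assert gc_content(g, GenomicInterval("c", 4, 8)) == 0.5
    assert np.isnan(gc_content(g, GenomicInterval("c", 8, 12)))  # all N
    # N excluded from numerator and denominator
    assert gc_content(g, GenomicInterval("c", 4, 12)) == 0.5
    with pytest.raises(ValueError):
        gc_content(g, GenomicInterval("c", 4, 13))


def test_gc_content_matches_counting_oracle(toy_genome):
    rng = np.random.default_rng(3)
    for _ in range(50):
        start = int(rng.integers(0, 2900))
        end = start + int(rng.integers(1, 100))
        seq = toy_genome.fetch("chr2", start, end)
        expected = sum(b in "GC" for b in seq) / len(seq)
        assert gc_content(toy_genome, GenomicInterval("chr2", start, end)) == pytest.approx(expected)


@given(st.integers(0, 97), st.integers(1, 40), st.integers(1, 40))
def test_gc_partition_property(start, left_len, right_len):
    """GC of an interval equals the length-weighted mean of a 2-part split."""
    rng = np.random.default_rng(start)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=200)])
    g = Genome({"c": seq})
    mid = start + left_len
    end = mid + right_len
    whole = gc_content(g, GenomicInterval("c", start, end))
    left = gc_content(g, GenomicInterval("c", start, mid))
    right = gc_content(g, GenomicInterval("c", mid, end))
    weighted = (left * left_len + right * right_len) / (left_len + right_len)
    assert whole == pytest.approx(weighted)


def test_mask_base_and_idempotence():
    g = Genome({"c": "ACGTACGT"})
    snp = SNPRecord("rs", "c", 2, "G", "T")
    masked = mask_base(g, snp)
    assert masked["c"][2] == "N"
    assert g["c"][2] == "G"  # input untouched
    assert mask_base(masked, snp)["c"] == masked["c"]  # idempotent
    before = g.base_counts("c")
    after = masked.base_counts("c")
    assert before["G"] - after["G"] == 1 and after["N"] - before["N"] == 1
    with pytest.raises(ValueError):
        mask_base(g, SNPRecord("rs2", "c", 2, "A", "C"))  # base matches neither allele
    with pytest.raises(ValueError):
        mask_base(g, SNPRecord("rs3", "c", 99, "G", "T"))


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

def test_pwm_from_counts_normalization():
    # uniform counts -> uniform probabilities
    pwm = PWM.from_counts(np.full((3, 4), 2.0), pseudocount=0.0)
    assert np.allclose(pwm.matrix, 0.25)
    # pseudocount 1 under uniform background: (c + 1) / (sum + 4)
    counts = np.array([[3.0, 1.0, 0.0, 0.0]])
    pwm = PWM.from_counts(counts, pseudocount=1.0)
    assert np.allclose(pwm.matrix, (counts + 1) / (counts.sum() + 4))
    # single column, pseudocount 0
    pwm = PWM.from_counts(np.array([[1.0, 0.0, 0.0, 0.0]]), pseudocount=0.0)
    assert pwm.matrix[0, 0] == 1.0


def test_pwm_validation():
    with pytest.raises(ValueError):
        PWM.from_counts(np.array([[1.0, -1.0, 0.0, 0.0]]))
    with pytest.raises(ValueError):
        PWM(np.array([[0.5, 0.5, 0.5, 0.5]]))  # rows must sum to 1


def test_read_pwm_jaspar_and_pfm(tmp_path):
    counts = np.array([[8.0, 0.0, 0.0, 2.0], [0.0, 10.0, 0.0, 0.0]])
    jaspar = tmp_path / "m.jaspar"
    write_pwm(counts, jaspar, name="toy")
    pwm = read_pwm(jaspar, pseudocount=1.0)
    assert np.allclose(pwm.matrix, (counts + 1) / (counts.sum(axis=1, keepdims=True) + 4))
    pfm = tmp_path / "m.pfm"
    pfm.write_text("8 0\n0 10\n0 0\n2 0\n")  # A/C/G/T rows
    pwm2 = read_pwm(pfm, pseudocount=1.0)
    assert np.allclose(pwm2.matrix, pwm.matrix)
    bad = tmp_path / "bad.pfm"
    bad.write_text("1 2\n3\n4 5\n6 7\n")
    with pytest.raises(MalformedRecordError):
        read_pwm(bad)


def test_pwm_score_strands():
    pwm = PWM(np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]]))  # consensus AT
    fwd = pwm.score("AT", "+")
    rev = pwm.score("AT", "-")  # revcomp(AT) = AT, palindromic here
    assert fwd == pytest.approx(rev)
    assert pwm.score("AT", "+") > pwm.score("GC", "+")


# ---------------------------------------------------------------------------
# DETable
# ---------------------------------------------------------------------------

def test_de_table_fold_change_convention():
    de = DETable.from_log2fc(["a", "b", "c"], [2.0, -3.0, 0.0], [0.01, 0.001, 0.9])
    fc = dict(zip(de.frame["gene"], de.frame["fold_change"]))
    assert fc["a"] == pytest.approx(4.0)
    assert fc["b"] == pytest.approx(-8.0)
    assert fc["c"] == pytest.approx(1.0)


def test_de_table_round_trip(tmp_path):
    de = DETable.from_log2fc(["a", "b"], [1.5, -0.5], [0.2, np.nan])
    path = tmp_path / "de.tsv"
    de.to_tsv(path)
    back = DETable.from_tsv(path)
    pd.testing.assert_frame_equal(back.frame, de.frame)
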