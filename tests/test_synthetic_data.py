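"""Generators: determinism, planted-truth consistency and configured
statistical structure."""

import numpy as np
import pytest

from cistromics.genome_model import gc_content, GenomicInterval, IntervalSet, overlap_count
from cistromics.peak_integration import filter_degs
from cistromics.synthetic_data import (
    AIConfig,
    DEConfig,
    GenomeConfig,
    LDConfig,
    PeakConfig,
    SimulationConfig,
    gen_allelic_reads,
    gen_de_table,
    gen_genome,
    gen_genotypes,
    gen_peaksets,
    gen_study,
    pick_planted_targets,
    synthetic_motif_pwm,
    write_study,
)
from cistromics.variant_pipeline import intersect_snps_peaks, ld_r2, scan_allele_effect
from cistromics.allelic_imbalance import allelic_imbalance_test, count_alleles, filter_reads
from cistromics.genome_model import SNPRecord

SMALL_GENOME = GenomeConfig(n_contigs=2, contig_length=100_000, open_fraction=0.15)


def small_cfg(seed, **kw):
    kw.setdefault("genome", SMALL_GENOME)
    return SimulationConfig(seed=seed, **kw)


class TestGenGenome:
    def test_pure_gc_stratum(self):
        cfg = SimulationConfig(
            seed=0, genome=GenomeConfig(n_contigs=1, contig_length=2_000, gc_strata=(1.0,))
        )
        genome, _, _ = gen_genome(cfg)
        assert set(genome["chr1"]) <= {"G", "C"}

    def test_strata_composition_law_of_large_numbers(self):
        cfg = SimulationConfig(
            seed=1,
            genome=GenomeConfig(n_contigs=1, contig_length=300_000, gc_strata=(0.3, 0.7)),
        )
        genome, _, _ = gen_genome(cfg)
        third = 150_000
        lo = gc_content(genome, GenomicInterval("chr1", 0, third))
        hi = gc_content(genome, GenomicInterval("chr1", third, 300_000))
        assert lo == pytest.approx(0.3, abs=0.02)
        assert hi == pytest.approx(0.7, abs=0.02)

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = small_cfg(7)
        g1, oc1, tss1 = gen_genome(cfg)
        g2, oc2, tss2 = gen_genome(cfg)
        assert g1.contigs == g2.contigs
        assert list(oc1) == list(oc2)
        assert dict(tss1.items()) == dict(tss2.items())
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        g1.to_fasta(p1)
        g2.to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_open_fraction_roughly_met(self):
        cfg = small_cfg(3)
        genome, oc, _ = gen_genome(cfg)
        covered = sum(iv.length for iv in oc)
        total = sum(genome.lengths.values())
        assert covered / total == pytest.approx(cfg.genome.open_fraction, rel=0.5)


class TestGenPeaksets:
    def test_full_overlap_fraction(self):
        cfg = small_cfg(4, peaks=PeakConfig(n_a=50, n_b=150, overlap_fraction=1.0))
        _, oc, _ = gen_genome(cfg)
        a, b, truth = gen_peaksets(cfg, oc)
        assert overlap_count(a, b)[0] == len(a) == 50
        assert truth["n_planted"] == 50

    def test_zero_fraction_near_chance(self):
        """With no planting and a B set sparse within open chromatin (the
        regime of real cistrome pairs), chance co-occupancy stays below 10%
        of |A| and matches the independent-placement expectation."""
        cfg = small_cfg(
            5,
            genome=GenomeConfig(n_contigs=2, contig_length=100_000, open_fraction=0.3),
            peaks=PeakConfig(n_a=200, n_b=10, overlap_fraction=0.0),
        )
        _, oc, _ = gen_genome(cfg)
        a, b, _ = gen_peaksets(cfg, oc)
        n, _ = overlap_count(a, b)
        assert n < 0.10 * len(a)
        # chance expectation: footprint of B (padded by a peak length) over open bp
        oc_bp = sum(iv.length for iv in oc)
        expected = len(a) * sum(iv.length + 200 for iv in b) / oc_bp
        assert abs(n - expected) < 4 * np.sqrt(expected)

    def test_planted_are_subset_of_hits(self):
        cfg = small_cfg(6, peaks=PeakConfig(n_a=60, n_b=120, overlap_fraction=0.5))
        _, oc, _ = gen_genome(cfg)
        a, b, truth = gen_peaksets(cfg, oc)
        _, hits = overlap_count(a, b)
        hit_set = {(iv.contig, iv.start, iv.end) for iv in hits}
        for idx in truth["planted_overlap_indices"]:
            iv = a[idx]
            assert (iv.contig, iv.start, iv.end) in hit_set

    def test_peaks_inside_open_chromatin(self):
        cfg = small_cfg(8)
        _, oc, _ = gen_genome(cfg)
        a, b, _ = gen_peaksets(cfg, oc)
        lookup = oc.by_contig()
        for iv in list(a) + list(b):
            starts, ends, _ = lookup[iv.contig]
            k = np.searchsorted(starts, iv.start, side="right") - 1
            assert starts[k] <= iv.start and iv.end <= ends[k]


class TestGenDETable:
    def test_fc_log2fc_consistent(self):
        cfg = small_cfg(9)
        genes = [f"g{i}" for i in range(100)]
        de, _ = gen_de_table(cfg, genes, set(genes[:10]))
        l2 = de.frame["log2_fc"].to_numpy()
        fc = de.frame["fold_change"].to_numpy()
        assert np.allclose(np.abs(fc), 2.0 ** np.abs(l2))
        assert np.all(np.sign(fc) == np.where(l2 >= 0, 1, -1))

    def test_null_effect_yields_no_calls(self):
        """Effect 0 with non-significant null padj: the filter recovers
        nothing beyond FDR-level noise."""
        cfg = small_cfg(10, de=DEConfig(n_down=0, n_up=0))
        genes = [f"g{i}" for i in range(1000)]
        de, _ = gen_de_table(cfg, genes, set())
        down, up = filter_degs(de)
        assert len(down) + len(up) == 0  # null padj drawn above 0.1

    def test_planted_down_fully_recovered_across_seeds(self):
        """Effect -3 log2 at noise 0.3: every planted down gene is called
        in 20/20 seeds."""
        for seed in range(20):
            cfg = small_cfg(seed, de=DEConfig(n_down=30, n_up=10, effect_log2=3.0, noise_sd=0.3))
            genes = [f"g{i}" for i in range(1000)]
            down_t, up_t = set(genes[:30]), set(genes[30:40])
            de, truth = gen_de_table(cfg, genes, down_t, up_t)
            down, up = filter_degs(de)
            assert down == down_t
            assert up == up_t


class TestGenGenotypes:
    def test_q_one_gives_perfect_ld(self):
        cfg = small_cfg(11, ld=LDConfig(n_blocks=1, block_size=4, copy_prob=1.0))
        g, _ = gen_genotypes(cfg)
        for i in range(4):
            for j in range(i + 1, 4):
                assert ld_r2(g, i, j) == pytest.approx(1.0)

    def test_q_zero_indistinguishable_from_unlinked(self):
        within, between = [], []
        for seed in range(20):
            cfg = small_cfg(seed, ld=LDConfig(n_blocks=2, block_size=4, copy_prob=0.0, n_samples=300))
            g, _ = gen_genotypes(cfg)
            within.append(ld_r2(g, 0, 1))
            between.append(ld_r2(g, 0, 4))
        assert abs(np.mean(within) - np.mean(between)) < 0.01

    def test_r2_monotone_in_copy_prob(self):
        means = []
        for q in (0.5, 0.7, 0.9):
            vals = []
            for seed in range(20):
                cfg = small_cfg(seed, ld=LDConfig(n_blocks=1, block_size=4, copy_prob=q, n_samples=300))
                g, _ = gen_genotypes(cfg)
                vals.extend(ld_r2(g, i, j) for i in range(4) for j in range(i + 1, 4))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestGenAllelicReads:
    SNP = SNPRecord("rs", "chr1", 100, "C", "T")

    def test_balanced_ratio_law_of_large_numbers(self):
        cfg = small_cfg(12, ai=AIConfig(depth=10_000, imbalance_ratio=1.0, n_donors=1, bad_read_fraction=0.0))
        reads, truth = gen_allelic_reads(cfg, self.SNP)
        c = truth[0]
        assert c.n_ref / (c.n_ref + c.n_alt) == pytest.approx(0.5, abs=0.02)

    def test_all_duplicates_filtered_to_zero(self):
        cfg = small_cfg(13, ai=AIConfig(depth=30, n_donors=1, bad_read_fraction=1.0))
        reads, _ = gen_allelic_reads(cfg, self.SNP)
        # force all-bad reads: every read carries some disqualifying flag
        kept = filter_reads(reads["donor1"])
        assert kept == []

    def test_truth_matches_post_filter_counts(self):
        cfg = small_cfg(14, ai=AIConfig(depth=60, imbalance_ratio=3.0, n_donors=2, bad_read_fraction=0.2))
        reads, truth = gen_allelic_reads(cfg, self.SNP)
        for c in truth:
            counted = count_alleles(filter_reads(reads[c.donor]), self.SNP, c.donor)
            assert (counted.n_ref, counted.n_alt) == (c.n_ref, c.n_alt)

    def test_seed_determinism(self):
        cfg = small_cfg(15)
        r1, t1 = gen_allelic_reads(cfg, self.SNP)
        r2, t2 = gen_allelic_reads(cfg, self.SNP)
        assert r1 == r2 and t1 == t2


@pytest.fixture(scope="module")
def bundle():
    cfg = SimulationConfig(
        seed=20,
        genome=GenomeConfig(n_contigs=2, contig_length=150_000, open_fraction=0.2),
        peaks=PeakConfig(n_a=80, n_b=200, overlap_fraction=0.65),
        n_genes=150,
        de=DEConfig(n_down=20, n_up=5),
    )
    return gen_study(cfg)


class TestStudyBundle:
    def test_risk_snp_inside_both_cistromes_within_motif(self, bundle):
        _, hits = intersect_snps_peaks([bundle.risk_snp], [bundle.set_a, bundle.set_b])
        assert hits == [bundle.risk_snp]
        eff = scan_allele_effect(bundle.pwm, bundle.genome, bundle.risk_snp, flank=12)
        assert eff.delta < 0  # T allele breaks the planted consensus

    def test_down_targets_recovered_and_shifted(self, bundle):
        down, _ = filter_degs(bundle.de_table)
        assert down == set(bundle.de_truth["down"])

    def test_allelic_imbalance_detected_in_bundle(self, bundle):
        counts = [
            count_alleles(filter_reads(rs), bundle.risk_snp, d)
            for d, rs in bundle.reads_by_donor.items()
        ]
        res = allelic_imbalance_test(counts)
        assert res.df == 4

    def test_write_study_plain_text(self, bundle, tmp_path):
        write_study(bundle, tmp_path)
        expected = {
            "genome.fa", "open_chromatin.bed", "peaks_A.bed", "peaks_B.bed",
            "tss.tsv", "de_table.tsv", "genotypes.tsv", "risk_snp.vcf",
            "motif_synthetic.jaspar", "allelic_reads.tsv", "truth.json",
        }
        assert {p.name for p in tmp_path.iterdir()} == expected


def test_motif_pwm_consensus():
    pwm = synthetic_motif_pwm()
    assert pwm.width == 6
    assert pwm.score("TAATCA") > pwm.score("TAATTA")  # C fits, T breaks
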