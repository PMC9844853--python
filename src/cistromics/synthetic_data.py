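"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of a TF-cistrome /
expression / regulatory-variant study on a toy genome: GC-stratified contig
sequences with open-chromatin intervals and uniform TSSs; two peak sets
with a controllable planted co-occupancy fraction; a differential-
expression table with a planted down-shift in a designated target set;
LD-block genotypes with tunable within-block r-squared; and per-donor
allele read pileups with a planted imbalance ratio.

Every generator is a pure function of :class:`SimulationConfig` — all
randomness flows from ``cfg.seed`` through per-stage named streams, so
outputs are byte-identical per seed and adding a stage never perturbs the
streams of earlier ones.  Each generator returns its truth record so tests
never re-derive planted ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genome_model import (
    DETable,
    Genome,
    GenomicInterval,
    IntervalSet,
    PWM,
    SNPRecord,
    TSSMap,
    write_intervals,
    write_pwm,
    write_snps_vcf,
)
from .allelic_imbalance import AlleleCounts, ReadRecord, write_reads_tsv
from .variant_pipeline import GenotypeMatrix

BASES = np.array(list("ACGT"))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for a named pipeline stage."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode("ascii"))])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    n_contigs: int = 2
    contig_length: int = 1_000_000
    gc_strata: tuple[float, ...] = (0.35, 0.5, 0.65)
    open_fraction: float = 0.08
    open_mean_length: int = 1_000


@dataclass(frozen=True)
class PeakConfig:
    n_a: int = 500
    n_b: int = 1_500
    overlap_fraction: float = 0.65
    length_mean: float = 200.0
    length_sd: float = 40.0
    min_length: int = 50


@dataclass(frozen=True)
class DEConfig:
    n_down: int = 30
    n_up: int = 10
    effect_log2: float = 3.0
    noise_sd: float = 0.3


@dataclass(frozen=True)
class LDConfig:
    n_blocks: int = 4
    block_size: int = 8
    copy_prob: float = 0.975  # per-chromosome allele-copy probability; r2 ~ copy_prob**4
    n_unlinked: int = 20
    n_samples: int = 200
    maf: float = 0.5


@dataclass(frozen=True)
class AIConfig:
    depth: int = 20
    imbalance_ratio: float = 3.0
    n_donors: int = 2
    bad_read_fraction: float = 0.15


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    genome: GenomeConfig = GenomeConfig()
    n_genes: int = 300
    peaks: PeakConfig = PeakConfig()
    de: DEConfig = DEConfig()
    ld: LDConfig = LDConfig()
    ai: AIConfig = AIConfig()


# ---------------------------------------------------------------------------
# Genome, open chromatin, TSS
# ---------------------------------------------------------------------------

def gen_genome(cfg: SimulationConfig) -> tuple[Genome, IntervalSet, TSSMap]:
    """Toy genome of GC strata + open-chromatin subset + uniform TSS map.

    Each contig is divided into ``len(gc_strata)`` equal segments; segment
    *k* is i.i.d. sequence with P(G or C) equal to the k-th stratum value.
    Open chromatin covers ~``open_fraction`` of each contig as disjoint
    intervals of exponential-ish lengths; TSSs are uniform.
    """
    g = cfg.genome
    if not all(0.0 <= f <= 1.0 for f in g.gc_strata):
        raise ValueError("GC strata fractions must lie in [0, 1]")
    if not (0.0 < g.open_fraction < 1.0):
        raise ValueError("open_fraction must lie in (0, 1)")
    rng = stage_rng(cfg.seed, "genome")
    contigs: dict[str, str] = {}
    for c in range(g.n_contigs):
        parts = []
        seg_len = g.contig_length // len(g.gc_strata)
        for k, gc in enumerate(g.gc_strata):
            length = seg_len if k < len(g.gc_strata) - 1 else g.contig_length - seg_len * (len(g.gc_strata) - 1)
            probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            idx = rng.choice(4, size=length, p=probs)
            parts.append("".join(BASES[idx]))
        contigs[f"chr{c + 1}"] = "".join(parts)
    genome = Genome(contigs)

    open_intervals: list[GenomicInterval] = []
    rng_open = stage_rng(cfg.seed, "open_chromatin")
    for name, length in genome.lengths.items():
        target = int(g.open_fraction * length)
        covered = 0
        pos = int(rng_open.integers(0, g.open_mean_length))
        while covered < target and pos < length - g.open_mean_length:
            span = int(max(200, rng_open.exponential(g.open_mean_length)))
            end = min(pos + span, length)
            open_intervals.append(GenomicInterval(name, pos, end))
            covered += end - pos
            pos = end + int(rng_open.exponential(g.open_mean_length * (1 - g.open_fraction) / g.open_fraction))
    if not open_intervals:
        raise ValueError("open-chromatin generation produced no intervals; infeasible config")
    open_chromatin = IntervalSet("open_chromatin", open_intervals)

    rng_tss = stage_rng(cfg.seed, "tss")
    names = list(genome.lengths)
    entries = {}
    digits = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        contig = names[int(rng_tss.integers(0, len(names)))]
        pos = int(rng_tss.integers(0, genome.lengths[contig]))
        strand = "+" if rng_tss.random() < 0.5 else "-"
        entries[f"g{i:0{digits}d}"] = (contig, pos, strand)
    return genome, open_chromatin, TSSMap(entries)


def _place_in_open(
    rng: np.random.Generator,
    open_chromatin: IntervalSet,
    length: int,
    weights: np.ndarray,
    max_tries: int = 1_000,
) -> GenomicInterval | None:
    ivs = open_chromatin.intervals
    for _ in range(max_tries):
        j = int(rng.choice(len(ivs), p=weights))
        oc = ivs[j]
        if oc.length < length:
            continue
        start = int(rng.integers(oc.start, oc.end - length + 1))
        return GenomicInterval(oc.contig, start, start + length)
    return None


def _peak_lengths(rng: np.random.Generator, n: int, pk: PeakConfig) -> np.ndarray:
    ls = rng.normal(pk.length_mean, pk.length_sd, size=n)
    return np.maximum(pk.min_length, np.round(ls)).astype(np.int64)


def gen_peaksets(
    cfg: SimulationConfig, open_chromatin: IntervalSet
) -> tuple[IntervalSet, IntervalSet, dict]:
    """Two peak sets inside open chromatin with a planted A-side overlap.

    A configured fraction of set-A intervals is placed to overlap a set-B
    interval by >= 1 bp (within the same open-chromatin interval); the rest
    are placed independently.  Truth records which A indices were planted.
    """
    pk = cfg.peaks
    rng = stage_rng(cfg.seed, "peaks")
    lens = (open_chromatin.lengths()).astype(float)
    weights = lens / lens.sum()
    oc_by_contig = open_chromatin.by_contig()

    b_intervals: list[GenomicInterval] = []
    for length in _peak_lengths(rng, pk.n_b, pk):
        iv = _place_in_open(rng, open_chromatin, int(length), weights)
        if iv is None:
            raise RuntimeError("open-chromatin capacity insufficient for set B")
        b_intervals.append(iv)
    set_b = IntervalSet("setB", b_intervals)

    n_planted = int(round(pk.overlap_fraction * pk.n_a))
    a_intervals: list[GenomicInterval] = []
    planted_idx: list[int] = []
    a_lengths = _peak_lengths(rng, pk.n_a, pk)
    for i in range(pk.n_a):
        length = int(a_lengths[i])
        if i < n_planted:
            iv = None
            for _ in range(1_000):
                b = b_intervals[int(rng.integers(0, len(b_intervals)))]
                starts, ends, _ = oc_by_contig[b.contig]
                k = np.searchsorted(starts, b.start, side="right") - 1
                oc_s, oc_e = int(starts[k]), int(ends[k])
                lo = max(oc_s, b.start - length + 1)
                hi = min(b.end - 1, oc_e - length)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                iv = GenomicInterval(b.contig, start, start + length)
                break
            if iv is None:
                raise RuntimeError("could not place a planted overlapping A peak")
            planted_idx.append(i)
        else:
            iv = _place_in_open(rng, open_chromatin, length, weights)
            if iv is None:
                raise RuntimeError("open-chromatin capacity insufficient for set A")
        a_intervals.append(iv)
    set_a = IntervalSet("setA", a_intervals)
    truth = {"planted_overlap_indices": planted_idx, "n_planted": n_planted}
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

def gen_de_table(
    cfg: SimulationConfig,
    gene_ids: list[str],
    down_targets: set[str],
    up_targets: set[str] | None = None,
) -> tuple[DETable, dict]:
    """DE table with planted shifts: non-targets are null (log2FC ~ N(0, sd),
    adjusted p ~ U(0.1, 1)); planted genes get the configured shift and a
    small adjusted p."""
    if not down_targets <= set(gene_ids):
        raise ValueError("down targets must be a subset of gene ids")
    up_targets = up_targets or set()
    de = cfg.de
    rng = stage_rng(cfg.seed, "de_table")
    l2fc = rng.normal(0.0, de.noise_sd, size=len(gene_ids))
    padj = rng.uniform(0.1, 1.0, size=len(gene_ids))
    for i, gene in enumerate(gene_ids):
        if gene in down_targets:
            l2fc[i] = -de.effect_log2 + rng.normal(0.0, de.noise_sd)
            padj[i] = 10 ** rng.uniform(-10, -6)
        elif gene in up_targets:
            l2fc[i] = de.effect_log2 + rng.normal(0.0, de.noise_sd)
            padj[i] = 10 ** rng.uniform(-10, -6)
    table = DETable.from_log2fc(gene_ids, l2fc, padj)
    truth = {"down": sorted(down_targets), "up": sorted(up_targets)}
    return table, truth


def pick_planted_targets(cfg: SimulationConfig, gene_ids: list[str]) -> tuple[set[str], set[str]]:
    """Deterministically choose the planted down/up gene sets."""
    rng = stage_rng(cfg.seed, "de_targets")
    n = cfg.de.n_down + cfg.de.n_up
    chosen = rng.choice(len(gene_ids), size=min(n, len(gene_ids)), replace=False)
    down = {gene_ids[i] for i in chosen[: cfg.de.n_down]}
    up = {gene_ids[i] for i in chosen[cfg.de.n_down:]}
    return down, up


# ---------------------------------------------------------------------------
# Genotypes with LD blocks
# ---------------------------------------------------------------------------

def gen_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, dict]:
    """LD-block genotypes: within a block each SNP copies a latent diploid
    haplotype pair with probability ``copy_prob`` per chromosome (else an
    independent allele), giving within-block allele correlation
    ``copy_prob**2`` and dosage r-squared ~ ``copy_prob**4``.  Unlinked SNPs
    and distinct blocks are independent."""
    ld = cfg.ld
    rng = stage_rng(cfg.seed, "genotypes")
    snps: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    block_members: dict[str, list[str]] = {}
    block_spacing = 200_000
    for b in range(ld.n_blocks):
        latent = rng.random((ld.n_samples, 2)) < ld.maf  # latent haplotype pair
        members = []
        base_pos = 10_000 + b * block_spacing
        for s in range(ld.block_size):
            copy = rng.random((ld.n_samples, 2)) < ld.copy_prob
            indep = rng.random((ld.n_samples, 2)) < ld.maf
            alleles = np.where(copy, latent, indep)
            snp_id = f"blk{b}_snp{s}"
            snps.append(SNPRecord(snp_id, "chr1", base_pos + s * 500, "A", "G"))
            columns.append(alleles.sum(axis=1).astype(float))
            members.append(snp_id)
        block_members[f"blk{b}"] = members
    unlinked_base = 10_000 + ld.n_blocks * block_spacing
    for u in range(ld.n_unlinked):
        alleles = rng.random((ld.n_samples, 2)) < ld.maf
        snp_id = f"unl_snp{u}"
        snps.append(SNPRecord(snp_id, "chr1", unlinked_base + u * 500, "A", "G"))
        columns.append(alleles.sum(axis=1).astype(float))
    dosages = np.column_stack(columns)
    truth = {"blocks": block_members}
    return GenotypeMatrix(dosages, snps), truth


# ---------------------------------------------------------------------------
# Allelic reads
# ---------------------------------------------------------------------------

def gen_allelic_reads(
    cfg: SimulationConfig, snp: SNPRecord
) -> tuple[dict[str, list[ReadRecord]], list[AlleleCounts]]:
    """Per-donor read pileups at a het SNP with a planted imbalance.

    Each donor gets ``depth`` reads whose base is the reference allele with
    probability ``r / (1 + r)`` (``r`` = imbalance_ratio).  A configured
    fraction of reads receives a disqualifying flag (low MAPQ, duplicate, or
    unpaired) to exercise the read filter; the returned truth counts are the
    post-filter allele counts.
    """
    ai = cfg.ai
    if ai.imbalance_ratio <= 0:
        raise ValueError("imbalance ratio must be > 0")
    rng = stage_rng(cfg.seed, "allelic_reads")
    p_ref = ai.imbalance_ratio / (1.0 + ai.imbalance_ratio)
    reads_by_donor: dict[str, list[ReadRecord]] = {}
    truth: list[AlleleCounts] = []
    for d in range(ai.n_donors):
        donor = f"donor{d + 1}"
        reads: list[ReadRecord] = []
        n_ref = n_alt = 0
        for _ in range(ai.depth):
            base = snp.ref if rng.random() < p_ref else snp.alt
            bad = rng.random() < ai.bad_read_fraction
            if bad:
                which = int(rng.integers(0, 3))
                mapq = int(rng.integers(0, 10)) if which == 0 else 30
                dup = which == 1
                pair = which != 2
            else:
                mapq, dup, pair = 30, False, True
            reads.append(
                ReadRecord(snp.contig, snp.position, mapq, dup, pair, base)
            )
            if not bad:
                if base == snp.ref:
                    n_ref += 1
                else:
                    n_alt += 1
        reads_by_donor[donor] = reads
        truth.append(AlleleCounts(donor=donor, n_ref=n_ref, n_alt=n_alt))
    return reads_by_donor, truth


# ---------------------------------------------------------------------------
# End-to-end toy study
# ---------------------------------------------------------------------------

# Synthetic homeodomain-style consensus used for the planted risk SNP; the
# SNP sits at the C of the consensus, so the alternate T allele breaks it.
MOTIF_CONSENSUS = "TAATCA"
_MOTIF_STRONG = 0.94
_SNP_OFFSET_IN_MOTIF = MOTIF_CONSENSUS.index("C")


def synthetic_motif_pwm() -> PWM:
    """A synthetic strong-consensus PWM (homeodomain-flavoured TAAT core).

    Stand-in for a curated TF motif; each consensus base has probability
    0.94, the others 0.02.
    """
    probs = np.full((len(MOTIF_CONSENSUS), 4), (1 - _MOTIF_STRONG) / 3)
    for i, base in enumerate(MOTIF_CONSENSUS):
        probs[i, "ACGT".index(base)] = _MOTIF_STRONG
    return PWM(probs)


def synthetic_motif_counts(scale: int = 100) -> np.ndarray:
    """Integer count matrix for the synthetic motif (for JASPAR-text export)."""
    return np.round(synthetic_motif_pwm().matrix * scale).astype(int)


@dataclass
class StudyBundle:
    """One complete paper-shaped toy study."""

    genome: Genome
    open_chromatin: IntervalSet
    tss: TSSMap
    set_a: IntervalSet
    set_b: IntervalSet
    peaks_truth: dict
    de_table: DETable
    de_truth: dict
    genotypes: GenotypeMatrix
    genotype_truth: dict
    risk_snp: SNPRecord
    pwm: PWM
    reads_by_donor: dict[str, list[ReadRecord]]
    allele_counts: list[AlleleCounts]
    truth: dict = field(default_factory=dict)


def gen_study(cfg: SimulationConfig) -> StudyBundle:
    """Generate a full toy study on which every pipeline stage has a known
    qualitative outcome.

    Planted structure: set A overlaps set B at the configured fraction; the
    down-regulated DE genes are enriched among genes nearest to A∩B peaks;
    one risk SNP sits inside overlapping A and B peaks within a consensus
    motif match (C allele fits, T breaks); and the het donors' pileups show
    the configured allelic imbalance (defaults reproduce 15:5-like counts).
    """
    from .genome_model import nearest_tss, overlap_hits  # local to avoid cycle noise

    genome, open_chromatin, tss = gen_genome(cfg)
    set_a, set_b, peaks_truth = gen_peaksets(cfg, open_chromatin)

    # planted risk SNP: embed the consensus motif inside an A∩B overlap region
    rng = stage_rng(cfg.seed, "risk_snp")
    a_hits = overlap_hits(set_a, set_b)
    if not a_hits:
        raise RuntimeError("no overlapping peaks to host the risk SNP")
    b_by_contig = set_b.by_contig()
    host = None
    motif_start = None
    order = rng.permutation(len(a_hits))
    for k in order:
        cand = a_hits[int(k)]
        starts, ends, _ = b_by_contig[cand.contig]
        best = (0, None)
        for bs, be in zip(starts, ends):
            lo, hi = max(cand.start, int(bs)), min(cand.end, int(be))
            if hi - lo > best[0]:
                best = (hi - lo, (lo, hi))
        if best[1] is not None and best[0] >= len(MOTIF_CONSENSUS) + 2:
            lo, hi = best[1]
            host = cand
            motif_start = (lo + hi) // 2 - len(MOTIF_CONSENSUS) // 2
            break
    if host is None:
        raise RuntimeError("no A∩B overlap region wide enough to host the motif")
    seq = genome[host.contig]
    new_seq = (
        seq[:motif_start] + MOTIF_CONSENSUS + seq[motif_start + len(MOTIF_CONSENSUS):]
    )
    genome = Genome({**genome.contigs, host.contig: new_seq})
    snp_pos = motif_start + _SNP_OFFSET_IN_MOTIF
    risk_snp = SNPRecord("rs_toy1", host.contig, snp_pos, "C", "T")

    # planted DE targets: genes nearest the co-bound peaks
    annotated = nearest_tss(IntervalSet("a_and_b", a_hits), tss)
    cobound_genes = [g for g in annotated["gene"].dropna().unique()]
    rng_t = stage_rng(cfg.seed, "study_targets")
    rng_t.shuffle(cobound_genes)
    down = set(cobound_genes[: cfg.de.n_down])
    gene_ids = tss.genes
    remaining = [g for g in gene_ids if g not in down]
    up = set(remaining[: cfg.de.n_up])
    de_table, de_truth = gen_de_table(cfg, gene_ids, down, up)

    genotypes, genotype_truth = gen_genotypes(cfg)
    reads_by_donor, allele_counts = gen_allelic_reads(cfg, risk_snp)

    return StudyBundle(
        genome=genome,
        open_chromatin=open_chromatin,
        tss=tss,
        set_a=set_a,
        set_b=set_b,
        peaks_truth=peaks_truth,
        de_table=de_table,
        de_truth=de_truth,
        genotypes=genotypes,
        genotype_truth=genotype_truth,
        risk_snp=risk_snp,
        pwm=synthetic_motif_pwm(),
        reads_by_donor=reads_by_donor,
        allele_counts=allele_counts,
        truth={
            "risk_snp": risk_snp.id,
            "motif_start": motif_start,
            "down_targets": sorted(down),
        },
    )


def write_study(bundle: StudyBundle, outdir: str | Path) -> None:
    """Write a study bundle as plain-text files (FASTA, BED, TSV, VCF-lite,
    JASPAR text, truth.json)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.genome.to_fasta(out / "genome.fa")
    write_intervals(bundle.open_chromatin, out / "open_chromatin.bed", "bed")
    write_intervals(bundle.set_a, out / "peaks_A.bed", "bed")
    write_intervals(bundle.set_b, out / "peaks_B.bed", "bed")
    bundle.tss.to_tsv(out / "tss.tsv")
    bundle.de_table.to_tsv(out / "de_table.tsv")
    bundle.genotypes.to_tsv(out / "genotypes.tsv")
    write_snps_vcf([bundle.risk_snp], out / "risk_snp.vcf")
    write_pwm(synthetic_motif_counts(), out / "motif_synthetic.jaspar", name="synthetic_motif")
    write_reads_tsv(bundle.reads_by_donor, out / "allelic_reads.tsv")
    truth = {
        "peaks": bundle.peaks_truth,
        "de": bundle.de_truth,
        "genotypes": bundle.genotype_truth,
        "study": bundle.truth,
        "allele_counts": [asdict(c) for c in bundle.allele_counts],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
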