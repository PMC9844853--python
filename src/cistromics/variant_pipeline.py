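"""GWAS variant scan: LD expansion of tag SNPs, cistrome intersection, and
allele-aware PWM scoring.

A GWAS/eQTL tag SNP stands in for every variant in high linkage
disequilibrium with it, so candidate-causal scans first expand each tag
into its LD block (dosage r-squared above a threshold within a genomic
window), then ask which candidates fall inside TF-bound regions, and
finally score how each variant's alleles change the best position-weight-
matrix match covering the site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import PWM, Genome, IntervalSet, SNPRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MonomorphicSNPError(ValueError):
    """LD is undefined for a SNP with no dosage variation."""


class InsufficientDataError(ValueError):
    """Too few jointly non-missing genotypes to estimate LD."""


class GenotypeMatrix:
    """Samples x SNPs dosage matrix (0/1/2 alt-allele copies, NaN missing)."""

    def __init__(
        self,
        dosages: np.ndarray,
        snps: Sequence[SNPRecord],
        samples: Sequence[str] | None = None,
    ):
        d = np.asarray(dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (samples x SNPs)")
        if d.shape[1] != len(snps):
            raise ValueError("column count must equal SNP metadata length")
        valid = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        self.dosages = d
        self.snps = list(snps)
        self.samples = (
            [f"s{i}" for i in range(d.shape[0])] if samples is None else list(samples)
        )
        self._id_index = {s.id: i for i, s in enumerate(self.snps)}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, snp_id: str) -> int:
        return self._id_index[snp_id]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.dosages, index=self.samples, columns=[s.id for s in self.snps])
        df.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path, snps: Sequence[SNPRecord]) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        order = [s.id for s in snps]
        return cls(df.loc[:, order].to_numpy(dtype=float), snps, list(df.index))


def ld_r2(genotypes: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosage vectors over samples non-missing
    at both SNPs (genotypic, unphased r-squared)."""
    x = genotypes.dosages[:, i]
    y = genotypes.dosages[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise InsufficientDataError(
            f"fewer than 2 jointly non-missing samples for SNP columns {i}, {j}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MonomorphicSNPError(
            f"monomorphic dosage column among SNPs {i}, {j}; r2 undefined"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def expand_tag_snps(
    tags: Sequence[SNPRecord],
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.7,
    window: int = 1_000_000,
) -> set[SNPRecord]:
    """Union of tag SNPs and their LD mates (r2 strictly above the threshold,
    within ``window`` bp on the same contig)."""
    missing = [t.id for t in tags if t.id not in genotypes._id_index]
    if missing:
        raise KeyError(f"tag SNPs absent from genotype matrix: {missing}")
    out: set[SNPRecord] = set()
    for tag in tags:
        ti = genotypes.index_of(tag.id)
        out.add(genotypes.snps[ti])
        for j, snp in enumerate(genotypes.snps):
            if j == ti or snp.contig != tag.contig:
                continue
            if abs(snp.position - tag.position) > window:
                continue
            try:
                r2 = ld_r2(genotypes, ti, j)
            except (MonomorphicSNPError, InsufficientDataError):
                continue
            if r2 > r2_threshold:
                out.add(snp)
    return out


def intersect_snps_peaks(
    snps: Sequence[SNPRecord], cistromes: Sequence[IntervalSet]
) -> tuple[pd.DataFrame, list[SNPRecord]]:
    """Per-SNP membership in each cistrome plus the SNPs inside all of them.

    A SNP is inside a half-open interval when ``start <= pos < end``.
    """
    names = [c.name for c in cistromes]
    by_contig = [c.by_contig() for c in cistromes]
    rows = []
    hits = []
    for snp in snps:
        membership = []
        for groups in by_contig:
            inside = False
            if snp.contig in groups:
                starts, ends, _ = groups[snp.contig]
                k = np.searchsorted(starts, snp.position, side="right")
                inside = bool((ends[:k] > snp.position).any())
            membership.append(inside)
        rows.append([snp.id, snp.contig, snp.position, *membership])
        if membership and all(membership):
            hits.append(snp)
    table = pd.DataFrame(rows, columns=["snp", "contig", "position", *names])
    return table, hits


@dataclass
class AlleleEffect:
    """Allele effect of a SNP on the best PWM match covering it.

    ``delta = best_window_alt_score - best_window_ref_score`` in bits;
    negative delta means the alternate allele weakens the match.
    """

    snp: SNPRecord
    best_window_ref_score: float
    best_window_alt_score: float
    delta: float
    best_window_offset: int
    best_window_strand: str

    def __post_init__(self) -> None:
        if not np.isclose(
            self.delta, self.best_window_alt_score - self.best_window_ref_score
        ):
            raise ValueError("delta must equal alt - ref exactly")


def _best_window(pwm: PWM, context: str, snp_offset: int) -> tuple[float, int, str]:
    """Best log-odds score among windows (both strands) covering the SNP."""
    w = pwm.width
    best = (-np.inf, 0, "+")
    for off in range(max(0, snp_offset - w + 1), min(len(context) - w, snp_offset) + 1):
        window = context[off: off + w]
        for strand in ("+", "-"):
            s = pwm.score(window, strand)
            if s > best[0]:
                best = (s, off, strand)
    return best


def scan_allele_effect(
    pwm: PWM,
    genome: Genome,
    snp: SNPRecord,
    flank: int,
    mode: str = "ref_best",
) -> AlleleEffect:
    """Score the allele effect of a SNP on PWM matches covering it.

    The SNP base is substituted with each allele in turn, and every window
    of PWM width covering the SNP is scored on both strands.  With the
    default ``mode="ref_best"``, ``delta`` is evaluated on the window/strand
    pair that maximizes the reference-allele score, measuring disruption of
    the existing site; ``mode="max"`` compares the two per-allele maxima.
    """
    if flank < pwm.width:
        raise ValueError("flank must be at least the PWM width")
    contig_len = genome.lengths[snp.contig]
    lo = max(0, snp.position - flank)
    hi = min(contig_len, snp.position + flank + 1)
    context = genome.fetch(snp.contig, lo, hi)
    off = snp.position - lo
    if context[off] not in (snp.ref, snp.alt, "N"):
        raise ValueError(
            f"genome base {context[off]!r} at {snp.contig}:{snp.position} matches "
            f"neither allele of {snp.id}"
        )
    ref_ctx = context[:off] + snp.ref + context[off + 1:]
    alt_ctx = context[:off] + snp.alt + context[off + 1:]
    ref_score, ref_off, ref_strand = _best_window(pwm, ref_ctx, off)
    if mode == "ref_best":
        window = alt_ctx[ref_off: ref_off + pwm.width]
        alt_score = pwm.score(window, ref_strand)
        best_off, best_strand = ref_off, ref_strand
    elif mode == "max":
        alt_score, _, _ = _best_window(pwm, alt_ctx, off)
        best_off, best_strand = ref_off, ref_strand
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AlleleEffect(
        snp=snp,
        best_window_ref_score=float(ref_score),
        best_window_alt_score=float(alt_score),
        delta=float(alt_score - ref_score),
        best_window_offset=lo + best_off,
        best_window_strand=best_strand,
    )
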