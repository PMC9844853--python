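"""Allelic-imbalance (AI) testing at a heterozygous regulatory SNP.

In a heterozygous individual, reads from an accessibility or binding assay
should cover the two alleles of a SNP at a 1:1 ratio unless the alleles
differ in regulatory activity.  The pipeline here: filter aligned reads
(mapping quality, duplicates, proper pairing), count reads per allele per
donor, run an exact two-sided binomial test against the 1:1 null per donor,
and combine donors with Fisher's method (−2 Σ ln p ~ chi-square on 2k df).

Two-sidedness uses the minimal-likelihood convention (sum of outcome
probabilities no larger than the observed one), the standard exact-test
definition and the one implemented by :func:`scipy.stats.binomtest`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import SNPRecord


@dataclass(frozen=True)
class ReadRecord:
    """Minimal view of an aligned read at a query SNP."""

    contig: str
    position: int
    mapq: int
    is_duplicate: bool
    is_proper_pair: bool
    base: str  # base carried at the query SNP; "N" if ambiguous

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("MAPQ must be >= 0")
        if self.base not in "ACGTN":
            raise ValueError(f"invalid base {self.base!r}")


@dataclass(frozen=True)
class AlleleCounts:
    donor: str
    n_ref: int
    n_alt: int
    n_other: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ref, self.n_alt, self.n_other) < 0:
            raise ValueError("allele counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_ref + self.n_alt


@dataclass
class AIResult:
    """Per-donor binomial p-values and their Fisher combination."""

    per_donor_p: dict[str, float]
    statistic: float
    df: int
    pvalue: float


def filter_reads(reads: Iterable[ReadRecord], mapq_min: int = 10) -> list[ReadRecord]:
    """Keep non-duplicate, properly paired reads with MAPQ >= ``mapq_min``
    (order preserved)."""
    return [
        r
        for r in reads
        if not r.is_duplicate and r.is_proper_pair and r.mapq >= mapq_min
    ]


def count_alleles(
    reads: Iterable[ReadRecord], snp: SNPRecord, donor: str
) -> AlleleCounts:
    """Count reads supporting each allele at the SNP.

    Reads carrying a base that is neither allele (including N, e.g. residual
    mismatches after N-masked alignment) are tallied as ``n_other`` and
    excluded from the test.
    """
    n_ref = n_alt = n_other = 0
    for r in reads:
        if r.contig != snp.contig or r.position != snp.position:
            continue
        if r.base == snp.ref:
            n_ref += 1
        elif r.base == snp.alt:
            n_alt += 1
        else:
            n_other += 1
    return AlleleCounts(donor=donor, n_ref=n_ref, n_alt=n_alt, n_other=n_other)


def binomial_ai_test(counts: AlleleCounts, p0: float = 0.5) -> float:
    """Exact two-sided binomial p for departure of the ref:alt ratio from
    ``p0`` (minimal-likelihood two-sided definition)."""
    n = counts.total
    if n == 0:
        raise ValueError("no informative reads")
    return float(stats.binomtest(counts.n_ref, n, p0, alternative="two-sided").pvalue)


def fisher_combine(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: ``(-2 Σ ln p, df = 2k, chi-square upper-tail p)``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    statistic, combined = stats.combine_pvalues(p, method="fisher")
    return float(statistic), 2 * p.size, float(combined)


def allelic_imbalance_test(
    counts: Sequence[AlleleCounts], p0: float = 0.5
) -> AIResult:
    """Per-donor exact binomial tests combined across donors by Fisher."""
    per_donor = {c.donor: binomial_ai_test(c, p0=p0) for c in counts}
    statistic, df, combined = fisher_combine(list(per_donor.values()))
    return AIResult(per_donor_p=per_donor, statistic=statistic, df=df, pvalue=combined)


def sign_trend_test(n_consistent: int, n_total: int) -> float:
    """One-sided sign test: P(X >= n_consistent), X ~ Binomial(n_total, 1/2).

    For a fully consistent trend (k of k replicates in the same direction)
    this reduces to 0.5**k.
    """
    if not (0 <= n_consistent <= n_total):
        raise ValueError("need 0 <= n_consistent <= n_total")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return float(stats.binom.sf(n_consistent - 1, n_total, 0.5))


# ---------------------------------------------------------------------------
# Tabular I/O (SAM-subset TSV and bare counts)
# ---------------------------------------------------------------------------

def read_reads_tsv(path: str | Path) -> dict[str, list[ReadRecord]]:
    """Read a SAM-subset TSV: columns donor, contig, pos (1-based), mapq,
    is_duplicate, is_proper_pair, base."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[ReadRecord]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.donor), []).append(
            ReadRecord(
                contig=str(r.contig),
                position=int(r.pos) - 1,
                mapq=int(r.mapq),
                is_duplicate=bool(r.is_duplicate),
                is_proper_pair=bool(r.is_proper_pair),
                base=str(r.base),
            )
        )
    return out


def write_reads_tsv(reads_by_donor: dict[str, list[ReadRecord]], path: str | Path) -> None:
    rows = [
        {
            "donor": donor,
            "contig": r.contig,
            "pos": r.position + 1,
            "mapq": r.mapq,
            "is_duplicate": r.is_duplicate,
            "is_proper_pair": r.is_proper_pair,
            "base": r.base,
        }
        for donor, reads in reads_by_donor.items()
        for r in reads
    ]
    pd.DataFrame(
        rows,
        columns=["donor", "contig", "pos", "mapq", "is_duplicate", "is_proper_pair", "base"],
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> list[AlleleCounts]:
    """Read bare allele counts: columns donor, n_ref, n_alt [, n_other]."""
    df = pd.read_csv(path, sep="\t")
    return [
        AlleleCounts(
            donor=str(r.donor),
            n_ref=int(r.n_ref),
            n_alt=int(r.n_alt),
            n_other=int(getattr(r, "n_other", 0)),
        )
        for r in df.itertuples(index=False)
    ]


def write_counts_tsv(counts: Sequence[AlleleCounts], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"donor": c.donor, "n_ref": c.n_ref, "n_alt": c.n_alt, "n_other": c.n_other}
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)
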