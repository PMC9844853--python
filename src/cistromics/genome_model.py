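"""Core data model and I/O for regulatory-genomics analyses.

This module defines the currency every downstream stage trades in:

* :class:`GenomicInterval` / :class:`IntervalSet` — half-open, 0-based
  genomic regions (ChIP-seq peaks, open chromatin, masks);
* :class:`Genome` — in-memory contig sequences over ``{A,C,G,T,N}`` with
  cached prefix sums for O(1) GC queries;
* :class:`TSSMap` — gene → transcription start site lookup used for
  nearest-gene assignment and distance covariates;
* :class:`DETable` — per-gene fold change and adjusted p from a
  differential-expression analysis;
* :class:`SNPRecord` — a biallelic single-nucleotide variant;
* :class:`PWM` — position weight matrix with a background model,
  supporting log-odds scoring.

Coordinate convention: all in-memory coordinates are 0-based half-open
(``[start, end)``), the BED convention.  Tabular (TSV) interval input is
taken as 1-based inclusive and converted on read; TSV output converts back,
so both formats round-trip exactly.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MalformedRecordError(ValueError):
    """A record in an input file could not be parsed."""


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on ``contig``.

    ``summit`` is an offset from ``start`` (e.g. a peak-caller summit);
    when present it is the preferred anchor for distance computations.
    """

    contig: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (0 <= self.summit < self.length):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit position if known, else the midpoint."""
        if self.summit is not None:
            return self.start + self.summit
        return self.midpoint


@dataclass
class IntervalSet:
    """A named, ordered collection of :class:`GenomicInterval`."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            self.name,
            sorted(self.intervals, key=lambda iv: (iv.contig, iv.start, iv.end)),
        )

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=np.int64)

    def contigs(self) -> set[str]:
        return {iv.contig for iv in self.intervals}

    def by_contig(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[int]]]:
        """Group into per-contig ``(starts, ends, original indices)`` arrays,
        sorted by start."""
        groups: dict[str, list[tuple[int, int, int]]] = {}
        for idx, iv in enumerate(self.intervals):
            groups.setdefault(iv.contig, []).append((iv.start, iv.end, idx))
        out = {}
        for contig, rows in groups.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            out[contig] = (starts, ends, [r[2] for r in rows])
        return out


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

class Genome:
    """Contig sequences over ``{A,C,G,T,N}`` with cached GC prefix sums."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must have at least one contig")
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            s = str(seq).upper()
            if not s:
                raise ValueError(f"contig {name!r} is empty")
            if set(s) - set("ACGTN"):
                bad = sorted(set(s) - set("ACGTN"))
                raise ValueError(f"contig {name!r} contains non-ACGTN bases {bad}")
            clean[name] = s
        self._contigs = clean
        self._prefix_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- mapping-ish surface
    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def __getitem__(self, contig: str) -> str:
        return self._contigs[contig]

    @property
    def contigs(self) -> dict[str, str]:
        return dict(self._contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self._contigs[contig]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"region {contig}:{start}-{end} out of bounds (contig length {len(seq)})"
            )
        return seq[start:end]

    # -- prefix sums for O(1) composition queries
    def _prefixes(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (cumulative GC count, cumulative non-N count), length+1 arrays."""
        if contig not in self._prefix_cache:
            codes = np.frombuffer(self._contigs[contig].encode("ascii"), dtype=np.uint8)
            is_gc = (codes == ord("G")) | (codes == ord("C"))
            is_valid = codes != ord("N")
            gc = np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])
            valid = np.concatenate([[0], np.cumsum(is_valid, dtype=np.int64)])
            self._prefix_cache[contig] = (gc, valid)
        return self._prefix_cache[contig]

    def gc_fraction(self, contig: str, start: int, end: int) -> float:
        """GC fraction over ``[start, end)``; N bases excluded from numerator
        and denominator; NaN when every base is N."""
        seq_len = len(self._contigs[contig])
        if not (0 <= start < end <= seq_len):
            raise ValueError(f"region {contig}:{start}-{end} out of bounds")
        gc, valid = self._prefixes(contig)
        n_valid = valid[end] - valid[start]
        if n_valid == 0:
            return float("nan")
        return float(gc[end] - gc[start]) / float(n_valid)

    def base_counts(self, contig: str) -> dict[str, int]:
        seq = self._contigs[contig]
        return {b: seq.count(b) for b in "ACGTN"}

    # -- FASTA I/O (wrapped at 60 columns)
    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self._contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def gc_content(genome: Genome, interval: GenomicInterval) -> float:
    """GC fraction of ``interval``; NaN flags an all-N (undefined) interval."""
    return genome.gc_fraction(interval.contig, interval.start, interval.end)


def mask_base(genome: Genome, snp: "SNPRecord") -> Genome:
    """Return a copy of ``genome`` with the SNP base replaced by ``N``.

    Masking the variant base before alignment removes reference-allele
    mapping bias in allelic-imbalance analyses.  Idempotent: an already
    masked base stays ``N``.
    """
    seq = genome[snp.contig]
    if not (0 <= snp.position < len(seq)):
        raise ValueError(f"SNP position {snp.position} out of bounds for {snp.contig}")
    base = seq[snp.position]
    if base not in (snp.ref, snp.alt, "N"):
        raise ValueError(
            f"genome base {base!r} at {snp.contig}:{snp.position} matches neither "
            f"allele of {snp.id} ({snp.ref}/{snp.alt})"
        )
    contigs = genome.contigs
    contigs[snp.contig] = seq[: snp.position] + "N" + seq[snp.position + 1:]
    return Genome(contigs)


# ---------------------------------------------------------------------------
# TSS map
# ---------------------------------------------------------------------------

class TSSMap:
    """Gene → (contig, TSS position, strand) lookup.

    Positions are 0-based in memory; the TSV representation is 1-based
    (column ``tss``), converted on read/write.
    """

    def __init__(self, entries: Mapping[str, tuple[str, int, str]]):
        self._entries: dict[str, tuple[str, int, str]] = {}
        for gene, (contig, pos, strand) in entries.items():
            if strand not in STRANDS:
                raise ValueError(f"invalid strand {strand!r} for gene {gene}")
            if pos < 0:
                raise ValueError(f"negative TSS position for gene {gene}")
            self._entries[str(gene)] = (str(contig), int(pos), strand)
        self._by_contig_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def __getitem__(self, gene: str) -> tuple[str, int, str]:
        return self._entries[gene]

    def items(self):
        return self._entries.items()

    @property
    def genes(self) -> list[str]:
        return list(self._entries)

    def contig_set(self) -> set[str]:
        return {c for c, _, _ in self._entries.values()}

    def positions_by_contig(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per contig: sorted unique TSS positions and, for each position,
        the lexicographically smallest gene there (the documented tie-break)."""
        if self._by_contig_cache is None:
            per: dict[str, dict[int, str]] = {}
            for gene, (contig, pos, _strand) in self._entries.items():
                best = per.setdefault(contig, {})
                if pos not in best or gene < best[pos]:
                    best[pos] = gene
            cache = {}
            for contig, posmap in per.items():
                positions = np.array(sorted(posmap), dtype=np.int64)
                gene_arr = np.array([posmap[p] for p in positions], dtype=object)
                cache[contig] = (positions, gene_arr)
            self._by_contig_cache = cache
        return self._by_contig_cache

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TSSMap":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"gene", "contig", "tss", "strand"}
        if not required.issubset(df.columns):
            raise MalformedRecordError(
                f"TSS table must declare columns {sorted(required)}"
            )
        entries = {
            str(r.gene): (str(r.contig), int(r.tss) - 1, str(r.strand))
            for r in df.itertuples()
        }
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": g, "contig": c, "tss": p + 1, "strand": s}
            for g, (c, p, s) in self._entries.items()
        ]
        pd.DataFrame(rows, columns=["gene", "contig", "tss", "strand"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

class DETable:
    """Per-gene differential expression: log2 fold change, signed linear fold
    change and BH-adjusted p.

    Sign convention: negative fold change means *down* in the perturbation
    (knockdown) relative to control.  The linear fold change is the display
    scale many papers print (e.g. ``FC = -18.4``); it relates to log2 by
    ``FC = 2**l2fc`` for up-regulated genes and ``-2**(-l2fc)`` for
    down-regulated ones.
    """

    COLUMNS = ("gene", "log2_fc", "fold_change", "padj")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        df["gene"] = df["gene"].astype(str)
        if df["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in DE table")
        bad_p = df["padj"].dropna()
        if ((bad_p < 0) | (bad_p > 1)).any():
            raise ValueError("adjusted p-values must lie in [0, 1]")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> set[str]:
        return set(self.frame["gene"])

    @staticmethod
    def linear_fc(log2_fc: np.ndarray) -> np.ndarray:
        """Signed linear fold change: sign-preserving, magnitude 2**|l2fc|."""
        l2 = np.asarray(log2_fc, dtype=float)
        return np.where(l2 >= 0, 2.0 ** l2, -(2.0 ** (-l2)))

    @classmethod
    def from_log2fc(
        cls, genes: Sequence[str], log2_fc: Sequence[float], padj: Sequence[float]
    ) -> "DETable":
        l2 = np.asarray(log2_fc, dtype=float)
        return cls(
            pd.DataFrame(
                {
                    "gene": list(genes),
                    "log2_fc": l2,
                    "fold_change": cls.linear_fc(l2),
                    "padj": np.asarray(padj, dtype=float),
                }
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DETable":
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP; ``position`` is 0-based."""

    id: str
    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"alleles must be single A/C/G/T bases, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical for {self.id}")
        if self.position < 0:
            raise ValueError("negative SNP position")


def read_snps_vcf(path: str | Path) -> list[SNPRecord]:
    """Read a VCF-lite file (CHROM POS ID REF ALT; POS 1-based)."""
    snps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise MalformedRecordError(f"{path}:{lineno}: expected >=5 columns")
            chrom, pos, snp_id, ref, alt = fields[:5]
            try:
                position = int(pos) - 1
            except ValueError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: bad POS {pos!r}") from exc
            snps.append(SNPRecord(snp_id, chrom, position, ref.upper(), alt.upper()))
    return snps


def write_snps_vcf(snps: Iterable[SNPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for s in snps:
            fh.write(f"{s.contig}\t{s.position + 1}\t{s.id}\t{s.ref}\t{s.alt}\n")


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

class PWM:
    """Position weight matrix over A/C/G/T with a background model.

    Probabilities are stored row-normalized.  Log-odds scores are in bits:
    ``sum_i log2(P_i(base) / background(base))``.  An N base contributes 0
    (it is scored at background).
    """

    def __init__(
        self,
        probabilities: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.8,
    ):
        probs = np.asarray(probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if (probs < 0).any():
            raise ValueError("PWM probabilities must be nonnegative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9) or (bg <= 0).any():
            raise ValueError("background must be 4 positive probabilities summing to 1")
        self.matrix = probs
        self.background = bg
        self.pseudocount = float(pseudocount)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.8,
    ) -> "PWM":
        """Normalize a count matrix to probabilities.

        Each cell receives ``pseudocount * 4 * background[b]`` — per-cell
        ``pseudocount`` under the default uniform background, i.e.
        ``(c + pc) / (rowsum + 4*pc)``.
        """
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError("count matrix must be positions x 4")
        if (c < 0).any():
            raise ValueError("negative counts in PWM matrix")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        add = pseudocount * 4.0 * bg
        num = c + add[None, :]
        probs = num / num.sum(axis=1, keepdims=True)
        return cls(probs, background=bg, pseudocount=pseudocount)

    def log_odds(self) -> np.ndarray:
        """(width x 4) log2 odds matrix; zero-probability cells score -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background[None, :])

    def score(self, window: str, strand: str = "+") -> float:
        """Log-odds score of a window of exactly ``width`` bases."""
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != PWM width {self.width}")
        seq = window.upper()
        if strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        lo = self.log_odds()
        total = 0.0
        for i, base in enumerate(seq):
            if base == "N":
                continue
            total += lo[i, BASE_INDEX[base]]
        return float(total)


def read_pwm(
    path: str | Path,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.8,
) -> PWM:
    """Read a JASPAR-style matrix (bracketed ``jaspar`` or raw 4-row ``pfm``)."""
    text = Path(path).read_text()
    fmt = "jaspar" if text.lstrip().startswith(">") else "pfm"
    try:
        motif = motifs.read(io.StringIO(text), fmt)
    except Exception as exc:  # Bio raises assorted errors on malformed input
        raise MalformedRecordError(f"could not parse PWM file {path}: {exc}") from exc
    counts = np.array([motif.counts[b] for b in BASES], dtype=float).T
    if (counts < 0).any():
        raise MalformedRecordError(f"negative matrix entries in {path}")
    return PWM.from_counts(counts, background=background, pseudocount=pseudocount)


def write_pwm(pwm_counts: np.ndarray, path: str | Path, name: str = "motif") -> None:
    """Write a counts/frequency matrix in bracketed JASPAR text."""
    c = np.asarray(pwm_counts, dtype=float)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate(BASES):
            row = " ".join(f"{v:g}" for v in c[:, i])
            fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Interval I/O
# ---------------------------------------------------------------------------

def _parse_optional_float(token: str) -> float | None:
    return None if token == "." else float(token)


def read_intervals(path: str | Path, fmt: str = "bed") -> IntervalSet:
    """Read an interval file.

    ``fmt="bed"``: BED3/BED6 with an optional 7th summit-offset column;
    already 0-based half-open.  ``fmt="tsv"``: header-declared
    ``contig/start/end`` (optionally ``strand/score/summit``) with 1-based
    inclusive coordinates, converted to 0-based half-open on read.
    """
    path = Path(path)
    name = path.stem
    if fmt == "bed":
        intervals: list[GenomicInterval] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise MalformedRecordError(f"{path}:{lineno}: fewer than 3 BED columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise MalformedRecordError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                if start >= end:
                    raise MalformedRecordError(f"{path}:{lineno}: start >= end")
                score = _parse_optional_float(fields[4]) if len(fields) >= 5 else None
                strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
                summit = None
                if len(fields) >= 7 and fields[6] != ".":
                    summit = int(fields[6])
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, score, summit)
                )
        return IntervalSet(name, intervals)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"contig", "start", "end"}
        if not required.issubset(df.columns):
            raise MalformedRecordError(
                f"{path}: TSV must declare columns {sorted(required)}"
            )
        intervals = []
        for row_num, r in enumerate(df.itertuples(index=False), start=2):
            start = int(r.start) - 1  # 1-based inclusive -> 0-based half-open
            end = int(r.end)
            if start >= end:
                raise MalformedRecordError(f"{path}:{row_num}: start >= end")
            strand = getattr(r, "strand", ".")
            strand = strand if isinstance(strand, str) and strand in STRANDS else "."
            score = getattr(r, "score", None)
            score = None if score is None or (isinstance(score, float) and np.isnan(score)) else float(score)
            summit = getattr(r, "summit", None)
            summit = None if summit is None or (isinstance(summit, float) and np.isnan(summit)) else int(summit)
            intervals.append(GenomicInterval(str(r.contig), start, end, strand, score, summit))
        return IntervalSet(name, intervals)
    raise ValueError(f"unknown interval format {fmt!r}")


def write_intervals(interval_set: IntervalSet, path: str | Path, fmt: str = "bed") -> None:
    """Write intervals so that :func:`read_intervals` reproduces them exactly."""
    path = Path(path)
    if fmt == "bed":
        with open(path, "w") as fh:
            for iv in interval_set:
                fields = [
                    iv.contig,
                    str(iv.start),
                    str(iv.end),
                    ".",
                    "." if iv.score is None else repr(float(iv.score)),
                    iv.strand,
                    "." if iv.summit is None else str(iv.summit),
                ]
                fh.write("\t".join(fields) + "\n")
        return
    if fmt == "tsv":
        rows = [
            {
                "contig": iv.contig,
                "start": iv.start + 1,
                "end": iv.end,
                "strand": iv.strand,
                "score": iv.score,
                "summit": iv.summit,
            }
            for iv in interval_set
        ]
        pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "score", "summit"]).to_csv(
            path, sep="\t", index=False
        )
        return
    raise ValueError(f"unknown interval format {fmt!r}")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent-free sorted intervals into a disjoint union."""
    merged_s, merged_e = [], []
    cur_s, cur_e = None, None
    for s, e in zip(starts, ends):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s < cur_e:  # strictly overlapping (book-ended intervals stay separate)
            cur_e = max(cur_e, e)
        else:
            merged_s.append(cur_s)
            merged_e.append(cur_e)
            cur_s, cur_e = s, e
    if cur_s is not None:
        merged_s.append(cur_s)
        merged_e.append(cur_e)
    return np.array(merged_s, dtype=np.int64), np.array(merged_e, dtype=np.int64)


def overlap_hits(
    a: IntervalSet, b: IntervalSet, min_bp: int = 1
) -> list[GenomicInterval]:
    """A-side intervals that overlap some b-interval by at least ``min_bp``
    base pairs, in original order (each counted once)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    hit_idx: list[int] = []
    b_groups = b.by_contig()
    if min_bp == 1:
        merged = {
            contig: _merge_sorted(starts, ends)
            for contig, (starts, ends, _) in b_groups.items()
        }
        for contig, (a_starts, a_ends, a_idx) in a.by_contig().items():
            if contig not in merged:
                continue
            ms, me = merged[contig]
            # first merged interval whose end > a_start overlaps iff its start < a_end
            j = np.searchsorted(me, a_starts, side="right")
            ok = (j < len(ms)) & (ms[np.minimum(j, len(ms) - 1)] < a_ends)
            hit_idx.extend(idx for idx, flag in zip(a_idx, ok) if flag)
    else:
        trees = {
            contig: IntervalTree.from_tuples(zip(starts, ends))
            for contig, (starts, ends, _) in b_groups.items()
        }
        for idx, iv in enumerate(a):
            tree = trees.get(iv.contig)
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp:
                    hit_idx.append(idx)
                    break
    hit_idx.sort()
    return [a[idx] for idx in hit_idx]


def overlap_count(
    a: IntervalSet, b: IntervalSet, min_bp: int = 1
) -> tuple[int, list[GenomicInterval]]:
    """Count a-side intervals overlapping any b-interval by >= ``min_bp`` bp.

    The count is asymmetric (query side = ``a``): each a-interval is counted
    at most once no matter how many b-intervals it touches.
    """
    hits = overlap_hits(a, b, min_bp=min_bp)
    return len(hits), hits


def nearest_tss_distances(tss: TSSMap, contig: str, anchors: np.ndarray) -> np.ndarray:
    """Vectorized unsigned distance from each anchor to the nearest TSS on
    ``contig``; NaN where the contig has no TSS."""
    per = tss.positions_by_contig()
    anchors = np.asarray(anchors, dtype=np.int64)
    if contig not in per:
        return np.full(len(anchors), np.nan)
    positions, _genes = per[contig]
    j = np.searchsorted(positions, anchors)
    left = np.where(j > 0, np.abs(anchors - positions[np.maximum(j - 1, 0)]), np.iinfo(np.int64).max)
    right = np.where(j < len(positions), np.abs(positions[np.minimum(j, len(positions) - 1)] - anchors), np.iinfo(np.int64).max)
    return np.minimum(left, right).astype(float)


def nearest_tss(peaks: IntervalSet, tss: TSSMap) -> pd.DataFrame:
    """Assign each peak to its nearest TSS gene.

    The distance anchor is the peak summit when present, else the midpoint.
    Ties (equidistant TSSs) resolve to the lexicographically smallest gene
    id, deterministically.  Peaks on contigs with no TSS are flagged
    (``gene`` None, ``distance`` NaN), never dropped.

    Returns a DataFrame with columns ``contig start end anchor gene distance``
    in the peaks' original order.
    """
    per = tss.positions_by_contig()
    rows = []
    for iv in peaks:
        anchor = iv.anchor
        if iv.contig not in per:
            rows.append((iv.contig, iv.start, iv.end, anchor, None, float("nan")))
            continue
        positions, genes = per[iv.contig]
        j = int(np.searchsorted(positions, anchor))
        candidates: list[tuple[int, str]] = []
        if j > 0:
            candidates.append((abs(anchor - int(positions[j - 1])), str(genes[j - 1])))
        if j < len(positions):
            candidates.append((abs(int(positions[j]) - anchor), str(genes[j])))
        dist = min(c[0] for c in candidates)
        gene = min(g for d, g in candidates if d == dist)
        rows.append((iv.contig, iv.start, iv.end, anchor, gene, float(dist)))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "anchor", "gene", "distance"]
    )


def resize_to_summit(interval_set: IntervalSet, half_width: int) -> IntervalSet:
    """Standardize peaks to ``anchor +/- half_width`` (clipped at 0).

    Optional pre-processing before overlap analyses when a fixed resolution
    (e.g. ~200 bp fragments) is preferred over raw peak widths.
    """
    out = []
    for iv in interval_set:
        a = iv.anchor
        start = max(0, a - half_width)
        end = a + half_width
        if end <= start:
            end = start + 1
        out.append(replace(iv, start=start, end=end, summit=a - start))
    return IntervalSet(interval_set.name, out)
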