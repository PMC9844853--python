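"""Integration of TF cistromes with differential expression.

Covers threshold filtering of a differential-expression table, rank-based
shift tests of a candidate target-gene set, peak-to-TSS distance summaries,
and the two-factor target-network tabulation (how many down-regulated genes
carry a peak of TF A, of TF B, of both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import DETable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGFilter:
    """Thresholds for calling differential genes.

    ``fc_threshold`` is on the signed *linear* fold-change scale (a gene is
    down when ``FC <= -fc_threshold``); ``fdr_threshold`` applies to the
    BH-adjusted p.  Defaults: |FC| 1.5, FDR 5%.
    """

    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1 (linear scale)")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")


def filter_degs(
    de: DETable, deg_filter: DEGFilter = DEGFilter()
) -> tuple[set[str], set[str]]:
    """Split a DE table into (down-regulated, up-regulated) gene sets.

    Genes with missing fold change or adjusted p (e.g. independent-filtering
    NAs) are excluded from filtering; the count of exclusions is logged.
    """
    if len(de) == 0:
        raise ValueError("DE table is empty")
    df = de.frame
    usable = df["fold_change"].notna() & df["padj"].notna()
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.warning("filter_degs: excluded %d genes with missing FC or p-adj", n_excluded)
    sub = df[usable]
    sig = sub["padj"] < deg_filter.fdr_threshold
    down = set(sub.loc[sig & (sub["fold_change"] <= -deg_filter.fc_threshold), "gene"])
    up = set(sub.loc[sig & (sub["fold_change"] >= deg_filter.fc_threshold), "gene"])
    return down, up


@dataclass
class ShiftTestResult:
    statistic: float
    pvalue: float
    median_target: float
    median_background: float
    n_target: int
    n_background: int
    mode: str


def target_shift_test(
    de: DETable,
    targets: set[str],
    mode: str = "two-sample",
    alternative: str = "two-sided",
) -> ShiftTestResult:
    """Wilcoxon test of whether target genes' log2 fold changes are shifted.

    ``two-sample`` (default): rank-sum of target vs non-target log2FC.
    ``one-sample``: signed-rank of target log2FC against zero.  Exact null
    enumeration is used for small samples (n <= 25, no ties); otherwise the
    normal approximation with continuity correction.  Genes with NA adjusted
    p are retained here (the shift test does not threshold on significance).
    """
    df = de.frame
    in_target = df["gene"].isin(targets)
    t_vals = df.loc[in_target, "log2_fc"].to_numpy(dtype=float)
    b_vals = df.loc[~in_target, "log2_fc"].to_numpy(dtype=float)
    t_vals = t_vals[~np.isnan(t_vals)]
    b_vals = b_vals[~np.isnan(b_vals)]
    if len(t_vals) < 5:
        raise ValueError("need at least 5 target genes present in the DE table")
    if mode == "two-sample":
        pooled = np.concatenate([t_vals, b_vals])
        if np.unique(pooled).size == 1:
            raise ValueError("all fold changes tied; rank test undefined")
        has_ties = np.unique(pooled).size < pooled.size
        small = max(len(t_vals), len(b_vals)) <= 25
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            t_vals, b_vals, alternative=alternative, method=method, use_continuity=True
        )
        stat, p = float(res.statistic), float(res.pvalue)
    elif mode == "one-sample":
        nonzero = t_vals[t_vals != 0]
        if nonzero.size == 0:
            raise ValueError("all target fold changes are zero; signed-rank undefined")
        small = len(nonzero) <= 25
        has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
        method = "exact" if (small and not has_ties) else "approx"
        res = stats.wilcoxon(
            t_vals, alternative=alternative, method=method, correction=True
        )
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ShiftTestResult(
        statistic=stat,
        pvalue=min(p, 1.0),
        median_target=float(np.median(t_vals)),
        median_background=float(np.median(b_vals)) if len(b_vals) else float("nan"),
        n_target=len(t_vals),
        n_background=len(b_vals),
        mode=mode,
    )


@dataclass
class DistanceStats:
    mean: float
    median: float
    histogram: np.ndarray
    bin_edges: np.ndarray
    n: int


def distance_stats(
    annotated: pd.DataFrame, bins: np.ndarray | int | None = None
) -> DistanceStats:
    """Summarize peak-to-nearest-TSS distances from :func:`nearest_tss` output.

    Distances are unsigned; flagged rows (NaN distance) are excluded.
    Histogram bins are half-open ``[lo, hi)``.
    """
    dists = annotated["distance"].to_numpy(dtype=float)
    dists = dists[~np.isnan(dists)]
    if dists.size == 0:
        raise ValueError("no annotated peaks with defined distance")
    if bins is None:
        bins = 20
    counts, edges = np.histogram(dists, bins=bins)
    return DistanceStats(
        mean=float(np.mean(dists)),
        median=float(np.median(dists)),
        histogram=counts,
        bin_edges=edges,
        n=int(dists.size),
    )


@dataclass
class TargetSetReport:
    """Cell counts and gene lists of the down-regulated x cistrome cross-table."""

    n_down: int
    n_up: int
    n_down_with_tfA_peak: int
    n_down_with_tfB_peak: int
    n_down_with_both: int
    down_genes: list[str] = field(default_factory=list)
    up_genes: list[str] = field(default_factory=list)
    down_tfA_genes: list[str] = field(default_factory=list)
    down_tfB_genes: list[str] = field(default_factory=list)
    down_both_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            self.n_down_with_both
            <= min(self.n_down_with_tfA_peak, self.n_down_with_tfB_peak)
            <= self.n_down
        ):
            raise ValueError("inconsistent target-set report cell counts")


def build_network_report(
    down_genes: set[str],
    tfA_target_genes: set[str],
    tfB_target_genes: set[str],
    up_genes: set[str] | None = None,
) -> TargetSetReport:
    """Tabulate how many down-regulated genes are proximal targets of TF A,
    TF B, or both (exact set intersections; gene lists sorted)."""
    down_a = down_genes & tfA_target_genes
    down_b = down_genes & tfB_target_genes
    both = down_a & down_b
    up = up_genes or set()
    return TargetSetReport(
        n_down=len(down_genes),
        n_up=len(up),
        n_down_with_tfA_peak=len(down_a),
        n_down_with_tfB_peak=len(down_b),
        n_down_with_both=len(both),
        down_genes=sorted(down_genes),
        up_genes=sorted(up),
        down_tfA_genes=sorted(down_a),
        down_tfB_genes=sorted(down_b),
        down_both_genes=sorted(both),
    )
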