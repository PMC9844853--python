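"""Integrate two cistromes with a knockdown differential-expression table.

Simulates a DE table whose planted down-regulated genes lie near peaks
bound by both TFs, filters differential genes (|FC| threshold + FDR),
tests the target-set shift, and tabulates the TF -> gene network report.
"""

from cistromics.genome_model import IntervalSet, nearest_tss
from cistromics.peak_integration import (
    DEGFilter,
    build_network_report,
    distance_stats,
    filter_degs,
    target_shift_test,
)
from cistromics.synthetic_data import (
    DEConfig,
    GenomeConfig,
    PeakConfig,
    SimulationConfig,
    gen_study,
)

cfg = SimulationConfig(
    seed=23,
    genome=GenomeConfig(n_contigs=2, contig_length=150_000, open_fraction=0.2),
    peaks=PeakConfig(n_a=80, n_b=200, overlap_fraction=0.65),
    n_genes=150,
    de=DEConfig(n_down=20, n_up=5),
)
study = gen_study(cfg)

down, up = filter_degs(study.de_table, DEGFilter(fc_threshold=1.5, fdr_threshold=0.05))
print(f"differential genes: {len(down)} down, {len(up)} up "
      f"(|FC| > 1.5, FDR < 5%)")

shift = target_shift_test(study.de_table, down, alternative="less")
print(f"down-gene shift test: rank-sum p = {shift.pvalue:.3g}, "
      f"median target log2FC = {shift.median_target:.2f} "
      f"vs background {shift.median_background:.2f}")

ann_a = nearest_tss(study.set_a, study.tss)
ann_b = nearest_tss(study.set_b, study.tss)
stats_a = distance_stats(ann_a)
print(f"TF-A peak distance to nearest TSS: mean {stats_a.mean/1000:.1f} kb, "
      f"median {stats_a.median/1000:.1f} kb over {stats_a.n} peaks")

report = build_network_report(
    down, set(ann_a["gene"].dropna()), set(ann_b["gene"].dropna()), up_genes=up
)
print(f"network report: of {report.n_down} down genes, "
      f"{report.n_down_with_tfA_peak} near a TF-A peak, "
      f"{report.n_down_with_tfB_peak} near a TF-B peak, "
      f"{report.n_down_with_both} near both")
print(
    "\nThe planted targets were chosen near co-bound peaks, so most down"
    "\ngenes fall in the 'both' cell — the feed-forward signature."
)
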