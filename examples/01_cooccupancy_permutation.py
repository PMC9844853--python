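"""Test whether two TF peak sets co-occupy the genome more than chance.

Simulates a toy genome with open chromatin and two peak sets, 60% of the
first planted to overlap the second, then runs the covariate-matched
permutation test: random region sets constrained to open chromatin and
matched to the query set's joint GC x distance-to-TSS profile replace the
query, and the overlap with the genuine second set forms the null.
"""

from cistromics.genome_model import overlap_count
from cistromics.overlap_null import permutation_overlap_test
from cistromics.synthetic_data import (
    GenomeConfig,
    PeakConfig,
    SimulationConfig,
    gen_genome,
    gen_peaksets,
)

cfg = SimulationConfig(
    seed=11,
    genome=GenomeConfig(n_contigs=2, contig_length=200_000, open_fraction=0.3),
    peaks=PeakConfig(n_a=60, n_b=120, overlap_fraction=0.6),
)
genome, open_chromatin, tss = gen_genome(cfg)
set_a, set_b, truth = gen_peaksets(cfg, open_chromatin)

observed, _ = overlap_count(set_a, set_b)
print(f"peak sets: |A| = {len(set_a)}, |B| = {len(set_b)}")
print(f"planted co-occupying A peaks: {truth['n_planted']}")
print(f"observed A-side overlap: {observed}")

result = permutation_overlap_test(
    set_a, set_b, open_chromatin, genome, tss, n_perm=199, seed=7
)
print(f"matched-null mean overlap: {result.null_mean:.1f}")
print(f"empirical p: {result.empirical_p:.4g}  (floor at 199 permutations: {1/200})")
print(
    "\nThe observed overlap sits far above the matched null, so the"
    "\nco-occupancy is not explained by shared open chromatin, GC"
    "\ncomposition or promoter proximity; p is at the permutation floor."
)
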