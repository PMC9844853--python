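import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cistromics.genome_model import Genome, GenomicInterval, IntervalSet, TSSMap

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return Genome(
        {
            "chr1": "".join(bases[rng.integers(0, 4, size=5000)]),
            "chr2": "".join(bases[rng.integers(0, 4, size=3000)]),
        }
    )


@pytest.fixture(scope="session")
def toy_tss() -> TSSMap:
    return TSSMap(
        {
            "geneA": ("chr1", 100, "+"),
            "geneB": ("chr1", 2500, "-"),
            "geneC": ("chr1", 4800, "+"),
            "geneD": ("chr2", 50, "+"),
            "geneE": ("chr2", 2900, "-"),
        }
    )


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    contigs=("chr1", "chr2"),
    max_pos: int = 2000,
    name: str = "random",
) -> IntervalSet:
    out = []
    for _ in range(n):
        contig = contigs[int(rng.integers(0, len(contigs)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, 120))
        out.append(GenomicInterval(contig, start, start + length))
    return IntervalSet(name, out)
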