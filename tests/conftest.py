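import numpy as np
import pytest

from extremeseq.core import GenotypeMatrix, VariantSite


def make_matrix(genotypes, positions=None, depth=40, quality=60, chrom="chr3", var_class="SNV"):
    """Build a GenotypeMatrix from a (samples x sites) genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, k = g.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(k)]
    sites = [
        VariantSite(chrom, int(p), "A", ("G",), var_class=var_class) for p in positions
    ]
    d = np.broadcast_to(np.asarray(depth), g.shape).copy()
    q = np.broadcast_to(np.asarray(quality), g.shape).copy()
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        sites=sites,
        genotypes=g,
        depth=d,
        quality=q,
    )


@pytest.fixture
def small_cohort():
    """A fast deterministic synthetic cohort shared by several tests."""
    from extremeseq.simulate import SimulationParams, simulate_cohort

    params = SimulationParams(seed=11, interval_length=20_000, planted_window=None)
    return simulate_cohort(params)
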