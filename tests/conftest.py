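import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from featuregp.genotypes import GenotypeMatrix

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_genotypes(matrix, chrom="1", pos=None, populations=None, sex=None):
    """Build a GenotypeMatrix from a plain array for toy tests."""
    g = np.asarray(matrix, dtype=float)
    n, m = g.shape
    pos = list(pos) if pos is not None else list(range(1, m + 1))
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "C"}
    )
    samples = pd.DataFrame(
        {
            "id": [f"ind{i}" for i in range(n)],
            "population": populations if populations is not None else "pop1",
            "sex": sex if sex is not None else "male",
        }
    )
    return GenotypeMatrix(g, variants, samples)


@pytest.fixture(scope="session")
def hwe_genotypes():
    """Unstructured HWE genotypes: n=500, m=1000, no missing calls."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.1, 0.9, 1000)
    g = rng.binomial(2, p, size=(500, 1000)).astype(float)
    return make_genotypes(g)


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end synthetic dataset shared across tests."""
    from featuregp.simdata import SimConfig, simulate

    cfg = SimConfig(
        seed=123,
        n_chromosomes=2,
        chrom_length_bp=250_000,
        n_genes=12,
        n_variants_dense=1500,
        n_variants_chip=200,
        n_individuals={"validation": 400, "discovery": 100},
        h2_target=0.3,
    )
    return cfg, simulate(cfg)
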