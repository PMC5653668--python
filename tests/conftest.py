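import numpy as np
import pytest

from lesionevo.synthetic import CohortConfig, LohEvent, simulate_patient

# compact genome for fast LOH tests: six 100 Mb chromosomes
SMALL_GENOME = tuple((f"chr{i}", 100_000_000) for i in range(1, 7))


def small_patient_config(seed=0, **overrides):
    """3-sample, 3-cluster patient on the compact genome, one LOH event per
    cluster edge, ~200 SNPs per 100 Mb chromosome (20 per 10 Mb)."""
    defaults = dict(
        n_samples=3,
        n_clusters=3,
        n_snps=1200,
        purity_range=(0.6, 0.9),
        genome_model=SMALL_GENOME,
        loh_segments=(
            LohEvent("chr1", 0, 100_000_000, 0),
            LohEvent("chr2", 0, 100_000_000, 1),
            LohEvent("chr3", 0, 100_000_000, 2),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_patient():
    return simulate_patient(small_patient_config(seed=11))


@pytest.fixture(scope="session")
def exome_patient():
    """Full-genome patient used by variant/clonality tests."""
    return simulate_patient(
        CohortConfig(
            n_samples=5, n_clusters=4, n_snps=400,
            purity_range=(0.6, 0.9), seed=7,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
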