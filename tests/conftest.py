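import numpy as np
import pandas as pd
import pytest

from mirgwas.simulate import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A dataset small enough for per-test simulation but with real structure."""
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length=5_000_000,
        n_snps=10_000,
        n_genes=40,
        n_precursors=30,
        sigma0=0.01,
        n_samples=12,
        n_true_pairs=10,
        pair_r=-0.9,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def toy_snps() -> pd.DataFrame:
    """Ten SNPs on one chromosome at 1 kb spacing with known betas."""
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(1, 11)],
            "chrom": "chr1",
            "pos": np.arange(1, 11) * 1000,
            "beta": np.linspace(-0.5, 0.4, 10),
        }
    )
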