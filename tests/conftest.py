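import numpy as np
import pytest

from galmap import simulate


@pytest.fixture
def small_cross_config():
    """Small, fast cross: 2 chromosomes, 200 segregants."""
    return simulate.SimConfig(
        seed=11,
        chrom_lengths_bp=(1_000_000, 1_000_000),
        snp_spacing_bp=2000,
        n_segregants=200,
        qtl=("chr1", 500_000, 1.0),
        segregant_noise_sd=0.4,
    )


@pytest.fixture
def null_cross_config():
    """Cross with no planted effects."""
    return simulate.SimConfig(
        seed=13,
        chrom_lengths_bp=(1_000_000, 1_000_000),
        snp_spacing_bp=2000,
        n_segregants=400,
        qtl=None,
        segregant_noise_sd=0.4,
    )


@pytest.fixture
def flow_config():
    return simulate.SimConfig(
        seed=5,
        strains=(
            simulate.StrainSpec("hi", 0.5, 2.0),
            simulate.StrainSpec("mid", 0.1, 2.0),
            simulate.StrainSpec("lo", 0.02, 2.0),
            simulate.StrainSpec("m2", 0.3, 2.0),
            simulate.StrainSpec("m3", 0.05, 3.0),
            simulate.StrainSpec("m4", 0.15, 1.5),
        ),
        cells_per_well=400,
        n_replicates=3,
        measurement_sd_log2=0.1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
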