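import numpy as np
import pytest

from cardiomap import synth


@pytest.fixture(scope="session")
def qc_bundle():
    """3,000-nucleus two-arm bundle: 15 samples x 200 nuclei, 10% planted
    low-quality, 5% doublets (the QC/clustering recovery conditions)."""
    cfg = synth.SimulationConfig(nuclei_per_sample=200, seed=0)
    return synth.generate_dataset(cfg)


@pytest.fixture(scope="session")
def de_bundle():
    """Default two-arm bundle (8 vs 7 samples, 250 nuclei each) with
    planted |log2FC| = 2 condition effects."""
    return synth.generate_dataset(synth.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def two_type_bundle():
    """Two clean, separable cell types; no artifacts, no condition effect."""
    cfg = synth.SimulationConfig(
        n_cell_types=2,
        doublet_rate=0.0,
        lowq_rate=0.0,
        de_log2fc=0.0,
        samples_per_condition={"NF": 4, "ICM": 4},
        nuclei_per_sample=200,
        seed=0,
    )
    return synth.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
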