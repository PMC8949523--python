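import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import saltgrain as sg

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_cfg() -> sg.SimConfig:
    """Default study conditions with the demo planted tolerance loci."""
    return sg.SimConfig(seed=11, planted_qtls=sg.demo_planted_qtls())


@pytest.fixture(scope="session")
def demo_panel(demo_cfg) -> sg.GenotypePanel:
    return sg.syndata.simulate_genotypes(demo_cfg)


@pytest.fixture(scope="session")
def demo_raw(demo_cfg, demo_panel) -> pd.DataFrame:
    return sg.syndata.simulate_phenotypes(demo_panel, demo_cfg)


@pytest.fixture(scope="session")
def demo_traits(demo_raw) -> pd.DataFrame:
    return sg.phenotyping.relative_traits(demo_raw)


@pytest.fixture(scope="session")
def tiny_panel() -> sg.GenotypePanel:
    """30 accessions x ~80 SNPs, no missing calls: oracle-equivalence scale."""
    cfg = sg.SimConfig(
        seed=5, n_accessions=30, n_chrom=2, snps_per_chrom=40,
        chrom_length_bp=2_000_000, missing_rate=0.0, fst=0.05,
    )
    return sg.syndata.simulate_genotypes(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)
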