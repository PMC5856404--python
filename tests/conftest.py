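import numpy as np
import pytest

from amplicall import BackgroundModel, make_toy_panel
from amplicall.experiments import build_study_fixture


@pytest.fixture(scope="session")
def toy_panel():
    """10 amplicons x 100 bp inserts, 5 genes of 2 amplicons each."""
    return make_toy_panel(n_amplicons=10, insert_len=100, n_genes=5, seed=42)


@pytest.fixture(scope="session")
def flat_background(toy_panel):
    return BackgroundModel.uniform(toy_panel, rate=1e-4, rho=0.0)


@pytest.fixture(scope="session")
def study_fixture():
    """Full calibrated study: 1 kb panel, 30 simulated controls, fitted
    background, thresholds calibrated to the 3e-6 per-base budget."""
    return build_study_fixture(seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
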