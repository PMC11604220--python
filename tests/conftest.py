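"""Shared fixtures: small architectures and reference rate sets.

Reduced architectures (two transcript bins) keep the exact oracle and the
Gillespie runs fast while exercising every transition type.
"""

import numpy as np
import pytest

from polkin import GeneArchitecture, RateSet, SimulationConfig
from polkin.presets import FREE_RATE_MIDPOINTS, published_rates


@pytest.fixture(scope="session")
def tfo_rates() -> RateSet:
    """Published TFO rates with free rates at functional-range midpoints."""
    return published_rates("TFO").replace(
        k_rev3=FREE_RATE_MIDPOINTS["k_rev3"], k4=FREE_RATE_MIDPOINTS["k4"]
    )


@pytest.fixture(scope="session")
def stm_rates() -> RateSet:
    return published_rates("STM").replace(**FREE_RATE_MIDPOINTS)


@pytest.fixture(scope="session")
def arch_tfo() -> GeneArchitecture:
    return GeneArchitecture()


@pytest.fixture(scope="session")
def arch_stm() -> GeneArchitecture:
    return GeneArchitecture(has_uas=True)


@pytest.fixture(scope="session")
def arch_reduced() -> GeneArchitecture:
    """Promoter + 2 transcript bins + terminator."""
    return GeneArchitecture(n_transcript_bins=2)


@pytest.fixture(scope="session")
def arch_reduced_stm() -> GeneArchitecture:
    return GeneArchitecture(n_transcript_bins=2, has_uas=True)


@pytest.fixture
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_genes=2000, seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
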