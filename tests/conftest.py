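import numpy as np
import pandas as pd
import pytest

from epimsap import SimConfig, simulate_pedigree, simulate_population
from epimsap.state_calling import StateMatrix


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, n_groups=3, n_samples_per_group=6, n_loci=60)


@pytest.fixture(scope="session")
def small_population(small_cfg) -> StateMatrix:
    return simulate_population(small_cfg)


@pytest.fixture(scope="session")
def pedigree_data():
    cfg = SimConfig(seed=23, n_loci=300, sexual_families=2, f2_per_family=4,
                    clonal_families=3, clonal_offspring=(3, 2, 2))
    return simulate_pedigree(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_state_matrix(codes: list[str], sample_ids=None, locus_ids=None,
                      metadata: pd.DataFrame | None = None) -> StateMatrix:
    """Build a StateMatrix from rows of one-character state codes."""
    from epimsap.state_calling import CODE_TO_STATE

    calls = np.array([[int(CODE_TO_STATE[c]) for c in row] for row in codes], dtype=np.int8)
    n, L = calls.shape
    return StateMatrix(
        sample_ids or [f"S{i + 1}" for i in range(n)],
        locus_ids or [f"L{j + 1}" for j in range(L)],
        calls,
        metadata if metadata is not None else pd.DataFrame(),
    )
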