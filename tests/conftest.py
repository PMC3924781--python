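import numpy as np
import pytest

from bcqtl.config import RunConfig
from bcqtl.simulate import (
    EpistasisEffect,
    LinkageMap,
    QtlEffect,
    QtlScenario,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes x 6 markers at 10 cM: fast scan tests."""
    return LinkageMap(
        chrom_names=["C1", "C2"],
        marker_names=[[f"A{i}" for i in range(6)], [f"B{i}" for i in range(6)]],
        positions=[np.arange(6) * 10.0, np.arange(6) * 10.0],
    )


@pytest.fixture(scope="session")
def small_scenario():
    """One strong main QTL + one epistatic pair, single environment."""
    return QtlScenario(
        qtls=[
            QtlEffect("Qa", "C1", 25.0, a=2.0, d=1.5),
            QtlEffect("Qb", "C2", 35.0, a=-1.5, d=0.0),
        ],
        epistasis=[EpistasisEffect("E1", "Qa", "Qb", aa=2.0)],
        n_env=1,
        heritability=0.5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_map, small_scenario):
    return simulate_dataset(small_scenario, 80, 80, seed=11, lmap=small_map)


@pytest.fixture()
def fast_config():
    """Config sized for unit tests: EM estimation, few permutations."""
    return RunConfig(
        seed=1, n_perm=100, estimation="em",
        gibbs_burn=100, gibbs_iter=400,
    )
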