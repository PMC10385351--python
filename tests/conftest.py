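import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from augbreed.synthetic_data import SimulationConfig, TraitSim
from augbreed.traits_io import TraitSpec, TrialTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast 3-trait, 4-block, 4-check, 40-test configuration."""
    traits = [
        TraitSim("yield", mean=100.0, sigma_g2=25.0, sigma_e2=16.0,
                 block_sd=2.0),
        TraitSim("size", mean=30.0, sigma_g2=4.0, sigma_e2=1.0,
                 block_sd=0.5),
        TraitSim("colour", mean=50.0, sigma_g2=9.0, sigma_e2=4.0,
                 block_sd=1.0, direction=-1),
    ]
    corr = np.array([[1.0, 0.5, 0.0],
                     [0.5, 1.0, 0.0],
                     [0.0, 0.0, 1.0]])
    return SimulationConfig(
        traits=traits, genetic_corr=corr, n_blocks=4,
        check_ids=("chkA", "chkB", "chkC", "chkD"),
        populations={"POP1": 22, "POP2": 18}, seed=424242)


def build_trial(check_values: np.ndarray, test_values: dict[str, float],
                test_blocks: dict[str, str], trait: str = "y",
                check_ids=None, blocks=None) -> TrialTable:
    """Assemble a one-trait TrialTable from an explicit checks x blocks
    matrix and per-test-genotype values."""
    check_values = np.asarray(check_values, dtype=float)
    c, b = check_values.shape
    check_ids = check_ids or [f"check{i + 1}" for i in range(c)]
    blocks = blocks or [f"B{j + 1}" for j in range(b)]
    rows = []
    for i, chk in enumerate(check_ids):
        for j, blk in enumerate(blocks):
            rows.append({"genotype_id": chk, "population_id": "check",
                         "role": "check", "block": blk,
                         trait: check_values[i, j]})
    for gid, value in test_values.items():
        rows.append({"genotype_id": gid, "population_id": "pop",
                     "role": "test", "block": test_blocks[gid],
                     trait: value})
    return TrialTable(pd.DataFrame(rows), [TraitSpec(trait)])


@pytest.fixture
def toy_trial() -> TrialTable:
    """2 checks x 2 blocks plus 2 tests; values chosen for hand checks."""
    return build_trial(
        np.array([[1.0, 2.0], [3.0, 5.0]]),
        test_values={"g1": 10.0, "g2": 20.0},
        test_blocks={"g1": "B1", "g2": "B2"})
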