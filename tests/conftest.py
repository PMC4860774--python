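import numpy as np
import pandas as pd
import pytest

from radscreen import PlateLayout, SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def compact_sim():
    """One small simulated duplicate screen shared across tests."""
    return simulate_screen(SimulationConfig(seed=12345).compact())


@pytest.fixture
def tiny_layout():
    """A 4x6 plate: outer columns empty, controls in B02/C02, samples elsewhere."""
    roles, genes = {}, {}
    k = 0
    for r in range(4):
        for c in range(6):
            well = f"{'ABCD'[r]}{c + 1:02d}"
            if c in (0, 5):
                roles[well] = "empty"
            elif well == "B02":
                roles[well] = "negative_control"
            elif well == "C02":
                roles[well] = "positive_control"
            else:
                k += 1
                roles[well] = "sample"
                genes[well] = f"G{k:02d}"
    return PlateLayout("PL1", n_rows=4, n_cols=6, roles=roles, genes=genes)


def make_cells(records):
    """Build a per-cell DataFrame from (plate, well, cell, dna, foci) tuples."""
    return pd.DataFrame(
        records,
        columns=["plate", "well", "cell", "dna_intensity", "foci_count"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
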