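import pytest

from repdyn import CloneTable, SimulationConfig, simulate_series


@pytest.fixture
def small_table() -> CloneTable:
    """Three clones with counts 8/1/1 (frequencies 0.8/0.1/0.1)."""
    return CloneTable.from_counts(
        {"CASSLGETQYF": 8, "CASSIRSSYEQYF": 1, "CASRPGQGNTEAFF": 1}, "small"
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default seeded study: blood Pre/PI/PC/PS, expansions injected at PC."""
    series, truth = simulate_series(SimulationConfig(seed=11))
    return series, truth
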