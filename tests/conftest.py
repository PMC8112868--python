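import numpy as np
import pandas as pd
import pytest

from cytoclust.core import Panel, SampleTable, build_experiment


@pytest.fixture
def toy_panel():
    return Panel(
        pd.DataFrame(
            {
                "channel_id": ["c1", "c2", "c3", "c4", "c5"],
                "marker_name": ["CD3", "CD4", "CD8", "Ki67", "DNA"],
                "role": ["lineage", "lineage", "lineage", "functional", "none"],
                "use_clustering": [True, True, True, False, False],
                "use_reduction": [True, True, True, True, False],
            }
        )
    )


@pytest.fixture
def toy_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2"],
                "condition": ["case", "control"],
            }
        )
    )


@pytest.fixture
def toy_exp(toy_panel, toy_samples):
    rng = np.random.default_rng(7)
    raw = rng.uniform(0, 10, size=(10, 5))
    exp = build_experiment(raw, ["S1"] * 6 + ["S2"] * 4, toy_panel, toy_samples)
    return exp


@pytest.fixture(scope="session")
def sim_small():
    """One seeded small simulated experiment shared across tests."""
    from cytoclust.simulate import default_spec, simulate_experiment

    spec = default_spec(seed=11, cells_per_sample=500)
    return simulate_experiment(spec)
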