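import numpy as np
import pandas as pd
import pytest

from jointcoord.simulate import SimConfig, generate_experiment, generate_pair_session


@pytest.fixture(scope="session")
def small_experiment():
    """Six cooperative pairs, default parameters."""
    return generate_experiment(SimConfig(seed=7), n_pairs=6, design="cooperative")


@pytest.fixture(scope="session")
def joint_pair():
    cfg = SimConfig(seed=11, coupling=0.8)
    return generate_pair_session(cfg, "joint", pair_id="p00")


def make_cell_trials(cell_means: dict, n_per_cell: int = 2, spread: float = 4.0):
    """Trials for two participants whose cell means equal ``cell_means`` exactly.

    ``cell_means`` maps a tuple of ``(column, value)`` pairs to a mean RT; each
    participant gets ``n_per_cell`` trials per cell placed symmetrically around
    the mean, so participant cell means — and hence the two-stage group means —
    hit the target exactly.
    """
    rows = []
    offsets = np.linspace(-spread, spread, n_per_cell) if n_per_cell > 1 else [0.0]
    for part in ("s1", "s2"):
        for key, mean in cell_means.items():
            for off in offsets:
                rows.append({**dict(key), "agent_id": part, "rt_ms": mean + off})
    return pd.DataFrame(rows)
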