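import numpy as np
import pandas as pd
import pytest

from repfp import MCParams, SimParams, WindowMatrix, simulate_window_matrix


def make_matrix(values: dict[str, list[float]], labels: pd.DataFrame) -> WindowMatrix:
    """Build a WindowMatrix from raw per-sample value lists."""
    n = len(next(iter(values.values())))
    windows = pd.DataFrame(
        {
            "region_id": [f"chr1:{i * 200000}-{(i + 1) * 200000}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 200000,
            "end": (np.arange(n) + 1) * 200000,
            "partial": False,
        }
    )
    vals = pd.DataFrame(values, index=pd.Index(windows["region_id"], name="region_id"))
    return WindowMatrix(windows=windows, labels=labels, values=vals)


def labels_for(samples: dict[str, str]) -> pd.DataFrame:
    rows = []
    seen: dict[str, int] = {}
    for sid, ct in samples.items():
        seen[ct] = seen.get(ct, 0) + 1
        rows.append({"sample_id": sid, "cell_type": ct, "replicate": f"R{seen[ct]}"})
    return pd.DataFrame(rows)


@pytest.fixture
def worked_example():
    """Two cell types x two replicates over two regions; L1 ratio is 9.0."""
    labels = labels_for({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
    return make_matrix(
        {"A1": [0.0, 0.0], "A2": [0.0, 0.2], "B1": [1.0, 1.0], "B2": [1.0, 0.8]},
        labels,
    )


@pytest.fixture(scope="session")
def planted_sim():
    """4 types x 3 reps, 1000 windows, 12 planted single-window regions."""
    params = SimParams(
        n_types=4,
        reps_per_type=3,
        n_windows=1000,
        n_diff_blocks=12,
        block_len=1,
        effect_size=2.0,
        noise_sd=0.2,
        seed=7,
    )
    return simulate_window_matrix(params)


@pytest.fixture(scope="session")
def sim_mc_params():
    """Selection parameters scaled to the simulated 1000-window genome."""
    return MCParams(n_candidates=100, n_iterations=2000, n_min=20, seed=11)
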