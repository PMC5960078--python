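import numpy as np
import pandas as pd
import pytest

from brmmode.genome_model import CountMatrix, CoverageTrack, GeneModel
from brmmode.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study shared across tests."""
    return simulate_study(SimConfig(n_genes=200, seed=42, n_replicates=3))


@pytest.fixture()
def toy_track():
    """Single 1000-bp chromosome with signal 0..999 (position index)."""
    t = CoverageTrack({"chr1": 1000})
    t.data["chr1"] = np.arange(1000, dtype=float)
    return t


@pytest.fixture()
def flat_track():
    t = CoverageTrack({"chr1": 1000})
    t.data["chr1"][:] = 2.0
    return t


def make_count_matrix(counts: np.ndarray, conditions: list[str]) -> CountMatrix:
    """Assemble a CountMatrix from an array and per-sample condition labels."""
    names = []
    seen: dict[str, int] = {}
    rows = []
    for cond in conditions:
        seen[cond] = seen.get(cond, 0) + 1
        name = f"{cond}_r{seen[cond]}"
        names.append(name)
        rows.append((name, cond, seen[cond]))
    counts_df = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=names
    )
    samples = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"]).set_index(
        "sample_id"
    )
    return CountMatrix(counts=counts_df.astype(np.int64), samples=samples)
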