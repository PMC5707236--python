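import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture(scope="session")
def cohort_geno_table() -> pd.DataFrame:
    """A small genotype table exercising every category and dialect."""
    from genconn.genotypes import parse_genotype_table

    raw = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(8)],
            "httlpr": ["S/S", "s/l", "L/S", "L/L", "la/lg", "NA", "S/L", "L/L"],
            "rs4680": ["Met/Met", "Val/Met", "val/val", "A/G", "G/G", "Met/Val", "", "Val/Val"],
            "rs165599": ["A/A", "A/G", "G/G", "g/a", "A/A", "A/G", "A/A", "NA"],
        }
    )
    return parse_genotype_table(raw)


@pytest.fixture(scope="session")
def two_clique_graph() -> np.ndarray:
    """Two disconnected 3-cliques with unit weights."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        w[a, b] = w[b, a] = 1.0
    return w


def planted_partition_graph(seed: int, n_blocks: int = 6, block_size: int = 10,
                            p_in: float = 0.8, p_out: float = 0.05):
    """Seeded binary planted-partition graph and its true labels."""
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    labels = np.repeat(np.arange(n_blocks), block_size)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                w[i, j] = w[j, i] = 1.0
    return w, labels


@pytest.fixture(scope="session")
def small_cohort():
    """A small end-to-end synthetic cohort (kept light for unit tests)."""
    from genconn import simulate

    return simulate.simulate_cohort(n_subjects=8, n_rois=30, n_volumes=150, seed=42)
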