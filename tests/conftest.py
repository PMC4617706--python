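import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import epasis as ep

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_matrix(data: dict[str, np.ndarray], replicates: list[str], steps: list[str]):
    """Build an IntensityMatrix from accession -> (n_rep, n_step) arrays."""
    cols = pd.MultiIndex.from_product([replicates, steps], names=["replicate", "step"])
    rows = {acc: np.asarray(a, dtype=float).ravel() for acc, a in data.items()}
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return ep.IntensityMatrix(values, replicates, steps)


def assignment_accuracy(assignment: ep.Assignment, truth: ep.SyntheticTruth) -> float:
    """Fraction of proteins whose category matches the generator truth.

    A true module member is correct when assigned its own module label
    (reference group); a background protein is correct when 'unknown'.
    """
    correct = 0
    for acc, label in truth.labels.items():
        cat = assignment.table.at[acc, "category"] if acc in assignment.table.index else "unknown"
        if label == "background":
            correct += cat == "unknown"
        else:
            correct += cat == label
    return correct / len(truth.labels)


@pytest.fixture(scope="session")
def noise_free():
    """Noise-free default-size experiment: 2 modules x 10 members + 20 background."""
    cfg = ep.SynthConfig(seed=11, noise_sd=0.0, dropout=0.0)
    matrix, truth = ep.generate_experiment(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def noisy_default():
    """Default generator config (sigma 0.2, dropout 0.1, 7 replicates)."""
    cfg = ep.SynthConfig(seed=7)
    matrix, truth = ep.generate_experiment(cfg)
    return cfg, matrix, truth


@pytest.fixture
def small_matrix():
    """3 proteins x 2 replicates x 5 steps, no missing cells."""
    steps = list(ep.DEFAULT_STEPS)
    reps = ["R1", "R2"]
    data = {
        "P1": [[2, 2, 2, 2, 2], [2, 2, 2, 2, 2]],
        "P2": [[0, 0, 0, 0, 5], [0, 0, 0, 0, 10]],
        "P3": [[1, 3, 0, 0, 0], [2, 6, 0, 0, 0]],
    }
    return make_matrix(data, reps, steps)
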