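"""Shared fixtures: small hand-built cohorts and label tables."""

import numpy as np
import pandas as pd
import pytest

from immunorules import ImmunoDataset, MarkerSpec


def make_dataset(values: dict, labels: dict | None = None,
                 binary: set | None = None) -> ImmunoDataset:
    """Tiny dataset from column dicts; NaN encodes missing.

    ``labels`` defaults to all-zero aberrations; ``binary`` names markers
    with 0/1 scale (all others graded).
    """
    binary = binary or set()
    vals = pd.DataFrame({k: pd.array(v, dtype=float) for k, v in values.items()})
    n = len(vals)
    lab = pd.DataFrame({"ETV6-RUNX1": [0.0] * n, "KMT2A": [0.0] * n,
                        "hyperdiploidy": [0.0] * n})
    if labels:
        for k, v in labels.items():
            lab[k] = pd.array(v, dtype=float)
    specs = [MarkerSpec(c, "binary" if c in binary else "graded")
             for c in vals.columns]
    return ImmunoDataset(vals, lab, specs)


@pytest.fixture
def eight_patient_labels() -> ImmunoDataset:
    """8 patients: 2 ETV6-only, 1 ETV6+hyperdiploid, 2 hyperdiploid-only,
    3 triple-negative; one dummy marker column."""
    return make_dataset(
        {"CD10": [1, 2, 3, 4, 5, 6, 7, 8]},
        labels={
            "ETV6-RUNX1":    [1, 1, 1, 0, 0, 0, 0, 0],
            "KMT2A":         [0, 0, 0, 0, 0, 0, 0, 0],
            "hyperdiploidy": [0, 0, 1, 1, 1, 0, 0, 0],
        },
    )


@pytest.fixture
def separable_dataset() -> ImmunoDataset:
    """20 patients perfectly separated by X <= 3."""
    x = [0, 1, 2, 3, 0, 1, 2, 3, 1, 2, 4, 5, 6, 7, 4, 5, 6, 7, 5, 6]
    y = [1] * 10 + [0] * 10
    return make_dataset({"X": x, "Z": [0] * 20}, labels={"KMT2A": y})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
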