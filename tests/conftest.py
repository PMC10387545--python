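import warnings

import numpy as np
import pytest

from raschkit import (
    ResponseMatrix,
    estimate_item_parameters,
    estimate_person_measures,
)
from raschkit.simulate import SimulationDesign, simulate_responses, standard_items


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


@pytest.fixture(scope="session")
def pcm_bank():
    """11 five-category PCM items with thresholds spanning about +/-2 logits."""
    return standard_items(11, 5, span=0.8, spacing_jitter=0.2, seed=42)


@pytest.fixture(scope="session")
def conforming_data(pcm_bank):
    """One model-conforming sample at n=500 with its truth record."""
    design = SimulationDesign(n_persons=500, items=pcm_bank, seed=2024)
    return simulate_responses(design)


@pytest.fixture(scope="session")
def conforming_fit(conforming_data, pcm_bank):
    """Estimated items and persons for the conforming sample."""
    rm, _ = conforming_data
    items = estimate_item_parameters(rm)
    persons = estimate_person_measures(rm, items)
    return rm, items, persons


@pytest.fixture(scope="session")
def dichotomous_pair():
    """Two dichotomous items answered by 400 simulated persons."""
    rng = np.random.default_rng(7)
    n = 400
    theta = rng.normal(0, 1, n)
    deltas = np.array([-0.5, 0.7])
    probs = 1 / (1 + np.exp(-(theta[:, None] - deltas[None, :])))
    x = (rng.random((n, 2)) < probs).astype(float)
    return ResponseMatrix(x, np.array([1, 1]),
                          [f"p{i}" for i in range(n)], ["i1", "i2"])
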