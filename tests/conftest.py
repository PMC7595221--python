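import numpy as np
import pandas as pd
import pytest

from proteonet.containers import AbundanceMatrix


def make_meta(sample_ids, condition="healthy", day=5):
    """Minimal single-cell metadata for ad-hoc matrices."""
    rows = [(s, condition, day, i + 1, 1) for i, s in enumerate(sample_ids)]
    return pd.DataFrame(rows, columns=["sample_id", "condition", "day", "bio_rep", "tech_rep"])


def make_matrix(values, proteins=None, samples=None, meta=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i:04d}" for i in range(1, values.shape[0] + 1)]
    samples = samples or [f"s{j}" for j in range(1, values.shape[1] + 1)]
    frame = pd.DataFrame(values, index=proteins, columns=samples)
    return AbundanceMatrix(frame, meta if meta is not None else make_meta(samples))


@pytest.fixture
def small_matrix():
    return make_matrix([[5.0, 2.0, 7.0], [1.0, 4.0, 3.0]])
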