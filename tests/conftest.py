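import numpy as np
import pandas as pd
import pytest

from mirsig.dataio import SignalMatrix, make_annotation, validate_metadata
from mirsig.synthetic_data import SyntheticConfig


def build_matrix(target, negative=None, internal=None, metadata=None, sample_ids=None):
    """Assemble a small SignalMatrix from per-class {probe: [signals]} dicts."""
    target = dict(target)
    negative = dict(negative or {})
    internal = dict(internal or {})
    rows = {**target, **negative, **internal}
    n = len(next(iter(rows.values())))
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    values = pd.DataFrame(rows, index=sample_ids).T
    ann = make_annotation(list(target), list(negative), list(internal))
    if metadata is not None:
        metadata = validate_metadata(pd.DataFrame(metadata, index=sample_ids))
    return SignalMatrix(values=values, annotation=ann, metadata=metadata)


@pytest.fixture
def small_config():
    """Down-scaled cohort for fast end-to-end tests."""
    return SyntheticConfig(
        n_healthy=40,
        n_pbca=40,
        n_mirna=60,
        module_sizes=(15, 15, 15, 15),
        disease_modules={0: 0.9, 1: -0.9},
        disturbance_modules={2: 0.02},
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
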