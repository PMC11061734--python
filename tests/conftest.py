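import numpy as np
import pytest
from hypothesis import settings

from goafs.schema import Dataset, cleveland_schema

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# one in-range template row for the 13 predictors, schema order
TEMPLATE_ROW = [54.0, 1, 3, 130.0, 240.0, 0, 1, 150.0, 0, 1.0, 2, 0, 3]


def build_dataset(n=4, overrides=None, labels=None, missing=None):
    """A small valid dataset from the template row.

    ``overrides``: {feature name: list of n values};
    ``missing``: {feature name: list of n bools}.
    """
    schema = cleveland_schema()
    values = np.tile(np.asarray(TEMPLATE_ROW, dtype=float), (n, 1))
    mask = np.zeros((n, 13), dtype=bool)
    if overrides:
        for name, col in overrides.items():
            values[:, schema.index(name)] = col
    if missing:
        for name, col in missing.items():
            mask[:, schema.index(name)] = col
    if labels is None:
        labels = np.arange(n) % 2
    return Dataset(values=values, missing=mask, labels=np.asarray(labels),
                   schema=schema)


@pytest.fixture
def schema():
    return cleveland_schema()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
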