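import numpy as np
import pytest


def centered_rows(rng, p, n, scale=False):
    """Random centered (optionally unit-mean-square) gene rows."""
    rows = rng.standard_normal((p, n))
    rows -= rows.mean(axis=1, keepdims=True)
    if scale:
        rows *= np.sqrt(n / (rows ** 2).sum(axis=1, keepdims=True))
    return rows


def centered_y(rng, n):
    y = rng.standard_normal(n)
    return y - y.mean()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_data(rng):
    """Centered rows (p=3) and phenotype for n=6 — enumeration scale."""
    return centered_rows(rng, 3, 6), centered_y(rng, 6)
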