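import numpy as np
import pytest


class StubRng:
    """Minimal stand-in for a Generator with scripted draws, used to
    pin the random coefficients of candidate-generation primitives."""

    def __init__(self, integers_values=(0, 0), uniform_value=0.0):
        self._ints = list(integers_values)
        self._uniform = uniform_value

    def integers(self, *args, **kwargs):
        return self._ints.pop(0)

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is not None:
            return np.full(size, self._uniform)
        return self._uniform


@pytest.fixture
def stub_rng_factory():
    return StubRng


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
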