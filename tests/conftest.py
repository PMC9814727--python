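import numpy as np
import pytest

from neqfe import REDUCED_TEMPERATURE, WorkSet


@pytest.fixture
def reduced_workset():
    """Build a WorkSet from reduced-unit (kT) work values."""

    def _make(w_forward=(), w_reverse=(), **kwargs):
        return WorkSet(
            w_forward=np.asarray(w_forward, dtype=float),
            w_reverse=np.asarray(w_reverse, dtype=float),
            temperature=REDUCED_TEMPERATURE,
            **kwargs,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
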