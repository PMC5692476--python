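import numpy as np
import pytest

from foldkit import FoldingTransient


@pytest.fixture
def time_grid():
    """600 s of 1 s sampling, the standard folding-assay grid."""
    return np.arange(0.0, 601.0, 1.0)


@pytest.fixture
def rising_exponential(time_grid):
    """Noiseless rising single-exponential transient, k = 0.0149 s^-1."""
    k = 0.0149
    return FoldingTransient(
        time=time_grid,
        signal=10.0 * (1.0 - np.exp(-k * time_grid)),
        condition_label="rising",
    ), k


def make_transient(time, signal, **kw):
    return FoldingTransient(time=np.asarray(time, float),
                            signal=np.asarray(signal, float), **kw)
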