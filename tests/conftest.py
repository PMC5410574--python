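import numpy as np
import pytest

from cdpmarkov import DetectionParams, make_templates, preprocess_event
from cdpmarkov.detect import Event
from cdpmarkov.dictionary import ShapeDictionary


@pytest.fixture(scope="session")
def det_params():
    return DetectionParams()


@pytest.fixture(scope="session")
def templates12():
    return make_templates(12, seed=1)


@pytest.fixture(scope="session")
def template_dictionary(templates12, det_params):
    """Oracle dictionary whose prototypes are the preprocessed templates."""
    proto = np.array([
        preprocess_event(Event("s", "s", 0, t.rate_hz, t.waveform), det_params).processed_window
        for t in templates12])
    return ShapeDictionary(proto, tuple(t.label for t in templates12),
                           np.zeros_like(proto), len(templates12), pca=None)


def sample_chain_ints(P, n, rng):
    """Small independent chain sampler used as a test-side generator."""
    P = np.asarray(P, dtype=float)
    cum = np.cumsum(P, axis=1)
    out = np.empty(n, dtype=np.int64)
    out[0] = rng.integers(P.shape[0])
    r = rng.random(n)
    for t in range(1, n):
        out[t] = np.searchsorted(cum[out[t - 1]], r[t])
    return out
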