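import numpy as np
import pytest

from larvatrack import PhantomSpec, StimulusProtocol


@pytest.fixture
def short_phantom_spec():
    """A 20 s noiseless phantom: 10 s baseline + ~3 stimulation cycles."""
    return PhantomSpec(protocol=StimulusProtocol(total_s=20.0), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(r: int, pad: int = 3) -> np.ndarray:
    """Digital disk by pixel-center test, used as an analytic shape."""
    n = 2 * r + 2 * pad
    y, x = np.mgrid[:n, :n]
    c = r + pad
    return (x - c) ** 2 + (y - c) ** 2 <= r * r
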