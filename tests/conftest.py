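import numpy as np
import pytest

from synstab import EMGRecording, FactorizationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_nmf_cfg():
    """Few restarts keep unit tests quick; plenty for 6 x 160 matrices."""
    return FactorizationConfig(restarts=10, seed=42)


@pytest.fixture
def triggered_recording(rng):
    """1 s of 6-channel signed noise at 1 kHz, trigger at 0.4 s."""
    samples = rng.normal(size=(6, 1000))
    return EMGRecording(
        samples=samples,
        rate=1000.0,
        muscles=("FHL", "TA", "TFL", "GM", "RA", "ES"),
        trigger_time=0.4,
    )


def unit_columns(W):
    """Normalize columns of W to unit Euclidean norm (test helper)."""
    W = np.asarray(W, dtype=float)
    return W / np.linalg.norm(W, axis=0)
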