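import numpy as np
import pytest

from nonwear.signal_io import AccelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def make_recording(samples, rate_hz=10.0, participant_id="p0"):
    return AccelRecording(
        participant_id=participant_id,
        rate_hz=rate_hz,
        start_epoch_s=0.0,
        samples=np.asarray(samples, dtype=float),
    )


@pytest.fixture
def make_rec():
    return make_recording


def flat_noisy_recording(
    rng, duration_s, rate_hz=10.0, flat=(None, None), noise_sd=0.05, flat_sd=0.001
):
    """Noisy recording with one flat (quiescent) span [flat[0], flat[1])."""
    n = int(duration_s * rate_hz)
    samples = rng.normal(0.0, noise_sd, size=(n, 3))
    samples[:, 2] += 1.0  # gravity on one axis
    a, b = flat
    if a is not None:
        i0, i1 = int(a * rate_hz), int(b * rate_hz)
        samples[i0:i1] = rng.normal(0.0, flat_sd, size=(i1 - i0, 3))
        samples[i0:i1, 2] += 1.0
    return make_recording(samples, rate_hz)


@pytest.fixture
def make_flat_noisy():
    return flat_noisy_recording
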