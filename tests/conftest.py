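import numpy as np
import pytest

from timemap.montage import spherical_montage
from timemap.preprocess import EpochSet


@pytest.fixture(scope="session")
def montage32():
    return spherical_montage(32)


@pytest.fixture(scope="session")
def montage96():
    return spherical_montage(96)


def make_toy_epochs(
    n_epochs=20,
    n_channels=8,
    n_samples=64,
    sfreq=256.0,
    artifact_epochs=(),
    artifact_uv=150.0,
    noise_sd=5.0,
    template=None,
    seed=0,
):
    """Toy raw-epoch generator with optional injected voltage excursions.

    Test-only fixture: ``artifact_epochs`` get a single ``artifact_uv``
    spike on one channel, emulating blink-scale transients that the
    amplitude criterion must catch.
    """
    rng = np.random.default_rng(seed)
    data = noise_sd * rng.standard_normal((n_epochs, n_channels, n_samples))
    if template is not None:
        data += template[None, :, None] * np.sin(
            np.pi * np.arange(n_samples) / n_samples
        )
    for k, e in enumerate(artifact_epochs):
        ch = k % n_channels
        data[e, ch, n_samples // 2] = artifact_uv
    return EpochSet(data=data, sfreq=sfreq, condition="Now", correct=None)
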