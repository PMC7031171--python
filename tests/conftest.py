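import numpy as np
import pytest

from semgfatigue import (
    ChannelSpec,
    PreprocessConfig,
    SpectralConfig,
    compute_mf_series,
    fit_mf_regression,
    generate_semg_channel,
)
from semgfatigue.preprocess import preprocess_channel
from semgfatigue.types import Channel


@pytest.fixture(scope="session")
def preprocess_cfg() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def spectral_cfg() -> SpectralConfig:
    return SpectralConfig()


def recover_fit(onset: float, slope: float, seed, duration: float = 30.0):
    """Full generator -> preprocess -> spectral -> regression round trip."""
    spec = ChannelSpec(label="L5_left", onset_mf=onset, normalized_slope=slope)
    x = generate_semg_channel(spec, duration, 2000.0, seed=seed)
    art = preprocess_channel(Channel(x, 2000.0), PreprocessConfig())
    series = compute_mf_series(
        art.channel, SpectralConfig(), sample_mask=art.sample_mask, electrode="L5_left"
    )
    return fit_mf_regression(series), series


@pytest.fixture(scope="session")
def stationary_channel():
    """One stationary 30-s synthetic channel (onset 100 Hz, slope 0)."""
    spec = ChannelSpec(label="L5_left", onset_mf=100.0)
    x = generate_semg_channel(spec, 30.0, 2000.0, seed=11)
    return Channel(x, 2000.0)
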