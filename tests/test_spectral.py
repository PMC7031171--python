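"""Median-frequency estimation: oracles, structure, invariances."""

import numpy as np
import pytest
from scipy import stats as spstats

from semgfatigue import SpectralConfig, compute_mf_series, median_frequency
from semgfatigue.preprocess import PreprocessConfig, preprocess_channel
from semgfatigue.types import Channel

from conftest import recover_fit

FS = 2000.0


def test_flat_spectrum_median_is_band_midpoint():
    f = np.linspace(20.0, 500.0, 481)
    assert median_frequency(f, np.ones_like(f)) == pytest.approx(260.0, abs=1e-9)


def test_pure_tone_periodogram_median_near_tone():
    t = np.arange(1000) / FS
    x = np.sin(2 * np.pi * 100.0 * t)
    seg = (x - x.mean()) * np.blackman(1000)
    freqs = np.fft.rfftfreq(1000, 1 / FS)
    spec = np.abs(np.fft.rfft(seg)) ** 2
    # oracle: direct cumulative sum over the periodogram bins
    sel = (freqs >= 20) & (freqs <= 500)
    cum = np.cumsum(spec[sel])
    oracle = freqs[sel][np.searchsorted(cum, cum[-1] / 2)]
    assert abs(oracle - 100.0) <= 2.0
    assert median_frequency(freqs, spec) == pytest.approx(100.0, abs=2.0)


def test_single_bin_spectrum_returns_that_bin():
    f = np.arange(20.0, 501.0, 2.0)
    p = np.zeros_like(f)
    p[f == 250.0] = 1.0
    assert median_frequency(f, p) == pytest.approx(250.0, abs=1.0)


def test_zero_power_signalled():
    f = np.arange(20.0, 501.0, 2.0)
    with pytest.raises(ValueError, match="undefined"):
        median_frequency(f, np.zeros_like(f))
    with pytest.raises(ValueError, match="non-negative"):
        median_frequency(f, -np.ones_like(f))


def test_stationary_channel_gives_54_points_near_onset(
    stationary_channel, preprocess_cfg, spectral_cfg
):
    art = preprocess_channel(stationary_channel, preprocess_cfg)
    series = compute_mf_series(art.channel, spectral_cfg, art.sample_mask)
    assert series.n == 54
    assert series.times[0] >= 3.0 and series.times[-1] < 30.0
    assert np.allclose(np.diff(series.times), 0.5)
    assert abs(np.nanmean(series.mf) - 100.0) < 2.0


def test_raw_4hz_output_has_107_estimates(stationary_channel, preprocess_cfg):
    art = preprocess_channel(stationary_channel, preprocess_cfg)
    series = compute_mf_series(art.channel, SpectralConfig(mf_output="raw4hz"))
    assert series.n == 107
    assert np.allclose(np.diff(series.times), 0.25)


def test_artifact_epochs_yield_excluded_points(stationary_channel, preprocess_cfg):
    x = stationary_channel.samples.copy()
    for t0 in (8.0, 15.5):  # aligned to the 500-ms epoch grid
        i = int(t0 * FS)
        x[i : i + int(0.1 * FS)] = preprocess_cfg.adc_full_scale_v
    art = preprocess_channel(Channel(x, FS), preprocess_cfg)
    series = compute_mf_series(art.channel, SpectralConfig(), art.sample_mask)
    assert series.n == 54
    assert series.excluded.sum() == 2


def test_epoch_longer_than_signal_rejected():
    short = Channel(np.random.default_rng(0).standard_normal(500), FS)
    with pytest.raises(ValueError, match="longer"):
        compute_mf_series(short, SpectralConfig())


def test_scale_invariance_of_mf(stationary_channel, preprocess_cfg, spectral_cfg):
    art = preprocess_channel(stationary_channel, preprocess_cfg)
    a = compute_mf_series(art.channel, spectral_cfg)
    scaled = Channel(art.channel.samples * 137.0, FS, art.channel.t_start)
    b = compute_mf_series(scaled, spectral_cfg)
    assert np.max(np.abs(a.mf - b.mf)) < 1e-9


def test_time_reversal_preserves_stationary_mf_distribution(preprocess_cfg, spectral_cfg):
    fwd, rev = [], []
    for seed in range(8):
        _, series = recover_fit(100.0, 0.0, seed=200 + seed)
        fwd.extend(series.mf[~series.excluded])
        from semgfatigue import ChannelSpec, generate_semg_channel

        x = generate_semg_channel(
            ChannelSpec("L5_left", 100.0), 30.0, FS, seed=200 + seed
        )[::-1]
        art = preprocess_channel(Channel(x.copy(), FS), preprocess_cfg)
        s2 = compute_mf_series(art.channel, spectral_cfg, art.sample_mask)
        rev.extend(s2.mf[~s2.excluded])
    _, p = spstats.ks_2samp(fwd, rev)
    assert p > 0.01


def test_monotone_tracking_of_programmed_slopes():
    means = []
    for slope in (0.0, -0.2, -0.4):
        fits = [recover_fit(100.0, slope, seed=300 + s)[0] for s in range(5)]
        means.append(np.mean([f.slope_norm for f in fits]))
    assert means[0] > means[1] > means[2]
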