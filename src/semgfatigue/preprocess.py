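"""SEMG preprocessing: onset trimming, band-pass filtering, artifact rejection.

The unstable first seconds of the sustained contraction are discarded
(default: the first 3 s, analysing 3-30 s), each channel is band-pass
filtered with a zero-phase Butterworth design (20-500 Hz pass band), and
artifact-contaminated epochs are flagged so that downstream
median-frequency estimates can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import Channel


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing stage.

    ``trim_start``/``analysis_end`` bound the analysis window in seconds
    from contraction onset.  The Butterworth order is the order of the
    one-way design; it is applied forward-backward (zero phase), doubling
    the effective order.  The artifact rule is two-part: samples at or
    above ``clip_fraction`` of the ADC full scale mark their epoch as
    clipped, and epochs whose RMS exceeds ``rms_factor`` times the median
    epoch RMS are excluded.  A recording with more than
    ``max_excluded_fraction`` of its epochs excluded is flagged unusable.
    """

    trim_start: float = 3.0
    analysis_end: float = 30.0
    highpass_hz: float = 20.0
    lowpass_hz: float = 500.0
    butter_order: int = 4
    adc_full_scale_v: float = 0.011
    clip_fraction: float = 0.99
    rms_factor: float = 5.0
    artifact_epoch_s: float = 0.5
    max_excluded_fraction: float = 0.5
    allow_short: bool = False

    def validate(self, fs: float | None = None) -> None:
        if not 0 <= self.trim_start < self.analysis_end:
            raise ValueError("need 0 <= trim_start < analysis_end")
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass_hz < lowpass_hz")
        if fs is not None and self.lowpass_hz >= fs / 2:
            raise ValueError(
                f"lowpass cutoff {self.lowpass_hz} Hz must be below the "
                f"Nyquist frequency {fs / 2} Hz"
            )


@dataclass
class ArtifactResult:
    """Outcome of artifact screening on one trimmed channel."""

    channel: Channel
    sample_mask: np.ndarray  # True where the sample lies in an excluded epoch
    epoch_excluded: np.ndarray  # per-epoch flags
    excluded_fraction: float
    usable: bool


def trim_window(channel: Channel, config: PreprocessConfig) -> Channel:
    """Restrict a channel to the analysis window ``[trim_start, analysis_end)``.

    Trimming an already-trimmed channel is a no-op.  Recordings shorter
    than ``analysis_end`` raise unless ``config.allow_short`` is set, in
    which case the available tail is analysed.
    """
    config.validate(channel.fs)
    end = config.analysis_end
    if channel.t_end < end - 0.5 / channel.fs:
        if not config.allow_short:
            raise ValueError(
                f"recording ends at {channel.t_end:.3f} s but the analysis "
                f"window requires {end} s (set allow_short to analyse the "
                "available portion)"
            )
        end = channel.t_end
    start = max(config.trim_start, channel.t_start)
    i0 = int(round((start - channel.t_start) * channel.fs))
    i1 = int(round((end - channel.t_start) * channel.fs))
    return Channel(channel.samples[i0:i1], channel.fs, t_start=start)


def bandpass_filter(channel: Channel, config: PreprocessConfig) -> Channel:
    """Zero-phase Butterworth band-pass (default 20-500 Hz, 4th order)."""
    config.validate(channel.fs)
    sos = sps.butter(
        config.butter_order,
        [config.highpass_hz, config.lowpass_hz],
        btype="bandpass",
        fs=channel.fs,
        output="sos",
    )
    if channel.n == 0:
        return Channel(channel.samples.copy(), channel.fs, channel.t_start)
    filtered = sps.sosfiltfilt(sos, channel.samples)
    return Channel(filtered, channel.fs, t_start=channel.t_start)


def remove_artifacts(channel: Channel, config: PreprocessConfig) -> ArtifactResult:
    """Flag artifact-contaminated epochs of a trimmed channel.

    Epochs are consecutive non-overlapping windows of
    ``config.artifact_epoch_s``.  An epoch is excluded when it contains a
    clipped sample (|x| >= ``clip_fraction`` x ADC full scale) or when its
    RMS exceeds ``rms_factor`` times the median epoch RMS.  The returned
    sample mask is True inside excluded epochs.
    """
    x = channel.samples
    epoch_len = max(1, int(round(config.artifact_epoch_s * channel.fs)))
    n_epochs = max(1, x.size // epoch_len)
    clipped = np.zeros(n_epochs, dtype=bool)
    rms = np.zeros(n_epochs)
    clip_level = config.clip_fraction * config.adc_full_scale_v
    for e in range(n_epochs):
        seg = x[e * epoch_len : (e + 1) * epoch_len if e < n_epochs - 1 else x.size]
        clipped[e] = bool(np.any(np.abs(seg) >= clip_level))
        rms[e] = float(np.sqrt(np.mean(seg**2))) if seg.size else 0.0
    med = float(np.median(rms))
    loud = rms > config.rms_factor * med if med > 0 else np.zeros(n_epochs, bool)
    excluded = clipped | loud
    mask = np.zeros(x.size, dtype=bool)
    for e in np.nonzero(excluded)[0]:
        hi = (e + 1) * epoch_len if e < n_epochs - 1 else x.size
        mask[e * epoch_len : hi] = True
    frac = float(excluded.mean())
    return ArtifactResult(
        channel=channel,
        sample_mask=mask,
        epoch_excluded=excluded,
        excluded_fraction=frac,
        usable=frac <= config.max_excluded_fraction,
    )


def preprocess_channel(
    channel: Channel, config: PreprocessConfig
) -> ArtifactResult:
    """Trim, artifact-screen and band-pass filter one SEMG channel.

    Artifact screening runs on the trimmed raw signal (clipping plateaus
    would be flattened by the high-pass stage); the returned channel is
    the filtered one, with the artifact mask aligned to it.
    """
    trimmed = trim_window(channel, config)
    art = remove_artifacts(trimmed, config)
    filtered = bandpass_filter(trimmed, config)
    return ArtifactResult(
        channel=filtered,
        sample_mask=art.sample_mask,
        epoch_excluded=art.epoch_excluded,
        excluded_fraction=art.excluded_fraction,
        usable=art.usable,
    )
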