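"""Median-frequency time series from short-time spectral analysis.

Each preprocessed channel is cut into Blackman-windowed 500-ms epochs with
50% overlap; every epoch's one-sided periodogram, restricted to the filter
pass band, yields one spectral median frequency (MF).  The raw epoching
produces MF estimates at 4 Hz; adjacent pairs are averaged to emit the
analysis series of 54 samples at 2 Hz spanning the 27-s window (the last
grid point averages the single trailing raw estimate).  Both the raw 4 Hz
and the paired 2 Hz output are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import Channel


@dataclass
class SpectralConfig:
    """Epoching and band parameters of the MF estimator."""

    epoch_s: float = 0.5
    overlap: float = 0.5
    band_low_hz: float = 20.0
    band_high_hz: float = 500.0
    mf_output: str = "paired2hz"  # "paired2hz" (54 @ 2 Hz) or "raw4hz"
    min_usable_epochs: int = 4

    def validate(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.mf_output not in ("paired2hz", "raw4hz"):
            raise ValueError("mf_output must be 'paired2hz' or 'raw4hz'")


@dataclass
class MFSeries:
    """Median-frequency trajectory of one electrode.

    ``times`` is a uniform grid in seconds from contraction onset;
    ``excluded`` marks points invalidated by artifact epochs.
    ``window_start`` is the analysis-window start used as the origin of
    the fatigue regression (the trim point, 3 s by default).
    """

    times: np.ndarray
    mf: np.ndarray
    excluded: np.ndarray
    electrode: str | None = None
    window_start: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mf = np.asarray(self.mf, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (self.times.size == self.mf.size == self.excluded.size):
            raise ValueError("times, mf and excluded must have equal length")
        if self.window_start is None:
            self.window_start = float(self.times[0]) if self.times.size else 0.0

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_usable(self) -> int:
        return int((~self.excluded).sum())

    @property
    def usable(self) -> bool:
        return self.n_usable >= 4


def median_frequency(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = (20.0, 500.0),
) -> float:
    """Frequency splitting the band-limited spectral power in half.

    The spectrum is treated as a density that is piecewise constant over
    each frequency bin; the cumulative power is therefore piecewise linear
    and the half-power crossing is located by linear interpolation, so a
    flat spectrum over [f_lo, f_hi] returns exactly the band midpoint.

    Raises ``ValueError`` when the band carries no power.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.size != power.size:
        raise ValueError("freqs and power must have equal length")
    if np.any(power < 0):
        raise ValueError("power spectrum must be non-negative")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f = freqs[sel]
    p = power[sel]
    if f.size == 0 or not np.any(p > 0):
        raise ValueError("zero total power in band: median frequency undefined")
    if f.size == 1:
        return float(f[0])
    # bin edges halfway between centres; outer edges extend half a step
    mid = 0.5 * (f[1:] + f[:-1])
    edges = np.concatenate(([f[0] - (mid[0] - f[0])], mid, [f[-1] + (f[-1] - mid[-1])]))
    widths = np.diff(edges)
    bin_power = p * widths
    cum = np.concatenate(([0.0], np.cumsum(bin_power)))
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half, side="left")) - 1
    i = min(max(i, 0), widths.size - 1)
    while bin_power[i] == 0 and i < widths.size - 1 and cum[i + 1] <= half:
        i += 1
    frac = (half - cum[i]) / bin_power[i] if bin_power[i] > 0 else 0.5
    return float(edges[i] + frac * widths[i])


def _epoch_starts(n: int, epoch_len: int, hop: int) -> np.ndarray:
    if n < epoch_len:
        raise ValueError(
            f"epoch of {epoch_len} samples is longer than the signal ({n} samples)"
        )
    return np.arange(0, n - epoch_len + 1, hop)


def compute_mf_series(
    channel: Channel,
    config: SpectralConfig | None = None,
    sample_mask: np.ndarray | None = None,
    electrode: str | None = None,
) -> MFSeries:
    """Blackman-windowed short-time MF series of a preprocessed channel.

    ``sample_mask`` (True = artifact) invalidates every epoch it overlaps;
    a 2 Hz output point is excluded when all of its constituent raw
    estimates are invalid.  A series with fewer than
    ``config.min_usable_epochs`` usable points is still returned but
    reports ``usable = False``.
    """
    config = config or SpectralConfig()
    config.validate()
    x = channel.samples
    fs = channel.fs
    epoch_len = int(round(config.epoch_s * fs))
    hop = max(1, int(round(epoch_len * (1.0 - config.overlap))))
    starts = _epoch_starts(x.size, epoch_len, hop)
    window = np.blackman(epoch_len)
    freqs = np.fft.rfftfreq(epoch_len, d=1.0 / fs)
    band = (config.band_low_hz, config.band_high_hz)

    if sample_mask is not None:
        sample_mask = np.asarray(sample_mask, dtype=bool)
        if sample_mask.size != x.size:
            raise ValueError("sample_mask must align with the channel samples")

    raw_mf = np.empty(starts.size)
    raw_bad = np.zeros(starts.size, dtype=bool)
    for k, s in enumerate(starts):
        seg = x[s : s + epoch_len]
        if sample_mask is not None and np.any(sample_mask[s : s + epoch_len]):
            raw_bad[k] = True
            raw_mf[k] = np.nan
            continue
        seg = (seg - seg.mean()) * window
        spec = np.abs(np.fft.rfft(seg)) ** 2
        try:
            raw_mf[k] = median_frequency(freqs, spec, band)
        except ValueError:
            raw_bad[k] = True
            raw_mf[k] = np.nan
    centres = channel.t_start + (starts + epoch_len / 2.0) / fs

    if config.mf_output == "raw4hz":
        return MFSeries(
            times=centres,
            mf=raw_mf,
            excluded=raw_bad,
            electrode=electrode,
            window_start=channel.t_start,
        )

    # pair adjacent raw estimates -> 2 Hz grid (last point may be a singleton)
    n_out = (starts.size + 1) // 2
    out_mf = np.empty(n_out)
    out_bad = np.zeros(n_out, dtype=bool)
    step = hop / fs * 2.0
    out_t = channel.t_start + (epoch_len / 2.0 + hop / 2.0) / fs + step * np.arange(n_out)
    for k in range(n_out):
        idx = [2 * k] + ([2 * k + 1] if 2 * k + 1 < starts.size else [])
        good = [i for i in idx if not raw_bad[i]]
        if good:
            out_mf[k] = float(np.mean(raw_mf[good]))
        else:
            out_mf[k] = np.nan
            out_bad[k] = True
    return MFSeries(
        times=out_t,
        mf=out_mf,
        excluded=out_bad,
        electrode=electrode,
        window_start=channel.t_start,
    )
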