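"""Synthetic SEMG recordings and cohorts with known ground truth.

The signal model is Gaussian noise shaped in the short-time spectral
domain: independent white-noise frames are band-limited to a flat band of
configurable width centred on the programmed median-frequency trajectory
MF(t) = onset * (1 + slope/100 * t) and combined by square-root-Hann
overlap-add, which keeps the output variance stationary.  Because the
band is flat (with fractional-bin soft edges), its spectral median is the
band centre, so the downstream spectral stage recovers the programmed
trajectory without simulating motor units.

Cohorts for reliability and group-statistics testing are drawn from the
crossed random-effects model value = group mean + subject + day + side +
subject x day + subject x side + residual, all Gaussian with configurable
variances, so every estimator downstream has a recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reliability import VarianceComponents
from .types import (
    AGE_GROUPS,
    CANONICAL_CHANNELS,
    DEFAULT_ACCEL_FS,
    DEFAULT_SEMG_FS,
    LEVELS,
    SEXES,
    SIDES,
    ContractionRecording,
    RecordingMeta,
    channel_label,
)

#: Typical onset MFs (Hz) per lumbar level for a young cohort and a common
#: normalised fatigue slope (%/s) used as simulation defaults.
DEFAULT_ONSETS_HZ = {"L5": 117.0, "L2": 101.0, "L1": 85.5}
DEFAULT_SLOPE_NORM = -0.19


@dataclass
class ChannelSpec:
    """Ground-truth parameters of one synthetic SEMG channel.

    ``onset_mf`` is the spectral median at contraction onset (t = 0) and
    ``normalized_slope`` its linear rate of change in %/s, so
    MF(t) = onset_mf * (1 + normalized_slope/100 * t).  ``bandwidth_hz``
    is the width of the flat spectral band around MF(t);
    ``amplitude_rms`` scales the signal and ``noise_floor_rms`` adds
    broadband measurement noise (both in volts).
    """

    label: str
    onset_mf: float
    normalized_slope: float = 0.0
    amplitude_rms: float = 150e-6
    noise_floor_rms: float = 0.75e-6
    bandwidth_hz: float = 50.0

    def validate(self) -> None:
        if not 20.0 < self.onset_mf < 500.0:
            raise ValueError(
                f"onset_mf must lie in (20, 500) Hz, got {self.onset_mf}"
            )
        if self.amplitude_rms <= 0:
            raise ValueError("amplitude_rms must be positive")
        if self.noise_floor_rms < 0:
            raise ValueError("noise_floor_rms must be >= 0")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be positive")

    def mf_at(self, t) -> np.ndarray:
        return self.onset_mf * (1.0 + self.normalized_slope / 100.0 * np.asarray(t))


@dataclass
class AngleProfile:
    """Programmed trunk-angle trajectory for the lever-arm accelerometer."""

    onset_deg: float = 23.0
    drift_deg_s: float = 0.0
    noise_sd_g: float = 0.01
    quantize_8bit: bool = False
    range_g: float = 1.5  # quantiser full scale (+/-)

    def angle_at(self, t) -> np.ndarray:
        return self.onset_deg + self.drift_deg_s * np.asarray(t)


def generate_semg_channel(
    spec: ChannelSpec, duration: float, fs: float = DEFAULT_SEMG_FS, seed=0
) -> np.ndarray:
    """Synthesize one SEMG channel tracking the programmed MF trajectory.

    Returns ``round(duration * fs)`` zero-mean samples in volts whose
    short-time spectral median follows MF(t) within estimator noise.
    The programmed band must stay inside (20, fs/2) over the whole
    duration, mirroring the analysis filter band.
    """
    spec.validate()
    if duration < 4:
        raise ValueError("duration must be at least 4 s")
    if fs < 1024:
        raise ValueError("sampling rate must be at least 1024 Hz")
    half_bw = spec.bandwidth_hz / 2.0
    for t_edge in (0.0, duration):
        mf = float(spec.mf_at(t_edge))
        if mf - half_bw <= 20.0 or mf + half_bw >= min(500.0, fs / 2.0):
            raise ValueError(
                f"programmed MF trajectory ({mf:.1f} Hz at t={t_edge:.0f} s, "
                f"band +/-{half_bw:.0f} Hz) leaves the 20-500 Hz filter band"
            )

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    frame = 512
    hop = frame // 2
    window = np.sqrt(np.hanning(frame))
    freqs = np.fft.rfftfreq(frame, d=1.0 / fs)
    df = freqs[1] - freqs[0]
    out = np.zeros(n + frame)
    for start in range(0, n, hop):
        t_centre = (start + frame / 2.0) / fs
        centre = float(spec.mf_at(t_centre))
        lo, hi = centre - half_bw, centre + half_bw
        # fractional-bin soft edges keep the band's power median at its centre
        overlap = np.clip(
            (np.minimum(freqs + df / 2, hi) - np.maximum(freqs - df / 2, lo)) / df,
            0.0,
            1.0,
        )
        spectrum = np.sqrt(overlap) * (
            rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
        )
        spectrum[0] = 0.0
        seg = np.fft.irfft(spectrum, n=frame)
        out[start : start + frame] += seg * window
    x = out[:n]
    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0:
        x = x * (spec.amplitude_rms / rms)
    if spec.noise_floor_rms > 0:
        x = x + rng.normal(0.0, spec.noise_floor_rms, size=n)
    return x


def generate_accel_trace(
    profile: AngleProfile, duration: float, fs: float = DEFAULT_ACCEL_FS, seed=0
) -> np.ndarray:
    """Tri-axial accelerometer trace (g units) for a programmed angle profile.

    The z axis is sin(angle(t)) plus Gaussian noise; x carries the
    complementary cos component and y pure noise.  Optional 8-bit
    quantisation over +/-``range_g`` mirrors a low-resolution acquisition
    chain (off by default).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    theta = np.radians(profile.angle_at(t))
    trace = np.empty((n, 3))
    trace[:, 0] = np.cos(theta)
    trace[:, 1] = 0.0
    trace[:, 2] = np.sin(theta)
    if profile.noise_sd_g > 0:
        trace += rng.normal(0.0, profile.noise_sd_g, size=trace.shape)
    if profile.quantize_8bit:
        step = 2.0 * profile.range_g / 255.0
        trace = np.clip(np.round(trace / step) * step, -profile.range_g, profile.range_g)
    return trace


def default_channel_specs(
    slope_norm: float = DEFAULT_SLOPE_NORM,
    onsets: dict[str, float] | None = None,
    right_left_onset_ratio: float = 1.0,
) -> list[ChannelSpec]:
    """Six-channel spec set with typical per-level onsets.

    ``right_left_onset_ratio`` scales right-side onsets relative to the
    left to program a lateral MF asymmetry (1.0 = symmetric).
    """
    onsets = onsets or DEFAULT_ONSETS_HZ
    specs = []
    for level in LEVELS:
        for side in SIDES:
            onset = onsets[level] * (right_left_onset_ratio if side == "right" else 1.0)
            specs.append(
                ChannelSpec(
                    label=channel_label(level, side),
                    onset_mf=onset,
                    normalized_slope=slope_norm,
                )
            )
    return specs


def generate_recording(
    channel_specs: list[ChannelSpec],
    angle_profile: AngleProfile | None = None,
    duration: float = 30.0,
    seed=0,
    meta: RecordingMeta | None = None,
    semg_fs: float = DEFAULT_SEMG_FS,
    accel_fs: float = DEFAULT_ACCEL_FS,
) -> ContractionRecording:
    """Bundle six synthetic SEMG channels and an accelerometer trace.

    Exactly one spec per canonical electrode site is required.  All
    randomness derives from ``seed`` via spawned child generators, so
    identical inputs give bit-identical recordings.
    """
    labels = [s.label for s in channel_specs]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate channel labels in spec list")
    if set(labels) != set(CANONICAL_CHANNELS):
        missing = sorted(set(CANONICAL_CHANNELS) - set(labels))
        extra = sorted(set(labels) - set(CANONICAL_CHANNELS))
        raise ValueError(
            f"channel specs must cover all six sites; missing {missing}, "
            f"unexpected {extra}"
        )
    angle_profile = angle_profile or AngleProfile()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(channel_specs) + 1)
    by_label = {s.label: s for s in channel_specs}
    semg = {}
    for i, label in enumerate(CANONICAL_CHANNELS):
        semg[label] = generate_semg_channel(
            by_label[label], duration, semg_fs, seed=children[i]
        )
    accel = generate_accel_trace(angle_profile, duration, accel_fs, seed=children[-1])
    return ContractionRecording(
        semg=semg,
        accel=accel,
        meta=meta or RecordingMeta(subject_id="synthetic"),
        semg_fs=semg_fs,
        accel_fs=accel_fs,
    )


@dataclass
class CohortSpec:
    """Design of a synthetic cohort of per-subject metric values.

    ``group_means`` maps (age_group, sex) cells to the cell mean of the
    target metric; ``n_per_group`` subjects are drawn per cell.  Values
    follow the crossed random-effects model whose facet variances are
    given by ``variance_components`` (metric units squared).  The default
    components emulate a normalised fatigue slope in %/s with
    single-observation dependability around 0.85 and total SD ~0.1 %/s.
    """

    n_per_group: int = 25
    group_means: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("young", "male"): -0.21,
            ("young", "female"): -0.21,
            ("old", "male"): -0.12,
            ("old", "female"): -0.12,
        }
    )
    variance_components: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(
            subject=9.0e-3,
            day=1.0e-4,
            side=1.0e-4,
            subject_day=4.0e-4,
            subject_side=2.0e-4,
            residual=8.0e-4,
        )
    )
    n_days: int = 3
    n_sides: int = 2
    seed: int = 0
    metric: str = "slope_norm"

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_sides not in (1, 2):
            raise ValueError("n_sides must be 1 or 2")
        for age, sex in self.group_means:
            if age not in AGE_GROUPS or sex not in SEXES:
                raise ValueError(f"unknown cohort cell ({age!r}, {sex!r})")

    @property
    def total_variance(self) -> float:
        return sum(self.variance_components.as_dict().values())


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a tidy cohort table from the crossed random-effects model.

    Returns one row per subject x day x side with columns ``subject``,
    ``age_group``, ``sex``, ``test_day``, ``day``, ``side`` and the
    metric value.  With all variance components zero every value equals
    its cell mean exactly.  Reproducible for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vc = spec.variance_components
    days = list(range(1, spec.n_days + 1))
    sides = list(SIDES[: spec.n_sides])
    sd = {f: float(np.sqrt(v)) for f, v in vc.as_dict().items()}

    day_eff = rng.normal(0.0, sd["day"], size=spec.n_days)
    side_eff = rng.normal(0.0, sd["side"], size=len(sides))

    rows = []
    subject_idx = 0
    for (age, sex), mean in spec.group_means.items():
        for _ in range(spec.n_per_group):
            subject_idx += 1
            sid = f"S{subject_idx:04d}"
            p = rng.normal(0.0, sd["subject"])
            pd_eff = rng.normal(0.0, sd["subject_day"], size=spec.n_days)
            ps_eff = rng.normal(0.0, sd["subject_side"], size=len(sides))
            for j, day in enumerate(days):
                for k, side in enumerate(sides):
                    value = (
                        mean
                        + p
                        + day_eff[j]
                        + side_eff[k]
                        + pd_eff[j]
                        + ps_eff[k]
                        + rng.normal(0.0, sd["residual"])
                    )
                    rows.append(
                        {
                            "subject": sid,
                            "age_group": age,
                            "sex": sex,
                            "test_day": day,
                            "day": day,
                            "side": side,
                            spec.metric: value,
                        }
                    )
    return pd.DataFrame(rows)
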