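"""Core containers for sustained-contraction SEMG recordings.

A recording bundles six surface-EMG channels (three lumbar levels, two
sides) sampled at 2000 Hz with a tri-axial lever-arm accelerometer trace
sampled at 160 Hz, plus subject metadata.  All time axes start at t = 0 at
contraction onset and are expressed in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical electrode order; also the tie-break order for the
#: "most negative electrode" aggregate.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "L5_left",
    "L5_right",
    "L2_left",
    "L2_right",
    "L1_left",
    "L1_right",
)

#: Lumbar levels in canonical order (L5 multifidus, L2 longissimus,
#: L1 iliocostalis lumborum).
LEVELS: tuple[str, ...] = ("L5", "L2", "L1")

#: Report order used by the imbalance summary.
REPORT_LEVELS: tuple[str, ...] = ("L1", "L2", "L5")

SIDES: tuple[str, ...] = ("left", "right")
AGE_GROUPS: tuple[str, ...] = ("young", "old")
SEXES: tuple[str, ...] = ("male", "female")
TEST_DAYS: tuple[int, ...] = (1, 2, 3)

DEFAULT_SEMG_FS = 2000.0
DEFAULT_ACCEL_FS = 160.0


def channel_label(level: str, side: str) -> str:
    return f"{level}_{side}"


def split_label(label: str) -> tuple[str, str]:
    level, _, side = label.partition("_")
    return level, side


@dataclass
class Channel:
    """One sampled signal with its rate and the time of its first sample."""

    samples: np.ndarray
    fs: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("channel samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n) / self.fs


@dataclass
class RecordingMeta:
    """Per-recording metadata carried alongside the signals."""

    subject_id: str
    age_group: str = "young"
    sex: str = "male"
    test_day: int = 1
    mvc_load: float | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.test_day = int(self.test_day)
        if self.test_day not in TEST_DAYS:
            raise ValueError(f"test_day must be in {TEST_DAYS}, got {self.test_day}")


@dataclass
class ContractionRecording:
    """Raw signals from one 30-s sustained 80%-MVC back extension.

    Parameters
    ----------
    semg
        Mapping of electrode label to voltage samples.  Labels must be
        exactly the six canonical ``{L1,L2,L5} x {left,right}`` sites; the
        mapping is re-ordered canonically on construction.
    semg_fs
        SEMG sampling rate in Hz (2000 by default).
    accel
        ``(n, 3)`` accelerometer trace in g units (axes x, y, z).
    accel_fs
        Accelerometer sampling rate in Hz (160 by default).
    meta
        Subject/session metadata.
    """

    semg: dict[str, np.ndarray]
    accel: np.ndarray
    meta: RecordingMeta
    semg_fs: float = DEFAULT_SEMG_FS
    accel_fs: float = DEFAULT_ACCEL_FS

    def __post_init__(self) -> None:
        labels = set(self.semg)
        expected = set(CANONICAL_CHANNELS)
        missing = sorted(expected - labels)
        unknown = sorted(labels - expected)
        if unknown:
            raise ValueError(f"unknown SEMG channel label(s): {unknown}")
        if missing:
            raise ValueError(f"missing SEMG channel(s): {missing}")
        arrays = {k: np.asarray(v, dtype=float) for k, v in self.semg.items()}
        lengths = {k: a.size for k, a in arrays.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"SEMG channels have inconsistent lengths: {lengths}")
        self.semg = {k: arrays[k] for k in CANONICAL_CHANNELS}
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must have shape (n, 3)")
        if self.semg_fs <= 0 or self.accel_fs <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def duration(self) -> float:
        return next(iter(self.semg.values())).size / self.semg_fs

    def channel(self, label: str) -> Channel:
        """SEMG channel as a :class:`Channel` starting at t = 0."""
        return Channel(self.semg[label], self.semg_fs, t_start=0.0)

    def accel_axis(self, axis: str = "z") -> Channel:
        idx = {"x": 0, "y": 1, "z": 2}[axis]
        return Channel(self.accel[:, idx], self.accel_fs, t_start=0.0)
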