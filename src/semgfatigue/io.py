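"""Plain-text recording and metric-table I/O.

A recording is stored as three sibling files sharing a stem:

* ``<stem>.meta.txt``  -- ``key: value`` metadata sidecar
* ``<stem>.semg.csv``  -- wide table, ``t_s`` plus one column per electrode
* ``<stem>.accel.csv`` -- wide table, ``t_s`` plus ``acc_x/acc_y/acc_z``

Times are seconds from contraction onset.  Text keeps fixtures diff-able
and round-trips losslessly at 17 significant digits.  Metric tables are
tidy CSV written/read through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import CANONICAL_CHANNELS, ContractionRecording, RecordingMeta

FLOAT_FMT = "%.17g"


def _meta_path(stem: Path) -> Path:
    return stem.with_name(stem.name + ".meta.txt")


def write_recording(rec: ContractionRecording, stem) -> Path:
    """Write a recording as ``<stem>.meta.txt`` + two CSV signal tables."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    meta = rec.meta
    lines = [
        f"subject_id: {meta.subject_id}",
        f"age_group: {meta.age_group}",
        f"sex: {meta.sex}",
        f"test_day: {meta.test_day}",
        f"semg_fs: {rec.semg_fs!r}",
        f"accel_fs: {rec.accel_fs!r}",
    ]
    if meta.mvc_load is not None:
        lines.append(f"mvc_load: {meta.mvc_load!r}")
    _meta_path(stem).write_text("\n".join(lines) + "\n")

    n = next(iter(rec.semg.values())).size
    semg = pd.DataFrame({"t_s": np.arange(n) / rec.semg_fs})
    for label in CANONICAL_CHANNELS:
        semg[label] = rec.semg[label]
    semg.to_csv(stem.with_name(stem.name + ".semg.csv"), index=False, float_format=FLOAT_FMT)

    accel = pd.DataFrame(
        {
            "t_s": np.arange(rec.accel.shape[0]) / rec.accel_fs,
            "acc_x": rec.accel[:, 0],
            "acc_y": rec.accel[:, 1],
            "acc_z": rec.accel[:, 2],
        }
    )
    accel.to_csv(stem.with_name(stem.name + ".accel.csv"), index=False, float_format=FLOAT_FMT)
    return stem


def read_recording(stem) -> ContractionRecording:
    """Read a recording written by :func:`write_recording`.

    Channel order is normalised to the canonical label order regardless
    of the column order on disk; missing channels, unknown labels or
    inconsistent lengths raise a ``ValueError`` naming the offending
    field.
    """
    stem = Path(stem)
    meta_file = _meta_path(stem)
    if not meta_file.exists():
        raise FileNotFoundError(f"no metadata sidecar at {meta_file}")
    kv = {}
    for line in meta_file.read_text().splitlines():
        if line.strip():
            key, _, value = line.partition(":")
            kv[key.strip()] = value.strip()
    meta = RecordingMeta(
        subject_id=kv.get("subject_id", "unknown"),
        age_group=kv.get("age_group", "young"),
        sex=kv.get("sex", "male"),
        test_day=int(kv.get("test_day", 1)),
        mvc_load=float(kv["mvc_load"]) if "mvc_load" in kv else None,
    )
    semg_fs = float(kv.get("semg_fs", 2000.0))
    accel_fs = float(kv.get("accel_fs", 160.0))

    semg_df = pd.read_csv(
        stem.with_name(stem.name + ".semg.csv"), float_precision="round_trip"
    )
    cols = [c for c in semg_df.columns if c != "t_s"]
    unknown = sorted(set(cols) - set(CANONICAL_CHANNELS))
    if unknown:
        raise ValueError(f"unknown SEMG channel label(s) in file: {unknown}")
    missing = sorted(set(CANONICAL_CHANNELS) - set(cols))
    if missing:
        raise ValueError(f"missing SEMG channel(s) in file: {missing}")
    semg = {label: semg_df[label].to_numpy(dtype=float) for label in CANONICAL_CHANNELS}

    accel_df = pd.read_csv(
        stem.with_name(stem.name + ".accel.csv"), float_precision="round_trip"
    )
    for col in ("acc_x", "acc_y", "acc_z"):
        if col not in accel_df.columns:
            raise ValueError(f"missing accelerometer column {col!r}")
    accel = accel_df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    return ContractionRecording(
        semg=semg, accel=accel, meta=meta, semg_fs=semg_fs, accel_fs=accel_fs
    )


#: Column schema of the tidy per-recording fatigue metric table.
METRIC_COLUMNS = [
    "subject",
    "age_group",
    "sex",
    "test_day",
    "electrode",
    "intercept_hz",
    "slope_hz_s",
    "slope_norm",
    "n_points",
    "r2",
    "usable",
]


def write_metrics(table: pd.DataFrame, path, columns: list[str] | None = None) -> Path:
    """Write a tidy metric table as CSV with full float precision.

    ``columns`` (default: the fatigue metric schema) must all be present;
    an empty table produces a header-only file.
    """
    columns = columns or METRIC_COLUMNS
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"metric table is missing column(s): {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[columns].to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg
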