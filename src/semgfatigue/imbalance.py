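"""Left/right SEMG imbalance parameters.

For each lumbar level the sample-by-sample ratio right/left of the two MF
series is transformed into a corrected ratio R that is centred on zero,
antisymmetric (R(r) = -R(1/r)) and expressed as a percentage difference
between sides (positive = right > left).  The time-mean of each level's R
series is the segmental imbalance; across the three levels the mean of
absolute segmental values is the "uncompensated" imbalance and the signed
mean the "compensated" imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .spectral import MFSeries
from .types import REPORT_LEVELS


@dataclass
class RatioSeries:
    """Right/left ratio samples on the joint non-excluded grid points."""

    times: np.ndarray
    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ImbalanceSummary:
    """Segmental (per-level, %) and global imbalance parameters."""

    segmental: dict[str, float]  # level -> signed %, positive = right > left
    uncompensated: float  # mean of |segmental| across levels, >= 0
    compensated: float  # signed mean of segmental across levels


def ratio_series(right: MFSeries, left: MFSeries) -> RatioSeries:
    """Element-wise right/left ratios over jointly valid grid points."""
    if right.n != left.n or not np.allclose(right.times, left.times):
        raise ValueError("right and left MF series must share the same time grid")
    good = ~right.excluded & ~left.excluded
    good &= np.isfinite(right.mf) & np.isfinite(left.mf)
    lv = left.mf[good]
    if np.any(lv <= 0):
        raise ValueError("left-side MF values must be positive to form ratios")
    return RatioSeries(times=right.times[good], values=right.mf[good] / lv)


def _percent_diff(r: np.ndarray) -> np.ndarray:
    # (r - 1) * 100 for r >= 1, mirrored as -(1/r - 1) * 100 for r < 1
    return np.where(r >= 1.0, (r - 1.0) * 100.0, -(1.0 / r - 1.0) * 100.0)


def _log_percent(r: np.ndarray) -> np.ndarray:
    return 100.0 * np.log(r)


#: Available corrected-ratio transforms.  Both satisfy R(1) = 0,
#: antisymmetry R(r) = -R(1/r) and monotonicity in r.
TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "percent_diff": _percent_diff,
    "log": _log_percent,
}


def symmetric_transform(r, method: str = "percent_diff"):
    """Corrected ratio R (%) from a raw right/left ratio.

    Scalar in, scalar out; array in, array out.  ``r`` must be positive.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("raw ratios must be positive")
    try:
        fn = TRANSFORMS[method]
    except KeyError:
        raise ValueError(f"unknown transform {method!r}; options: {sorted(TRANSFORMS)}")
    out = fn(arr)
    return float(out) if np.isscalar(r) else out


def imbalance_summary(
    segmental_series: dict[str, np.ndarray],
    transform_applied: bool = True,
    method: str = "percent_diff",
) -> ImbalanceSummary:
    """Global imbalance parameters from the three levels' R series.

    ``segmental_series`` maps each of L1/L2/L5 to its corrected-ratio
    series (or to raw ratios when ``transform_applied`` is False, in
    which case the transform is applied here first).
    """
    missing = [lv for lv in REPORT_LEVELS if lv not in segmental_series]
    if missing:
        raise ValueError(f"missing lumbar level(s): {missing}")
    segmental: dict[str, float] = {}
    for lv in REPORT_LEVELS:
        series = np.asarray(segmental_series[lv], dtype=float)
        if series.size == 0:
            raise ValueError(f"empty ratio series for level {lv}")
        if not transform_applied:
            series = symmetric_transform(series, method=method)
        segmental[lv] = float(series.mean())
    vals = np.array([segmental[lv] for lv in REPORT_LEVELS])
    return ImbalanceSummary(
        segmental=segmental,
        uncompensated=float(np.abs(vals).mean()),
        compensated=float(vals.mean()),
    )
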