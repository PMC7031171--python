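"""Fatigue outcomes from the median-frequency trajectory.

For each electrode an ordinary least-squares line is fitted to MF versus
time over the analysis window.  The intercept, evaluated at the window
start, is the onset MF (initial spectral content); the slope in Hz/s
normalised to that onset gives the fatigue rate in %/s.  Per-recording
aggregates are the mean across the six electrodes ("all") and the
electrode with the steepest (most negative) normalised slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .spectral import MFSeries
from .types import CANONICAL_CHANNELS


@dataclass
class FatigueFit:
    """Linear MF-vs-time fit for one electrode."""

    electrode: str | None
    intercept_hz: float
    slope_hz_s: float
    n_points: int
    r2: float
    usable: bool = True

    @property
    def slope_norm(self) -> float:
        """Normalised fatigue slope in %/s: 100 * slope / onset MF."""
        return 100.0 * self.slope_hz_s / self.intercept_hz


@dataclass
class FatigueSummary:
    """Per-recording aggregate of the six electrode fits."""

    fits: dict[str, FatigueFit]
    all_mean_slope_norm: float
    all_mean_onset_hz: float
    most_negative: FatigueFit
    n_usable: int


def fit_mf_regression(series: MFSeries, min_points: int = 4) -> FatigueFit:
    """OLS fit of MF on time over the non-excluded points of a series.

    Time is referenced to the series' analysis-window start, so the
    intercept is the MF at the start of the regression domain (3 s from
    contraction onset at default settings).
    """
    good = ~series.excluded & np.isfinite(series.mf)
    n = int(good.sum())
    if n < min_points:
        return FatigueFit(series.electrode, np.nan, np.nan, n, np.nan, usable=False)
    t = series.times[good] - float(series.window_start)
    y = series.mf[good]
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return FatigueFit(series.electrode, float(intercept), float(slope), n, r2)


def summarize_fatigue(fits: dict[str, FatigueFit]) -> FatigueSummary:
    """Aggregate six electrode fits into the "all" and "most negative" outcomes.

    The "all" values are arithmetic means over the usable electrodes (all
    six when none failed); "most negative" is the usable fit with the
    smallest normalised slope, ties broken by canonical electrode order.
    """
    missing = [c for c in CANONICAL_CHANNELS if c not in fits]
    if missing:
        raise ValueError(f"missing electrode fit(s): {missing}")
    usable = [c for c in CANONICAL_CHANNELS if fits[c].usable]
    if not usable:
        raise ValueError("no usable electrode fits to summarise")
    slopes = np.array([fits[c].slope_norm for c in usable])
    onsets = np.array([fits[c].intercept_hz for c in usable])
    most = usable[0]
    for c in usable[1:]:
        if fits[c].slope_norm < fits[most].slope_norm:
            most = c
    return FatigueSummary(
        fits=fits,
        all_mean_slope_norm=float(slopes.mean()),
        all_mean_onset_hz=float(onsets.mean()),
        most_negative=fits[most],
        n_usable=len(usable),
    )


def slope_vs_zero_test(
    slopes: np.ndarray, threshold: float = 0.0025
) -> tuple[float, float, bool]:
    """One-sample t-test of a subgroup's normalised slopes against zero.

    Returns ``(t, p, significant)`` where significance uses the
    Bonferroni-corrected threshold for 5 electrode aggregates x 4
    age/sex subgroups (p < 0.0025 by default).  Requires at least three
    values with non-zero variance.
    """
    slopes = np.asarray(slopes, dtype=float)
    if slopes.size < 3:
        raise ValueError("slope-vs-zero test needs at least 3 subjects")
    if np.allclose(slopes, slopes[0]):
        if slopes[0] == 0.0:
            return 0.0, 1.0, False
        raise ValueError("zero variance: t statistic undefined")
    t, p = spstats.ttest_1samp(slopes, 0.0)
    return float(t), float(p), bool(p < threshold)
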