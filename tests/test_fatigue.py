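"""Fatigue regression, aggregates and the slope-vs-zero test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semgfatigue import (
    FatigueFit,
    MFSeries,
    fit_mf_regression,
    slope_vs_zero_test,
    summarize_fatigue,
)
from semgfatigue.types import CANONICAL_CHANNELS


def _series(values, start=3.0, excluded=None):
    values = np.asarray(values, dtype=float)
    t = start + 0.5 * np.arange(values.size)
    if excluded is None:
        excluded = np.zeros(values.size, bool)
    return MFSeries(times=t, mf=values, excluded=excluded, window_start=start)


def test_noiseless_line_recovered_exactly():
    t = 0.5 * np.arange(54)
    fit = fit_mf_regression(_series(100.0 - 0.5 * t))
    assert fit.intercept_hz == pytest.approx(100.0, abs=1e-9)
    assert fit.slope_hz_s == pytest.approx(-0.5, abs=1e-12)
    assert fit.slope_norm == pytest.approx(-0.5, abs=1e-9)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)


def test_constant_series_has_zero_slope():
    fit = fit_mf_regression(_series(np.full(54, 90.0)))
    assert fit.slope_hz_s == pytest.approx(0.0, abs=1e-10)
    assert fit.slope_norm == pytest.approx(0.0, abs=1e-10)


def test_insufficient_points_flagged_unusable():
    excluded = np.ones(54, bool)
    excluded[:3] = False
    fit = fit_mf_regression(_series(np.full(54, 90.0), excluded=excluded))
    assert not fit.usable
    assert fit.n_points == 3


@given(
    slope=st.floats(-1.0, 1.0),
    intercept=st.floats(50.0, 200.0),
    shift=st.floats(-20.0, 20.0),
)
@settings(max_examples=50, deadline=None)
def test_slope_norm_identity_and_shift_equivariance(slope, intercept, shift):
    """slope_norm = 100*slope/intercept exactly; adding c Hz moves only the intercept."""
    t = 0.5 * np.arange(54)
    base = fit_mf_regression(_series(intercept + slope * t))
    assert base.slope_norm == pytest.approx(
        100.0 * base.slope_hz_s / base.intercept_hz, abs=0, rel=1e-15
    )
    shifted = fit_mf_regression(_series(intercept + shift + slope * t))
    assert shifted.intercept_hz - base.intercept_hz == pytest.approx(shift, abs=1e-8)
    assert shifted.slope_hz_s == pytest.approx(base.slope_hz_s, abs=1e-9)


def _fits(slopes, onset=100.0):
    return {
        label: FatigueFit(label, onset, slopes[i] * onset / 100.0, 54, 0.99)
        for i, label in enumerate(CANONICAL_CHANNELS)
    }


def test_summary_of_equal_slopes():
    s = summarize_fatigue(_fits([-0.2] * 6))
    assert s.all_mean_slope_norm == pytest.approx(-0.2)
    assert s.most_negative.slope_norm == pytest.approx(-0.2)
    assert s.n_usable == 6


def test_summary_mean_and_canonical_tie_break():
    # canonical order: L5_left, L5_right, L2_left, L2_right, L1_left, L1_right
    s = summarize_fatigue(_fits([-0.1, -0.2, -0.3, -0.1, -0.2, -0.3]))
    assert s.all_mean_slope_norm == pytest.approx(-0.2)
    assert s.most_negative.slope_norm == pytest.approx(-0.3)
    assert s.most_negative.electrode == "L2_left"  # first canonical -0.3


def test_summary_invariants_hold():
    fits = _fits([-0.1, -0.25, -0.3, -0.05, -0.2, -0.15])
    s = summarize_fatigue(fits)
    slopes = [f.slope_norm for f in fits.values()]
    assert s.most_negative.slope_norm <= min(slopes) + 1e-12
    assert min(slopes) <= s.all_mean_slope_norm <= max(slopes)


def test_summary_with_unusable_electrode_uses_remaining_five():
    fits = _fits([-0.1, -0.2, -0.3, -0.1, -0.2, -0.3])
    fits["L5_left"] = FatigueFit("L5_left", np.nan, np.nan, 2, np.nan, usable=False)
    s = summarize_fatigue(fits)
    assert s.n_usable == 5
    assert s.all_mean_slope_norm == pytest.approx(np.mean([-0.2, -0.3, -0.1, -0.2, -0.3]))


def test_slope_vs_zero_all_zero_not_significant():
    t, p, sig = slope_vs_zero_test(np.zeros(10))
    assert t == 0.0
    assert not sig


def test_slope_vs_zero_detects_true_fatigue():
    """N(-0.2, 0.05^2) slopes at n=50 are significant at p < 0.0025 in >= 99% of seeds."""
    rng = np.random.default_rng(1)
    hits = 0
    for _ in range(100):
        slopes = rng.normal(-0.2, 0.05, size=50)
        _, _, sig = slope_vs_zero_test(slopes)
        hits += sig
    assert hits >= 99


def test_slope_vs_zero_validation():
    with pytest.raises(ValueError, match="3"):
        slope_vs_zero_test(np.array([-0.1, -0.2]))
    with pytest.raises(ValueError, match="variance"):
        slope_vs_zero_test(np.full(5, -0.2))
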