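"""G-theory variance components, dependability and SEM."""

import numpy as np
import pandas as pd
import pytest

from semgfatigue import (
    CohortSpec,
    VarianceComponents,
    dependability,
    estimate_variance_components,
    generate_cohort,
)

NULL_MEANS = {("young", "male"): 0.0, ("young", "female"): 0.0,
              ("old", "male"): 0.0, ("old", "female"): 0.0}


def test_dependability_closed_forms():
    c = VarianceComponents(9.0, 0.2, 0.2, 0.2, 0.2, 0.2)
    rep = dependability(c, n_days=1, n_sides=1)
    assert rep.D == pytest.approx(0.9, abs=1e-12)
    assert rep.sem_abs == pytest.approx(1.0, abs=1e-12)

    perfect = dependability(VarianceComponents(4.0, 0, 0, 0, 0, 0))
    assert perfect.D == 1.0
    assert perfect.sem_abs == 0.0

    with pytest.raises(ValueError, match="undefined"):
        dependability(VarianceComponents(0, 0, 0, 0, 0, 0))


def test_absolute_error_variance_is_sum_of_terms():
    c = VarianceComponents(2.0, 0.3, 0.5, 0.7, 1.1, 1.3)
    for n_d, n_s in [(1, 1), (3, 1), (1, 2), (3, 2)]:
        rep = dependability(c, n_days=n_d, n_sides=n_s)
        expected = (
            c.day / n_d + c.side / n_s + c.subject_day / n_d
            + c.subject_side / n_s + c.residual / (n_d * n_s)
        )
        assert rep.absolute_error_variance == pytest.approx(expected, rel=1e-15)
        assert rep.sem_abs == pytest.approx(np.sqrt(expected), rel=1e-15)


def test_dependability_monotone_in_design_and_subject_variance():
    c = VarianceComponents(9.0, 0.2, 0.2, 0.2, 0.2, 0.2)
    d1 = dependability(c, 1, 1).D
    d3 = dependability(c, 3, 1).D
    d32 = dependability(c, 3, 2).D
    assert d1 < d3 < d32
    bigger = VarianceComponents(12.0, 0.2, 0.2, 0.2, 0.2, 0.2)
    assert dependability(bigger, 1, 1).D > d1


def test_pure_residual_structure_recovered():
    spec = CohortSpec(
        n_per_group=50,
        group_means=NULL_MEANS,
        variance_components=VarianceComponents(0, 0, 0, 0, 0, 4.0),
        n_days=3,
        seed=13,
    )
    comp = estimate_variance_components(generate_cohort(spec), value_col="slope_norm")
    assert comp.residual == pytest.approx(4.0, rel=0.15)
    for facet in ("subject", "day", "side", "subject_day", "subject_side"):
        # zero components estimate near zero relative to the residual scale
        assert getattr(comp, facet) < 0.15 * 4.0


def test_constant_within_subject_gives_only_subject_variance():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(40):
        v = rng.normal(0, 3)
        for d in (1, 2):
            for s in ("left", "right"):
                rows.append({"subject": f"S{i}", "day": d, "side": s, "value": v})
    comp = estimate_variance_components(pd.DataFrame(rows))
    assert comp.subject > 1.0
    for facet in ("day", "side", "subject_day", "subject_side", "residual"):
        assert getattr(comp, facet) == pytest.approx(0.0, abs=1e-9)


def test_component_recovery_and_D_on_programmed_cohorts():
    """Mean raw estimates over replicate cohorts recover each programmed
    component within +/-20% relative, and the estimated D is within 0.05
    of the closed form."""
    true = dict(subject=9.0, day=0.5, side=0.25, subject_day=0.5,
                subject_side=0.25, residual=0.5)
    spec = CohortSpec(
        n_per_group=125,  # 500 subjects over the four cells
        group_means=NULL_MEANS,
        variance_components=VarianceComponents(**true),
        n_days=3,
        seed=0,
    )
    sums = {k: 0.0 for k in true}
    n_reps = 200
    for r in range(n_reps):
        spec.seed = 10_000 + r
        comp = estimate_variance_components(generate_cohort(spec), value_col="slope_norm")
        for k in true:
            sums[k] += comp.raw_estimates[k]
    for k, v in true.items():
        assert abs(sums[k] / n_reps - v) / v < 0.20, k

    # D from a single cohort inherits the heavy-tailed day/side estimates
    # (2 and 1 df); the estimator's mean over replicate cohorts is the
    # stable quantity and sits within 0.05 of the closed form.
    D_true = 9.0 / (9.0 + 0.5 + 0.25 + 0.5 + 0.25 + 0.5)
    D_est = []
    for r in range(20):
        spec.seed = 60_000 + r
        comp = estimate_variance_components(
            generate_cohort(spec), value_col="slope_norm"
        )
        D_est.append(dependability(comp).D)
    assert abs(np.mean(D_est) - D_true) < 0.05


def test_reml_agrees_with_ems_on_balanced_data():
    spec = CohortSpec(
        n_per_group=8,
        group_means=NULL_MEANS,
        variance_components=VarianceComponents(4.0, 0.2, 0.2, 0.5, 0.3, 1.0),
        n_days=2,
        seed=5,
    )
    df = generate_cohort(spec)
    ems = estimate_variance_components(df, value_col="slope_norm", method="ems")
    reml = estimate_variance_components(df, value_col="slope_norm", method="reml")
    for facet in ("subject", "subject_day", "subject_side", "residual"):
        a, b = getattr(ems, facet), getattr(reml, facet)
        assert b == pytest.approx(a, rel=0.3, abs=0.3), facet


def test_unbalanced_design_uses_reml():
    spec = CohortSpec(n_per_group=6, group_means=NULL_MEANS, n_days=2, seed=2)
    df = generate_cohort(spec).iloc[:-3]  # drop observations -> unbalanced
    comp = estimate_variance_components(df, value_col="slope_norm", method="auto")
    assert comp.subject >= 0
    with pytest.raises(ValueError, match="balanced"):
        estimate_variance_components(df, value_col="slope_norm", method="ems")


def test_non_identifiable_design_rejected():
    df = pd.DataFrame(
        {"subject": ["a", "b"], "day": [1, 1], "side": ["left", "left"],
         "value": [1.0, 2.0]}
    )
    with pytest.raises(ValueError, match="identifiable"):
        estimate_variance_components(df)


def test_negative_component_construction_rejected():
    with pytest.raises(ValueError):
        VarianceComponents(-1.0, 0, 0, 0, 0, 0)
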