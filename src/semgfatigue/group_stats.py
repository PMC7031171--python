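"""Inferential layer: mixed-effects group comparisons and power simulation.

Each outcome (onset MF, normalised fatigue slope, imbalance) is modelled
over all three test days with a linear mixed model

    outcome ~ age * sex + test_day + (1 | subject)

using sum-to-zero contrasts so that Type-III-style Wald F tests of the
main effects and interaction are meaningful.  Main-comparison p values
are Bonferroni-adjusted for the study's family of five comparisons
(significance at p <= 0.01); post-hoc subgroup contrasts on estimated
marginal means (EMMs) are Holm-adjusted.  Cohen's d for model contrasts
is the EMM difference divided by the model-implied between-subject SD
(sqrt of subject-intercept variance plus residual variance); the
two-sample ``cohens_d`` uses the classic pooled SD.

Denominator degrees of freedom use a containment rule (between-subject
terms: number of subjects minus number of between cells; within-subject
terms: observations minus subjects minus term df); the rule is recorded
in the result so alternative approximations can be compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

BONFERRONI_FAMILY = 5  # 3 electrode pairs, 5 comparisons in the study design


@dataclass
class GroupModelResult:
    """Fitted mixed-model summary for one outcome."""

    outcome: str
    anova: pd.DataFrame  # term, F, df_num, df_den, p, p_bonferroni
    emm: pd.DataFrame  # age_group, sex, emm, se
    contrasts: pd.DataFrame  # contrast, estimate, se, p, p_holm, cohens_d
    sigma2_subject: float
    sigma2_residual: float
    n_subjects: int
    n_obs: int
    converged: bool
    ddf_method: str = "containment"


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Classic two-sample Cohen's d: mean difference over pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p values (monotone in the raw p values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _aggregate_sides(df: pd.DataFrame, outcome: str) -> pd.DataFrame:
    keys = ["subject", "age_group", "sex", "test_day"]
    extra = [c for c in ("side", "electrode", "level") if c in df.columns]
    if not extra:
        return df[keys + [outcome]].copy()
    return df.groupby(keys, as_index=False, observed=True)[outcome].mean()


def fit_group_model(
    df: pd.DataFrame, outcome: str, family_size: int = BONFERRONI_FAMILY
) -> GroupModelResult:
    """Mixed model of one outcome with age, sex and test-day fixed effects.

    ``df`` is a long table with ``subject``, ``age_group``, ``sex``,
    ``test_day`` and the outcome column (side/electrode replicates are
    averaged per subject and day first).  Requires at least two subjects
    per age x sex cell.
    """
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices

    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not in table")
    data = _aggregate_sides(df, outcome).dropna(subset=[outcome])
    cells = data.groupby(["age_group", "sex"], observed=True)["subject"].nunique()
    if (cells < 2).any() or len(cells) < 2:
        raise ValueError("need at least 2 subjects per age x sex cell")
    multi_day = data["test_day"].nunique() > 1
    day_term = " + C(test_day, Sum)" if multi_day else ""
    formula = f"{outcome} ~ C(age_group, Sum) * C(sex, Sum){day_term}"

    model = smf.mixedlm(formula, data, groups=data["subject"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs")
        except Exception:
            res = model.fit(reml=True)
    converged = bool(getattr(res, "converged", True))

    fe = res.fe_params
    cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
    design_info = res.model.data.design_info
    n_subjects = data["subject"].nunique()
    n_obs = len(data)
    sigma2_subject = float(np.asarray(res.cov_re)[0, 0])
    sigma2_residual = float(res.scale)

    # Type-III style Wald F per term, containment denominator df
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(fe))[sl]
        L = np.eye(len(fe))[idx]
        b = fe.to_numpy()[idx]
        V = L @ cov @ L.T
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        q = len(idx)
        if "test_day" in term:
            ddf = max(n_obs - n_subjects - q, 1)
        else:
            ddf = max(n_subjects - len(cells), 1)
        F = stat / q
        p = float(spstats.f.sf(F, q, ddf)) if np.isfinite(F) else np.nan
        rows.append(
            {
                "term": term,
                "F": F,
                "df_num": q,
                "df_den": ddf,
                "p": p,
                "p_bonferroni": min(1.0, p * family_size) if np.isfinite(p) else np.nan,
            }
        )
    anova = pd.DataFrame(rows)

    # EMMs over the age x sex grid, averaging over test-day levels
    ages = sorted(data["age_group"].unique())
    sexes = sorted(data["sex"].unique())
    days = sorted(data["test_day"].unique())
    emm_rows = []
    xvec = {}
    for age in ages:
        for sex in sexes:
            grid = pd.DataFrame(
                [{"age_group": age, "sex": sex, "test_day": d} for d in days]
            )
            X = np.asarray(build_design_matrices([design_info], grid)[0])
            x = X.mean(axis=0)
            xvec[(age, sex)] = x
            est = float(x @ fe.to_numpy())
            se = float(np.sqrt(x @ cov @ x))
            emm_rows.append(
                {"age_group": age, "sex": sex, "emm": est, "se": se}
            )
    emm = pd.DataFrame(emm_rows)

    sd_between = float(np.sqrt(sigma2_subject + sigma2_residual))
    ddf_between = max(n_subjects - len(cells), 1)

    def _contrast(name: str, xa: np.ndarray, xb: np.ndarray) -> dict:
        dvec = xa - xb
        est = float(dvec @ fe.to_numpy())
        se = float(np.sqrt(dvec @ cov @ dvec))
        tval = est / se if se > 0 else np.nan
        p = float(2 * spstats.t.sf(abs(tval), ddf_between)) if np.isfinite(tval) else np.nan
        d = est / sd_between if sd_between > 0 else np.nan
        return {"contrast": name, "estimate": est, "se": se, "p": p, "cohens_d": d}

    contrast_rows = []
    if len(ages) == 2 and len(sexes) == 2:
        a0, a1 = "young", "old"
        s0, s1 = "male", "female"
        # main contrasts averaged over the other factor
        x_age0 = 0.5 * (xvec[(a0, s0)] + xvec[(a0, s1)])
        x_age1 = 0.5 * (xvec[(a1, s0)] + xvec[(a1, s1)])
        x_sex0 = 0.5 * (xvec[(a0, s0)] + xvec[(a1, s0)])
        x_sex1 = 0.5 * (xvec[(a0, s1)] + xvec[(a1, s1)])
        contrast_rows.append(_contrast("age: young - old", x_age0, x_age1))
        contrast_rows.append(_contrast("sex: male - female", x_sex0, x_sex1))
        posthoc = [
            _contrast("age | male", xvec[(a0, s0)], xvec[(a1, s0)]),
            _contrast("age | female", xvec[(a0, s1)], xvec[(a1, s1)]),
            _contrast("sex | young", xvec[(a0, s0)], xvec[(a0, s1)]),
            _contrast("sex | old", xvec[(a1, s0)], xvec[(a1, s1)]),
        ]
        adj = holm_adjust([c["p"] for c in posthoc])
        for c, pa in zip(posthoc, adj):
            c["p_holm"] = float(pa)
        contrast_rows.extend(posthoc)
    contrasts = pd.DataFrame(contrast_rows)
    if "p_holm" not in contrasts.columns and len(contrasts):
        contrasts["p_holm"] = np.nan

    return GroupModelResult(
        outcome=outcome,
        anova=anova,
        emm=emm,
        contrasts=contrasts,
        sigma2_subject=sigma2_subject,
        sigma2_residual=sigma2_residual,
        n_subjects=n_subjects,
        n_obs=n_obs,
        converged=converged,
    )


@dataclass
class PowerResult:
    """Outcome of the Monte-Carlo sample-size search."""

    required_n: int | None  # per group, before attrition inflation
    required_n_inflated: int | None  # after attrition inflation
    table: pd.DataFrame  # n, comparison, power
    alpha: float
    target_power: float
    attrition_fraction: float


def power_simulation(
    effect_sizes: dict[str, float],
    alpha: float = 0.01,
    target_power: float = 0.9,
    attrition_fraction: float = 0.10,
    n_grid: list[int] | None = None,
    n_sims: int = 400,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo sample-size estimate for a family of group comparisons.

    For every n in ``n_grid``, two groups of n subject-level values
    (unit SD, mean shifted by the comparison's Cohen's d) are simulated
    ``n_sims`` times and compared with a two-sided two-sample t-test at
    ``alpha``; power is the rejection fraction.  The returned required n
    is the smallest grid value at which every comparison reaches
    ``target_power``, inflated for the expected ``attrition_fraction``
    of lost recordings and rounded up.
    """
    if not 0 < alpha < 1 or not 0 < target_power < 1:
        raise ValueError("alpha and target_power must lie in (0, 1)")
    if not 0 <= attrition_fraction < 1:
        raise ValueError("attrition_fraction must lie in [0, 1)")
    n_grid = sorted(n_grid or range(20, 201, 10))
    if any(n < 2 for n in n_grid):
        raise ValueError("group sizes must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    power_at: dict[int, dict[str, float]] = {n: {} for n in n_grid}
    for name, d in effect_sizes.items():
        for n in n_grid:
            a = rng.standard_normal((n_sims, n)) + d
            b = rng.standard_normal((n_sims, n))
            _, p = spstats.ttest_ind(a, b, axis=1)
            power = float(np.mean(p < alpha))
            power_at[n][name] = power
            rows.append({"n": n, "comparison": name, "power": power})
    table = pd.DataFrame(rows)
    required = None
    for n in n_grid:
        if all(power_at[n][c] >= target_power for c in effect_sizes):
            required = n
            break
    inflated = (
        int(np.ceil(required / (1.0 - attrition_fraction))) if required else None
    )
    return PowerResult(
        required_n=required,
        required_n_inflated=inflated,
        table=table,
        alpha=alpha,
        target_power=target_power,
        attrition_fraction=attrition_fraction,
    )
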