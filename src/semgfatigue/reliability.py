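"""Generalizability-theory reliability of the fatigue measures.

The measurement model is a fully crossed random-effects design

    value[p, d, s] = mu + p + d + s + pd + ps + e

with subject (p), day (d) and side (s) main facets, the subject x day and
subject x side interactions, and a residual that absorbs everything else.
Variance components feed the single-observation dependability coefficient

    D = sigma2_p / (sigma2_p + absolute error variance)

where the absolute error variance for a D-study with n_d days and n_s
sides is sigma2_d/n_d + sigma2_s/n_s + sigma2_pd/n_d + sigma2_ps/n_s +
sigma2_e/(n_d*n_s), and the absolute SEM is its square root.

For balanced complete designs the components are estimated by the
closed-form expected-mean-squares (EMS) ANOVA solution, which coincides
with REML whenever all estimates are non-negative; unbalanced tables fall
back to REML via statsmodels' mixed-model variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FACETS = ("subject", "day", "side", "subject_day", "subject_side", "residual")


@dataclass
class VarianceComponents:
    """Estimated variance components (units of the metric squared)."""

    subject: float
    day: float
    side: float
    subject_day: float
    subject_side: float
    residual: float
    truncated: tuple[str, ...] = ()  # facets whose estimate was negative
    #: un-truncated estimates; averaging these across replicate designs is
    #: unbiased, whereas the truncated values are biased upward for
    #: components estimated on few degrees of freedom
    raw_estimates: dict | None = None

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in FACETS}

    def __post_init__(self) -> None:
        negatives = [f for f in FACETS if getattr(self, f) < 0]
        if negatives:
            raise ValueError(f"variance components must be >= 0: {negatives}")


@dataclass
class ReliabilityReport:
    """Dependability coefficient and absolute SEM for a D-study design."""

    components: VarianceComponents
    D: float
    sem_abs: float
    absolute_error_variance: float
    n_days: int
    n_sides: int


def _truncate(raw: dict[str, float]) -> VarianceComponents:
    truncated = tuple(f for f, v in raw.items() if v < 0)
    clipped = {f: max(0.0, v) for f, v in raw.items()}
    return VarianceComponents(**clipped, truncated=truncated, raw_estimates=dict(raw))


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["subject", "day", "side"], observed=True).size()
    n_p = df["subject"].nunique()
    n_d = df["day"].nunique()
    n_s = df["side"].nunique()
    return len(counts) == n_p * n_d * n_s and bool((counts == 1).all())


def _ems_components(df: pd.DataFrame, value_col: str) -> VarianceComponents:
    """Closed-form EMS solution on a balanced complete p x d x s table."""
    table = df.pivot_table(
        index="subject", columns=["day", "side"], values=value_col, observed=True
    )
    subjects = table.index
    days = sorted(df["day"].unique())
    sides = sorted(df["side"].unique())
    n_p, n_d, n_s = len(subjects), len(days), len(sides)
    y = np.empty((n_p, n_d, n_s))
    for j, d in enumerate(days):
        for k, s in enumerate(sides):
            y[:, j, k] = table[(d, s)].to_numpy()

    grand = y.mean()
    m_p = y.mean(axis=(1, 2))
    m_d = y.mean(axis=(0, 2))
    m_s = y.mean(axis=(0, 1))
    m_pd = y.mean(axis=2)
    m_ps = y.mean(axis=1)

    ss_p = n_d * n_s * np.sum((m_p - grand) ** 2)
    ss_d = n_p * n_s * np.sum((m_d - grand) ** 2)
    ss_s = n_p * n_d * np.sum((m_s - grand) ** 2)
    ss_pd = n_s * np.sum((m_pd - m_p[:, None] - m_d[None, :] + grand) ** 2)
    ss_ps = n_d * np.sum((m_ps - m_p[:, None] - m_s[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_e = ss_tot - ss_p - ss_d - ss_s - ss_pd - ss_ps

    df_p, df_d, df_s = n_p - 1, n_d - 1, n_s - 1
    df_pd, df_ps = df_p * df_d, df_p * df_s
    df_e = n_p * n_d * n_s - 1 - df_p - df_d - df_s - df_pd - df_ps
    ms = {
        "p": ss_p / df_p,
        "d": ss_d / df_d if df_d else 0.0,
        "s": ss_s / df_s if df_s else 0.0,
        "pd": ss_pd / df_pd if df_pd else 0.0,
        "ps": ss_ps / df_ps if df_ps else 0.0,
        "e": ss_e / df_e if df_e > 0 else 0.0,
    }
    raw = {
        "residual": ms["e"],
        "subject_day": (ms["pd"] - ms["e"]) / n_s,
        "subject_side": (ms["ps"] - ms["e"]) / n_d,
        "day": (ms["d"] - ms["pd"]) / (n_p * n_s),
        "side": (ms["s"] - ms["ps"]) / (n_p * n_d),
        "subject": (ms["p"] - ms["pd"] - ms["ps"] + ms["e"]) / (n_d * n_s),
    }
    return _truncate(raw)


def _reml_components(df: pd.DataFrame, value_col: str) -> VarianceComponents:
    """REML via a variance-components mixed model (crossed facets)."""
    import statsmodels.formula.api as smf

    data = df.copy()
    data["_one"] = 1
    vc = {
        "subject": "0 + C(subject)",
        "day": "0 + C(day)",
        "side": "0 + C(side)",
        "subject_day": "0 + C(subject):C(day)",
        "subject_side": "0 + C(subject):C(side)",
    }
    model = smf.mixedlm(
        f"{value_col} ~ 1", data, groups="_one", vc_formula=vc, re_formula="0"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    est = dict(zip(model.exog_vc.names, res.vcomp))
    raw = {
        "subject": float(est["subject"]),
        "day": float(est["day"]),
        "side": float(est["side"]),
        "subject_day": float(est["subject_day"]),
        "subject_side": float(est["subject_side"]),
        "residual": float(res.scale),
    }
    return _truncate(raw)


def estimate_variance_components(
    df: pd.DataFrame, value_col: str = "value", method: str = "auto"
) -> VarianceComponents:
    """Variance components of the crossed subject x day x side model.

    Parameters
    ----------
    df
        Long table with columns ``subject``, ``day``, ``side`` and the
        metric column.
    method
        ``"ems"`` (closed form, balanced designs only), ``"reml"``, or
        ``"auto"`` (EMS when the design is balanced and complete, REML
        otherwise).  Negative estimates are truncated to zero and listed
        in ``VarianceComponents.truncated``.
    """
    for col in ("subject", "day", "side", value_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    n_d = df["day"].nunique()
    n_s = df["side"].nunique()
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if n_d < 2 and n_s < 2:
        raise ValueError(
            "non-identifiable design: need at least 2 days or 2 sides to "
            "separate error facets"
        )
    if method == "auto":
        method = "ems" if _is_balanced(df) else "reml"
    if method == "ems":
        if not _is_balanced(df):
            raise ValueError("EMS estimation requires a balanced complete design")
        return _ems_components(df, value_col)
    if method == "reml":
        return _reml_components(df, value_col)
    raise ValueError(f"unknown method {method!r}")


def dependability(
    components: VarianceComponents, n_days: int = 1, n_sides: int = 1
) -> ReliabilityReport:
    """Dependability coefficient D and absolute SEM for a D-study design.

    ``n_days``/``n_sides`` are the numbers of observations averaged in
    the decision study; the default (1, 1) is the single-observation
    dependability.
    """
    if n_days < 1 or n_sides < 1:
        raise ValueError("n_days and n_sides must be >= 1")
    c = components
    total = sum(c.as_dict().values())
    if total == 0:
        raise ValueError("all variance components are zero: D undefined")
    abs_err = (
        c.day / n_days
        + c.side / n_sides
        + c.subject_day / n_days
        + c.subject_side / n_sides
        + c.residual / (n_days * n_sides)
    )
    denom = c.subject + abs_err
    if denom == 0:
        raise ValueError("zero subject and error variance: D undefined")
    return ReliabilityReport(
        components=c,
        D=c.subject / denom,
        sem_abs=float(np.sqrt(abs_err)),
        absolute_error_variance=abs_err,
        n_days=n_days,
        n_sides=n_sides,
    )
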