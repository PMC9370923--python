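"""Cohort-level statistics: group comparisons, covariate-adjusted T2DM effects,
and Pearson screening of gait variables against cognitive scores.

Group comparisons follow the normality-gated convention: Shapiro-Wilk on each
group at alpha = 0.05 selects an unpaired t-test (both normal) or a
Mann-Whitney U test.  Adjusted effects are ordinary least squares of the gait
variable on a group indicator plus age, sex, BMI and education.  Screening
computes pooled-cohort Pearson r per (gait variable x cognitive score) cell
and selects cells with |r| >= 0.3 (inclusive); no multiple-testing correction
is applied and raw r is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GaitcogError, InvalidParameterError

SCREEN_THRESHOLD = 0.3
NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    test: str  # "t" | "mannwhitney"
    statistic: float
    p_value: float
    shapiro_p: tuple[float, float]


@dataclass
class AdjustedEffect:
    """Group (T2DM) coefficient from a covariate-adjusted linear model."""

    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def compare_groups(
    a: np.ndarray, b: np.ndarray, alpha: float = NORMALITY_ALPHA
) -> GroupComparison:
    """Two-sided group comparison with a Shapiro-Wilk-gated test choice."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InvalidParameterError("need >= 3 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise GaitcogError("degenerate variance in both groups")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.var(x) == 0:
            return 0.0  # constant sample: treat as non-normal
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa >= alpha and pb >= alpha:
        res = stats.ttest_ind(a, b)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), (pa, pb))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("mannwhitney", float(res.statistic), float(res.pvalue), (pa, pb))


def compare_groups_frame(
    cohort: pd.DataFrame, variable: str, group_col: str = "group"
) -> GroupComparison:
    grps = cohort[group_col].unique()
    if len(grps) != 2:
        raise InvalidParameterError("expected exactly two groups")
    a = cohort.loc[cohort[group_col] == grps[0], variable].dropna().to_numpy()
    b = cohort.loc[cohort[group_col] == grps[1], variable].dropna().to_numpy()
    return compare_groups(a, b)


def adjusted_effect(
    cohort: pd.DataFrame,
    gait_var: str,
    group_col: str = "group",
    reference_group: str = "control",
    covariates: tuple[str, ...] = ("age_yr", "sex", "bmi", "education_yr"),
) -> AdjustedEffect:
    """OLS of ``gait_var`` on group + covariates; returns the group coefficient."""
    import statsmodels.api as sm

    df = cohort[[gait_var, group_col, *covariates]].dropna()
    y = df[gait_var].to_numpy(dtype=float)
    cols = {"const": np.ones(len(df))}
    gvals = df[group_col].to_numpy()
    other = [g for g in pd.unique(gvals) if g != reference_group]
    if len(other) != 1:
        raise InvalidParameterError("group column must have the reference plus one other level")
    cols["group"] = (gvals == other[0]).astype(float)
    for c in covariates:
        v = df[c]
        if v.dtype == object or str(v.dtype).startswith("category"):
            levels = pd.unique(v)
            if len(levels) < 2:
                raise GaitcogError(f"covariate {c} is constant")
            for lev in levels[1:]:
                cols[f"{c}[{lev}]"] = (v == lev).astype(float).to_numpy()
        else:
            cols[c] = v.to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise GaitcogError("collinear design matrix in adjusted model")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["group"]
    return AdjustedEffect(
        beta=float(fit.params["group"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["group"]),
        n=len(df),
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation via the covariance formula (complete pairs only)."""
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float((xc @ yc) / denom)


def screen_correlations(
    cohort: pd.DataFrame,
    gait_vars: list[str],
    cognitive_vars: list[str],
    threshold: float = SCREEN_THRESHOLD,
) -> pd.DataFrame:
    """Pooled-cohort Pearson screening; one row per (gait, cognitive) cell.

    Cells with an undefined r (constant column or < 3 complete pairs) carry
    NaN and are never selected.
    """
    rows = []
    for gv in gait_vars:
        x = cohort[gv].to_numpy(dtype=float)
        for cv in cognitive_vars:
            r = pearson_r(x, cohort[cv].to_numpy(dtype=float))
            rows.append(
                {
                    "gait_variable": gv,
                    "cognitive_score": cv,
                    "r": r,
                    "selected": bool(np.isfinite(r) and abs(r) >= threshold),
                }
            )
    return pd.DataFrame(rows)


def correlation_matrix(screening: pd.DataFrame) -> pd.DataFrame:
    """Pivot a screening table to a gait x cognition matrix of r values."""
    return screening.pivot(index="gait_variable", columns="cognitive_score", values="r")


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Write a heat map of the screening matrix (matplotlib, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * matrix.shape[1], 1 + 0.3 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
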