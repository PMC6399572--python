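"""Between-arm comparisons: two-sample t tests, chi-square tests on
proportions, and cluster-aware binary comparisons via generalized estimating
equations (exchangeable working correlation, robust variance).

The estimating-equation machinery is delegated to vetted implementations
(scipy, statsmodels) behind a uniform :class:`ComparisonResult` contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "ComparisonResult",
    "SmallCellWarning",
    "chi_square_2xk",
    "descriptive_table",
    "gee_binary",
    "two_sample_t",
    "two_sample_t_from_stats",
]


class SmallCellWarning(UserWarning):
    """Chi-square expected cell count below 5."""


class SeparationWarning(UserWarning):
    """Binary outcome constant within a group; GEE estimates unreliable."""


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    df: float | None = None
    n_clusters: int | None = None
    working_correlation: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p_value out of [0, 1]: {self.p_value}")


def _degenerate(x: np.ndarray, y: np.ndarray) -> bool:
    return x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean()


def two_sample_t(x, y, equal_var: bool = True) -> ComparisonResult:
    """Two-sample t test; pooled variance by default, Welch via flag.

    Degenerate input (zero variance in both groups, equal means) returns the
    p = 1 convention rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    method = "t_test" if equal_var else "welch_t_test"
    if _degenerate(x, y):
        return ComparisonResult(0.0, 1.0, method, (x.size, y.size),
                                df=float(x.size + y.size - 2))
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        n_per_group=(int(x.size), int(y.size)),
        df=float(res.df),
    )


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> ComparisonResult:
    """Summary-statistics entry point; equivalent to :func:`two_sample_t` on
    raw data with the same moments."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs at least 2 observations")
    if sd1 == 0 and sd2 == 0 and mean1 == mean2:
        return ComparisonResult(0.0, 1.0, "t_test" if equal_var else "welch_t_test",
                                (n1, n2), df=float(n1 + n2 - 2))
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="t_test" if equal_var else "welch_t_test",
        n_per_group=(int(n1), int(n2)),
        df=df,
    )


def chi_square_2xk(counts) -> ComparisonResult:
    """Pearson chi-square on a 2 x k contingency table, no continuity
    correction. Warns (``SmallCellWarning``) when any expected count < 5."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ParameterError(f"expected a 2 x k table, got shape {table.shape}")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ParameterError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ParameterError("zero-margin row or column")
    stat, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        warnings.warn("expected cell count below 5; chi-square approximation "
                      "may be poor", SmallCellWarning, stacklevel=2)
    return ComparisonResult(
        statistic=float(stat),
        p_value=float(p),
        method="chi_square",
        n_per_group=tuple(int(v) for v in table.sum(axis=1)),
        df=float(dof),
    )


def gee_binary(
    outcome,
    group,
    cluster,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> ComparisonResult:
    """Binary-outcome group comparison controlling for within-cluster
    dependence: logit link, exchangeable working correlation, robust
    (sandwich) variance. The p-value is the Wald test of the group effect.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({
        "y": np.asarray(outcome, dtype=float),
        "g": np.asarray(group),
        "cluster": np.asarray(cluster),
    }).dropna()
    groups = sorted(df["g"].unique())
    if len(groups) != 2:
        raise ParameterError(f"expected exactly 2 groups, got {groups}")
    for g in groups:
        if df.loc[df["g"] == g, "cluster"].nunique() < 2:
            raise ParameterError("need at least 2 clusters per group")
        mean = df.loc[df["g"] == g, "y"].mean()
        if mean in (0.0, 1.0):
            warnings.warn(f"outcome constant within group {g!r}; estimates are "
                          "unreliable (separation)", SeparationWarning, stacklevel=2)
    df["x"] = (df["g"] == groups[1]).astype(float)
    exog = sm.add_constant(df[["x"]])
    model = sm.GEE(
        df["y"], exog, groups=df["cluster"],
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(maxiter=maxiter, ctol=tol)
    converged = bool(getattr(result, "converged", True))
    if not converged:
        warnings.warn("GEE did not converge within the iteration budget",
                      UserWarning, stacklevel=2)
    rho = float(np.atleast_2d(model.cov_struct.dep_params)[0, 0]) \
        if np.ndim(model.cov_struct.dep_params) else float(model.cov_struct.dep_params)
    z = float(result.tvalues["x"])
    return ComparisonResult(
        statistic=z,
        p_value=float(result.pvalues["x"]),
        method="gee_exchangeable_logit",
        n_per_group=tuple(int((df["g"] == g).sum()) for g in groups),
        n_clusters=int(df["cluster"].nunique()),
        working_correlation=rho,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Descriptive reporting
# ---------------------------------------------------------------------------


def _fmt_mean_sd(values: pd.Series) -> str:
    v = values.dropna()
    return f"{v.mean():.1f} ({v.std(ddof=1):.1f})" if len(v) else "-"


def _fmt_n_pct(flags: pd.Series) -> str:
    v = flags.dropna().astype(bool)
    return f"{int(v.sum())} ({100 * v.mean():.1f}%)" if len(v) else "-"


def descriptive_table(patients: pd.DataFrame, consultations: pd.DataFrame) -> pd.DataFrame:
    """Arm-by-arm 'mean (SD)' / 'n (%)' descriptives with p-value columns,
    mirroring the usual baseline/travel table layout."""
    rows = []
    arms = ("standard", "telemedicine")
    pat = {a: patients[patients["arm"] == a] for a in arms}
    con = {a: consultations[consultations["arm"] == a] for a in arms}

    def num_row(label, series_by_arm):
        x, y = (series_by_arm[a].dropna() for a in arms)
        p = two_sample_t(x, y).p_value if len(x) > 1 and len(y) > 1 else np.nan
        rows.append({"characteristic": label,
                     "standard": _fmt_mean_sd(series_by_arm[arms[0]]),
                     "telemedicine": _fmt_mean_sd(series_by_arm[arms[1]]),
                     "p_value": p, "method": "t_test"})

    def flag_row(label, flags_by_arm):
        counts = []
        for a in arms:
            v = flags_by_arm[a].dropna().astype(bool)
            counts.append([int(v.sum()), int((~v).sum())])
        table = np.array(counts)
        p = np.nan
        if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SmallCellWarning)
                p = chi_square_2xk(table).p_value
        rows.append({"characteristic": label,
                     "standard": _fmt_n_pct(flags_by_arm[arms[0]]),
                     "telemedicine": _fmt_n_pct(flags_by_arm[arms[1]]),
                     "p_value": p, "method": "chi_square"})

    num_row("age_years", {a: pat[a]["age"] for a in arms})
    flag_row("male", {a: pat[a]["sex"] == "male" for a in arms})
    num_row("travel_time_one_way_min", {a: con[a]["travel_time_min"] for a in arms})
    num_row("travel_distance_one_way_km", {a: con[a]["distance_km"] for a in arms})
    flag_row("companion", {a: con[a]["companion"].astype(bool) for a in arms})
    flag_row("extra_transport", {a: con[a]["extra_transport"].astype(bool) for a in arms})
    for mode in ("private_car", "taxi", "bus"):
        flag_row(f"{mode}_as_main_transport",
                 {a: con[a]["main_mode"].dropna() == mode for a in arms})
    return pd.DataFrame(rows)
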