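"""Cohort statistics: rank-sum, FDR, KS, OLS and mixed-design rm-ANOVA.

Thin, contract-checked wrappers over scipy/statsmodels/pingouin with the
conventions used throughout the cohort analyses: two-sided tests by default,
exact rank-sum p-values for small untied samples, Benjamini–Hochberg
adjustment for per-pulse comparisons, and a mixed-design (between ×
repeated) ANOVA for recovery-delay and pulse-train profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_rank_sum(x, y, two_sided: bool = True) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact p-value when both samples have ≤12 observations and no ties;
    otherwise a tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 12 and y.size <= 12 and not has_ties) else "asymptotic"
    alt = "two-sided" if two_sided else "greater"
    res = sps.mannwhitneyu(x, y, alternative=alt, method=method)
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        f"wilcoxon-rank-sum ({method})",
        (x.size, y.size),
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), "ks-two-sample", (x.size, y.size))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """OLS of y on x with a t-test on the slope; needs n ≥ 3 and var(x) > 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
        int(x.size),
    )


def two_way_rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
) -> pd.DataFrame:
    """Mixed-design ANOVA: between-subject factor × repeated measurements.

    ``data`` is long-form; subjects with incomplete repeated measurements
    are dropped listwise.  Returns per-effect F and p for the between
    factor, the within factor and their interaction (no sphericity
    correction by default, matching the original analysis).
    """
    import pingouin as pg

    df = data[[dv, within, subject, between]].dropna()
    n_levels = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == n_levels].index
    df = df[df[subject].isin(complete)]
    group_sizes = df.groupby(between)[subject].nunique()
    if (group_sizes < 2).any():
        raise ValueError("each between-group needs at least 2 complete subjects")
    if np.allclose(df[dv].to_numpy(), df[dv].iloc[0]):
        raise ValueError("constant response; F undefined")
    res = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject, between=between)
    out = res.rename(columns={"p_unc": "p", "Source": "effect"})[
        ["effect", "F", "p", "DF1", "DF2"]
    ].copy()
    out["effect"] = out["effect"].map(
        {between: "between", within: "within", "Interaction": "interaction"}
    )
    return out
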