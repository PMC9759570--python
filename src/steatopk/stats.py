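"""Group-difference and correlation statistics for the feature table.

One-way ANOVA with Tukey's multiple-comparisons test assesses the effect
of the dietary induction protocol on TG, steatosis surfaces, CYP activity
and AUCs; pairwise Pearson correlations (with Fisher-z 95% CIs and
two-tailed p values) are assembled into a correlation matrix whose
off-diagonal p values are jointly Benjamini-Hochberg adjusted and
annotated with significance stars at 0.05 / 0.01 / 0.001.

The correlation-strength vocabulary follows the magnitude of r:
|r| >= 0.7 strong, [0.5, 0.7) moderate, [0.3, 0.5) fair, < 0.3
negligible, irrespective of sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "TukeyComparison",
    "CorrelationResult",
    "CorrelationMatrixResult",
    "one_way_anova",
    "tukey_hsd",
    "pearson_with_ci",
    "classify_r",
    "bh_adjust",
    "correlation_matrix",
    "significance_stars",
]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class TukeyComparison:
    group_i: int
    group_j: int
    mean_diff: float
    p_adj: float
    ci_lower: float
    ci_upper: float
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci95: tuple[float, float]
    p_two_tailed: float
    strength_label: str


@dataclass
class CorrelationMatrixResult:
    feature_names: list[str]
    r: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    stars: np.ndarray  # array of strings '', '*', '**', '***'

    def to_frame(self, which: str = "r") -> pd.DataFrame:
        arr = {"r": self.r, "p_raw": self.p_raw,
               "p_adjusted": self.p_adjusted, "stars": self.stars}[which]
        return pd.DataFrame(arr, index=self.feature_names, columns=self.feature_names)


def _check_groups(groups) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError("every group needs at least 2 values")
        out.append(arr)
    return out


def one_way_anova(groups) -> AnovaResult:
    """Ordinary (equal-variance) one-way ANOVA across the diet groups."""
    gs = _check_groups(groups)
    f, p = sps.f_oneway(*gs)
    k = len(gs)
    n = sum(g.size for g in gs)
    if np.isnan(f):  # all values identical in every group
        f, p = 0.0, 1.0
    return AnovaResult(f_stat=float(f), df_between=k - 1,
                       df_within=n - k, p_value=float(p))


def tukey_hsd(groups, alpha: float = 0.05) -> list[TukeyComparison]:
    """Tukey's HSD pairwise comparisons (studentized-range adjusted p)."""
    gs = _check_groups(groups)
    res = sps.tukey_hsd(*gs)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    out = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            p = float(res.pvalue[i, j])
            out.append(TukeyComparison(
                group_i=i, group_j=j,
                mean_diff=float(np.mean(gs[i]) - np.mean(gs[j])),
                p_adj=p,
                ci_lower=float(ci.low[i, j]),
                ci_upper=float(ci.high[i, j]),
                significant=p < alpha,
            ))
    return out


def classify_r(r: float) -> str:
    """Strength label for a correlation coefficient by magnitude."""
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    m = abs(r)
    if m >= 0.7:
        return "strong"
    if m >= 0.5:
        return "moderate"
    if m >= 0.3:
        return "fair"
    return "negligible"


def pearson_with_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r with Fisher-z confidence interval and two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=level)
    r = float(res.statistic)
    return CorrelationResult(r=r, ci95=(float(ci.low), float(ci.high)),
                             p_two_tailed=float(res.pvalue),
                             strength_label=classify_r(r))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p.reshape(-1), method="fdr_bh")[1].reshape(p.shape)


def significance_stars(p: float) -> str:
    """Star annotation at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(features: pd.DataFrame) -> CorrelationMatrixResult:
    """All-pairs Pearson correlation with joint BH adjustment and stars.

    Non-numeric columns and columns without variance are excluded (with a
    warning for the latter).  The off-diagonal upper-triangle p values are
    adjusted jointly, mirroring a matrix-wide multiple-testing correction.
    """
    num = features.select_dtypes(include=[np.number]).dropna()
    if num.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    keep = []
    for col in num.columns:
        if np.var(num[col].to_numpy()) == 0:
            warnings.warn(f"feature {col!r} has zero variance; excluded")
        else:
            keep.append(col)
    num = num[keep]
    names = list(num.columns)
    k = len(names)
    r = np.eye(k)
    p_raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = sps.pearsonr(num.iloc[:, i], num.iloc[:, j])
            r[i, j] = r[j, i] = float(res.statistic)
            p_raw[i, j] = p_raw[j, i] = float(res.pvalue)
    iu = np.triu_indices(k, 1)
    p_adj = np.zeros((k, k))
    if iu[0].size:
        adj = bh_adjust(p_raw[iu])
        p_adj[iu] = adj
        p_adj.T[iu] = adj
    stars = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            stars[i, j] = "" if i == j else significance_stars(p_adj[i, j])
    return CorrelationMatrixResult(feature_names=names, r=r, p_raw=p_raw,
                                   p_adjusted=p_adj, stars=stars)
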