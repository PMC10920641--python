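"""Group-comparison and clinical-association statistics.

Demographic and clinical variables are compared between diagnostic groups
with Welch's unequal-variance t-test (computable from published n/mean/SD
summaries alone) and Cohen's d; sex-by-group independence uses a
continuity-corrected chi-square. The pooled SVM decision scores are
correlated (Pearson) against the clinical score battery — ADOS-2 calibrated
severity scores (social affect, restricted/repetitive behaviors, total) and
ADI-R domains A/B/C — with Benjamini-Hochberg FDR across the battery;
family-wise adjustment of the group tests uses Bonferroni-Holm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (n, mean, sd) of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        return cls(len(x), float(x.mean()), float(x.std(ddof=1)))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    d: float


def welch_t(g1: GroupSummary, g2: GroupSummary, d_variant: str = "rms") -> WelchResult:
    """Welch's unequal-variance t-test from group summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite df and
    a two-sided p. The attached effect size is Cohen's d (see
    :func:`cohens_d` for the variants).
    """
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    se2 = v1 + v2
    if se2 == 0.0:
        raise ValueError("zero pooled standard error")
    t = (g1.mean - g2.mean) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=t, df=df, p=float(p), d=cohens_d(g1, g2, d_variant))


def welch_t_from_raw(
    x1: Sequence[float], x2: Sequence[float], d_variant: str = "rms"
) -> WelchResult:
    """Welch test from raw values (summaries computed internally)."""
    return welch_t(GroupSummary.from_values(x1), GroupSummary.from_values(x2),
                   d_variant)


def cohens_d(g1: GroupSummary, g2: GroupSummary, variant: str = "rms") -> float:
    """Cohen's d standardized mean difference.

    ``"rms"`` (default) divides by the unweighted root-mean of the two
    variances, sqrt((s1^2 + s2^2)/2); ``"pooled"`` uses the n-weighted
    pooled SD.
    """
    if variant == "rms":
        denom = math.sqrt((g1.sd**2 + g2.sd**2) / 2.0)
    elif variant == "pooled":
        denom = math.sqrt(
            ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
        )
    else:
        raise ValueError("variant must be 'rms' or 'pooled'")
    if denom == 0.0:
        raise ValueError("zero variance in both groups")
    return (g1.mean - g2.mean) / denom


def chi2_yates(table: np.ndarray) -> tuple[float, int, float]:
    """Continuity-corrected chi-square test of independence on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), int(dof), float(p)


#: Canonical clinical battery column order.
CLINICAL_SCALES = (
    "ados_css_sa", "ados_css_rrb", "ados_css_total",
    "adir_a", "adir_b", "adir_c",
)


def pearson_with_fdr(
    scores: pd.Series,
    clinical: pd.DataFrame,
    scales: Sequence[str] = CLINICAL_SCALES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations of decision scores with the clinical battery.

    Rows with a missing value on a scale are dropped for that scale only;
    two-sided p-values are Benjamini-Hochberg adjusted across the battery.
    Returns a table (scale, n, r, p, q, significant).
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for scale in scales:
        pair = pd.concat([scores, clinical[scale]], axis=1, join="inner").dropna()
        if len(pair) < 3:
            raise ValueError(f"fewer than 3 complete pairs for scale {scale!r}")
        x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"constant input vector for scale {scale!r}")
        r, p = stats.pearsonr(x, y)
        rows.append({"scale": scale, "n": len(pair), "r": float(r), "p": float(p)})
    df = pd.DataFrame(rows).set_index("scale")
    rej, q, *_ = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    df["q"] = q
    df["significant"] = rej
    return df


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def group_comparisons(
    metadata: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "label",
    groups: tuple[str, str] = ("ASD", "CC"),
    holm: bool = True,
) -> pd.DataFrame:
    """Welch-compare each variable between two groups, Holm-adjusting p.

    Emits one row per variable with group n/mean/SD, t, df, raw and
    adjusted p, and Cohen's d — the layout of a demographic group table.
    """
    g1 = metadata[metadata[group_col] == groups[0]]
    g2 = metadata[metadata[group_col] == groups[1]]
    rows = []
    for var in variables:
        s1 = GroupSummary.from_values(g1[var])
        s2 = GroupSummary.from_values(g2[var])
        res = welch_t(s1, s2)
        rows.append({
            "variable": var,
            "n1": s1.n, "mean1": s1.mean, "sd1": s1.sd,
            "n2": s2.n, "mean2": s2.mean, "sd2": s2.sd,
            "t": res.t, "df": res.df, "p": res.p, "d": res.d,
        })
    df = pd.DataFrame(rows).set_index("variable")
    if holm and len(df):
        df["p_holm"] = holm_adjust(df["p"].to_numpy())
    return df
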