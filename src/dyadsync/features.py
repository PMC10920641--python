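"""Dyad-level feature engineering.

Each synchrony matrix is collapsed to seven order-free summary statistics
(min, max, mean, median, SD, skew, kurtosis) over all of its non-missing
entries. Together with the four movement-quantity fractions this yields 25
behavioral features per dyad; a demographic variant appends the
participant's full-scale IQ (possibly missing) and sex for 27.

Age is carried as a covariate next to the features and is never itself a
feature: it is regressed out inside the cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synchrony import CrossCorrMatrix

STAT_NAMES = ("min", "max", "mean", "median", "sd", "skew", "kurtosis")

#: Fixed behavioral feature order: 7 head-synchrony, 7 body-synchrony,
#: 7 intrapersonal (participant head-body), 4 movement fractions.
FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(f"head_sync_{s}" for s in STAT_NAMES)
    + tuple(f"body_sync_{s}" for s in STAT_NAMES)
    + tuple(f"intra_sync_{s}" for s in STAT_NAMES)
    + (
        "movement_participant_head",
        "movement_participant_body",
        "movement_administrator_head",
        "movement_administrator_body",
    )
)

DEMO_COLUMNS: tuple[str, ...] = ("iq", "sex")
METADATA_COLUMNS: tuple[str, ...] = ("label", "age")


@dataclass(frozen=True)
class SummaryStats:
    """The seven order-free statistics of a pooled synchrony matrix.

    Skew is the adjusted Fisher-Pearson sample skewness and kurtosis is the
    bias-corrected Fisher *excess* kurtosis; both are NaN for constant input
    (such columns are pruned in-fold downstream). SD uses ddof=1.
    """

    min: float
    max: float
    mean: float
    median: float
    sd: float
    skew: float
    kurtosis: float

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        return {prefix + s: getattr(self, s) for s in STAT_NAMES}


def summarize_matrix(m: CrossCorrMatrix | np.ndarray) -> SummaryStats:
    """Pool all non-missing matrix entries and compute the seven statistics."""
    if isinstance(m, CrossCorrMatrix):
        x = m.entries
    else:
        x = np.asarray(m, dtype=float).ravel()
        x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 valid matrix entries to summarize")
    if x.min() == x.max():  # constant: sd exactly 0, higher moments undefined
        sd = 0.0
        skew = kurt = float("nan")
    else:
        sd = float(np.std(x, ddof=1))
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return SummaryStats(
        min=float(x.min()),
        max=float(x.max()),
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=sd,
        skew=skew,
        kurtosis=kurt,
    )


def assemble_features(
    head: CrossCorrMatrix | SummaryStats,
    body: CrossCorrMatrix | SummaryStats,
    intrapersonal: CrossCorrMatrix | SummaryStats,
    movement: Mapping[str, float],
    demographics: Mapping[str, float] | None = None,
    mode: str = "mea",
) -> pd.Series:
    """Build one dyad's feature vector in the fixed documented column order.

    ``movement`` maps the four ROI roles to movement-quantity fractions.
    In ``"mea+demo"`` mode ``demographics`` must provide ``sex`` (0/1) and
    may provide ``iq`` (NaN when missing, imputed in-fold later).
    """
    if mode not in ("mea", "mea+demo"):
        raise ValueError("mode must be 'mea' or 'mea+demo'")

    def _stats(m) -> SummaryStats:
        return m if isinstance(m, SummaryStats) else summarize_matrix(m)

    row: dict[str, float] = {}
    row.update(_stats(head).as_dict("head_sync_"))
    row.update(_stats(body).as_dict("body_sync_"))
    row.update(_stats(intrapersonal).as_dict("intra_sync_"))
    for role in (
        "participant_head",
        "participant_body",
        "administrator_head",
        "administrator_body",
    ):
        if role not in movement:
            raise ValueError(f"missing movement quantity for {role!r}")
        q = float(movement[role])
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"movement quantity for {role!r} outside [0, 1]")
        row[f"movement_{role}"] = q
    vec = pd.Series(row).reindex(list(FEATURE_COLUMNS))
    if mode == "mea+demo":
        if demographics is None or "sex" not in demographics or pd.isna(
            demographics["sex"]
        ):
            raise ValueError("mea+demo mode requires the participant's sex")
        vec["iq"] = float(demographics.get("iq", float("nan")))
        vec["sex"] = float(demographics["sex"])
    return vec


def feature_columns(mode: str = "mea") -> list[str]:
    """Feature column names for a mode (25 behavioral, +2 demographic)."""
    cols = list(FEATURE_COLUMNS)
    if mode == "mea+demo":
        cols += list(DEMO_COLUMNS)
    elif mode != "mea":
        raise ValueError("mode must be 'mea' or 'mea+demo'")
    return cols


def knn_impute(
    table: pd.DataFrame,
    k: int = 5,
    fit_rows: pd.Index | np.ndarray | None = None,
) -> pd.DataFrame:
    """Replace missing values by the mean of the k nearest complete donors.

    Distances are Euclidean over the observed coordinates; donor statistics
    are learned from ``fit_rows`` only (the training partition when called
    in-fold by the classifier) and applied to the whole table.
    """
    from sklearn.impute import KNNImputer

    if fit_rows is None:
        fit_rows = table.index
    fit = table.loc[fit_rows]
    if k > len(fit):
        raise ValueError(f"k={k} exceeds the {len(fit)} available donor rows")
    if not table.isna().any().any():
        return table.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputer.fit(fit.to_numpy(dtype=float))
    filled = imputer.transform(table.to_numpy(dtype=float))
    return pd.DataFrame(filled, index=table.index, columns=table.columns)


def make_feature_table(rows: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Stack per-dyad vectors (plus metadata) into a dyad-indexed table."""
    df = pd.DataFrame({k: v for k, v in rows.items()}).T
    df.index.name = "dyad_id"
    return df
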