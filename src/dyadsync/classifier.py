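"""Repeated nested stratified cross-validated linear SVM.

The diagnostic classifier is a linear soft-margin SVM (LIBSVM C-SVC, hinge
loss) with per-class misclassification weights to correct class imbalance.
Generalization is estimated with a repeated, nested, stratified CV scheme:
an outer loop (CV2, default 10 folds x 10 repetitions) measures performance
on held-out dyads while an inner loop (CV1, default 10 folds) tunes the C
parameter by balanced accuracy (BAC). All preprocessing — 0-1 scaling,
pruning of non-informative columns, optional kNN imputation, and age
residualization — is fit on training partitions only.

Each held-out dyad collects one decision score per winning inner model per
outer repetition (10 x 10 = 100 under the default scheme); the pooled score
is their median and its sign the predicted label. Feature stability is
summarized by the cross-validation ratio (CVR) and by sign-based
consistency with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import METADATA_COLUMNS

#: Default C grid for the inner-loop search.
C_GRID: tuple[float, ...] = (
    0.0156, 0.0312, 0.0625, 0.1250, 0.2500, 0.5000, 1.0, 2.0, 4.0, 8.0, 16.0,
)


@dataclass(frozen=True)
class CVScheme:
    """Geometry of the repeated nested stratified CV."""

    outer_folds: int = 10
    outer_perms: int = 10
    inner_folds: int = 10
    inner_perms: int = 1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.outer_perms < 1 or self.inner_perms < 1:
            raise ValueError("permutations must be >= 1")


@dataclass(frozen=True)
class InFoldPreprocSpec:
    """Which in-fold preprocessing steps to run (in this order):

    1. min-max scaling to [0, 1] from training extrema (test clipped),
    2. pruning of zero-variance / non-finite training columns,
    3. kNN imputation of missing values (demographic variant only),
    4. residualization of every feature against age (training-fit OLS).
    """

    scale01: bool = True
    prune: bool = True
    impute: bool = False
    knn_k: int = 5
    age_residualize: bool = True


def _derive_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31 from integer components."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def make_stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each row a fold id 0..k-1 preserving class proportions.

    Per-fold class counts differ from exact proportionality by at most one
    sample. Deterministic under the seed.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


class InFoldPreprocessor:
    """Training-fit feature transform applied identically to test rows."""

    def __init__(self, spec: InFoldPreprocSpec = InFoldPreprocSpec()):
        self.spec = spec

    def fit(self, X: np.ndarray, age: np.ndarray) -> "InFoldPreprocessor":
        X = np.asarray(X, dtype=float)
        age = np.asarray(age, dtype=float)
        spec = self.spec
        inf_cols = np.isinf(X).any(axis=0)
        if spec.scale01:
            with np.errstate(all="ignore"):
                self.col_min_ = np.nanmin(np.where(np.isinf(X), np.nan, X), axis=0)
                self.col_max_ = np.nanmax(np.where(np.isinf(X), np.nan, X), axis=0)
            rng_ = self.col_max_ - self.col_min_
            self.col_range_ = np.where(rng_ > 0, rng_, 1.0)
            X = self._scale(X)
        if spec.prune:
            with np.errstate(all="ignore"):
                var = np.nanvar(X, axis=0)
            keep = (var > 0) & np.isfinite(var) & ~inf_cols
            self.keep_ = keep
            if not keep.any():
                raise ValueError("all feature columns were pruned")
            X = X[:, keep]
        else:
            self.keep_ = np.ones(X.shape[1], dtype=bool)
        if spec.impute:
            from sklearn.impute import KNNImputer

            self.imputer_ = KNNImputer(n_neighbors=min(spec.knn_k, len(X) - 1))
            X = self.imputer_.fit_transform(X)
        if spec.age_residualize:
            A = np.column_stack([np.ones_like(age), age])
            self.age_coef_, *_ = np.linalg.lstsq(A, X, rcond=None)
            X = X - A @ self.age_coef_
        self.n_features_in_ = len(self.keep_)
        return self

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return np.clip((X - self.col_min_) / self.col_range_, 0.0, 1.0)

    def transform(self, X: np.ndarray, age: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        age = np.asarray(age, dtype=float)
        spec = self.spec
        if spec.scale01:
            X = self._scale(X)
        X = X[:, self.keep_]
        if spec.impute:
            X = self.imputer_.transform(X)
        if spec.age_residualize:
            A = np.column_stack([np.ones_like(age), age])
            X = X - A @ self.age_coef_
        return X


@dataclass
class LinearModel:
    """A trained linear decision function w.x + b over the retained features."""

    weights: np.ndarray
    bias: float
    C: float
    train_ids: tuple

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias


def class_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse-prevalence hyperplane weights w_c = N / (2 n_c)."""
    y = np.asarray(y)
    n = len(y)
    return {int(c): n / (2.0 * np.sum(y == c)) for c in np.unique(y)}


def train_weighted_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    weights: dict[int, float] | None = None,
    tol: float = 1e-6,
    train_ids: Sequence | None = None,
) -> LinearModel:
    """Fit a hinge-loss linear C-SVC with per-class misclassification weights.

    ``y`` must be binary 0/1; positive decision scores predict class 1.
    """
    from sklearn.svm import SVC

    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(kernel="linear", C=C, class_weight=weights, tol=tol)
    svc.fit(np.asarray(X, dtype=float), y)
    # sklearn orients decision_function toward classes_[1]; with 0/1 labels
    # classes_ is (0, 1), so positive scores already mean class 1
    return LinearModel(
        weights=svc.coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        train_ids=tuple(train_ids) if train_ids is not None else (),
    )


@dataclass
class PerformanceMetrics:
    """Confusion-derived metrics; rates are fractions in [0, 1].

    NND and PLR are +inf when their denominators vanish; DOR is the
    standard cross-product ratio (tp*tn)/(fn*fp).
    """

    tn: int
    tp: int
    fn: int
    fp: int
    sensitivity: float
    specificity: float
    bac: float
    accuracy: float
    ppv: float
    npv: float
    nnd: float
    plr: float
    dor: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tn", "tp", "fn", "fp", "sensitivity", "specificity", "bac",
            "accuracy", "ppv", "npv", "nnd", "plr", "dor", "auc",
        )}


def classification_metrics(
    tn: int, tp: int, fn: int, fp: int,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> PerformanceMetrics:
    """All confusion-derived metrics; AUC from pooled scores when given."""
    counts = (tn, tp, fn, fp)
    if any(c < 0 for c in counts) or sum(counts) == 0:
        raise ValueError("confusion counts must be nonnegative with a positive total")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("each true class must be represented to compute rates")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    bac = (sens + spec) / 2.0
    acc = (tp + tn) / sum(counts)
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    youden = sens + spec - 1.0
    nnd = 1.0 / youden if youden > 0 else float("inf")
    plr = sens / (1.0 - spec) if spec < 1.0 else float("inf")
    dor = (tp * tn) / (fn * fp) if fn * fp > 0 else float("inf")
    auc = None
    if scores is not None and y_true is not None:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(np.asarray(y_true, int), np.asarray(scores, float)))
    return PerformanceMetrics(tn, tp, fn, fp, sens, spec, bac, acc, ppv, npv,
                              nnd, plr, dor, auc)


def _bac(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return (sens + spec) / 2.0


@dataclass
class ModelRecord:
    """One inner (CV1) model retained in the ensemble, with bookkeeping."""

    outer_perm: int
    outer_fold: int
    inner_fold: int
    C: float
    model: LinearModel
    keep_mask: np.ndarray  # over the full feature space
    train_ids: frozenset

    def weights_full(self, n_features: int) -> np.ndarray:
        """Weights in the full feature space, NaN where the column was pruned."""
        w = np.full(n_features, np.nan)
        w[self.keep_mask] = self.model.weights
        return w


@dataclass
class NestedCVResult:
    """Ensemble predictions, metrics and the model store of one nested CV run."""

    scores: pd.DataFrame  # per dyad: n_scores, score_median, score_mean, predicted, true
    metrics: PerformanceMetrics
    models: list[ModelRecord]
    selected_C: pd.DataFrame  # per (outer_perm, outer_fold)
    score_contributors: dict  # dyad id -> list of model-store indices
    feature_names: list[str]
    pooling: str = "median"


def split_feature_table(
    table: pd.DataFrame, positive_label: str | Sequence[str] = "ASD"
):
    """Separate a feature table into X, binary y, age and dyad ids.

    Every non-metadata column is a feature; ``positive_label`` (one label or
    a collection, e.g. the neurodevelopmental-disorder grouping) maps to
    class 1, everything else to class 0.
    """
    feature_cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    positives = (
        {positive_label} if isinstance(positive_label, str) else set(positive_label)
    )
    y = table["label"].isin(positives).to_numpy().astype(int)
    X = table[feature_cols].to_numpy(dtype=float)
    age = table["age"].to_numpy(dtype=float)
    return X, y, age, table.index.to_numpy(), feature_cols


def run_nested_cv(
    table: pd.DataFrame,
    scheme: CVScheme = CVScheme(),
    grid: Sequence[float] = C_GRID,
    spec: InFoldPreprocSpec = InFoldPreprocSpec(),
    positive_label: str | Sequence[str] = "ASD",
    pooling: str = "median",
) -> NestedCVResult:
    """Run the full repeated nested stratified CV on a dyad feature table.

    For every outer repetition x outer fold the inner loop grid-searches C
    by mean inner-validation BAC (ties broken toward the smallest C, i.e.
    the stronger regularization); the winning inner models then score the
    held-out outer fold. Pooled per-dyad scores use only models whose
    training and tuning rows exclude that dyad — guaranteed by construction
    and auditable via :func:`leakage_audit`.
    """
    X, y, age, ids, feature_names = split_feature_table(table, positive_label)
    if min(np.bincount(y, minlength=2)) < max(scheme.outer_folds, 2):
        raise ValueError("each class needs at least as many members as outer folds")
    grid = sorted(grid)
    score_lists: dict = {i: [] for i in ids}
    contributors: dict = {i: [] for i in ids}
    models: list[ModelRecord] = []
    selected_rows = []

    for perm in range(scheme.outer_perms):
        outer_assign = make_stratified_folds(
            y, scheme.outer_folds, _derive_seed(scheme.seed, perm)
        )
        for fold in range(scheme.outer_folds):
            te = np.where(outer_assign == fold)[0]
            tr = np.where(outer_assign != fold)[0]
            inner_assign = make_stratified_folds(
                y[tr], scheme.inner_folds, _derive_seed(scheme.seed, perm, fold)
            )
            # one preprocessor per inner split, shared across the C grid
            splits = []
            for ifold in range(scheme.inner_folds):
                itr = tr[inner_assign != ifold]
                iva = tr[inner_assign == ifold]
                pre = InFoldPreprocessor(spec).fit(X[itr], age[itr])
                splits.append(
                    (ifold, itr, iva, pre,
                     pre.transform(X[itr], age[itr]),
                     pre.transform(X[iva], age[iva]))
                )
            best_C, best_bac = None, -np.inf
            for C in grid:
                bacs = []
                for _, itr, iva, pre, Xtr, Xva in splits:
                    m = train_weighted_linear_svm(
                        Xtr, y[itr], C, weights=class_weights(y[itr])
                    )
                    bacs.append(_bac(y[iva], (m.decision(Xva) > 0).astype(int)))
                mean_bac = float(np.mean(bacs))
                if mean_bac > best_bac:  # strict: ties keep the smaller C
                    best_bac, best_C = mean_bac, C
            selected_rows.append(
                {"outer_perm": perm, "outer_fold": fold, "C": best_C,
                 "inner_bac": best_bac}
            )
            # winning inner models score the held-out outer fold
            for ifold, itr, iva, pre, Xtr, _ in splits:
                m = train_weighted_linear_svm(
                    Xtr, y[itr], best_C, weights=class_weights(y[itr]),
                    train_ids=ids[itr],
                )
                rec = ModelRecord(perm, fold, ifold, best_C, m,
                                  pre.keep_.copy(), frozenset(ids[itr]))
                models.append(rec)
                te_scores = m.decision(pre.transform(X[te], age[te]))
                for i, s in zip(ids[te], te_scores):
                    score_lists[i].append(float(s))
                    contributors[i].append(len(models) - 1)

    pooled = pd.DataFrame(
        {
            "n_scores": [len(score_lists[i]) for i in ids],
            "score_median": [float(np.median(score_lists[i])) for i in ids],
            "score_mean": [float(np.mean(score_lists[i])) for i in ids],
            "true": y,
        },
        index=pd.Index(ids, name="dyad_id"),
    )
    pool_col = {"median": "score_median", "mean": "score_mean"}[pooling]
    pooled["predicted"] = (pooled[pool_col] > 0).astype(int)
    tn = int(np.sum((pooled.true == 0) & (pooled.predicted == 0)))
    tp = int(np.sum((pooled.true == 1) & (pooled.predicted == 1)))
    fn = int(np.sum((pooled.true == 1) & (pooled.predicted == 0)))
    fp = int(np.sum((pooled.true == 0) & (pooled.predicted == 1)))
    metrics = classification_metrics(
        tn, tp, fn, fp, scores=pooled[pool_col].to_numpy(), y_true=y
    )
    return NestedCVResult(
        scores=pooled,
        metrics=metrics,
        models=models,
        selected_C=pd.DataFrame(selected_rows),
        score_contributors=contributors,
        feature_names=list(feature_names),
        pooling=pooling,
    )


def leakage_audit(result: NestedCVResult) -> bool:
    """True iff no pooled score came from a model trained on its own dyad."""
    for dyad_id, model_idx in result.score_contributors.items():
        for k in model_idx:
            if dyad_id in result.models[k].train_ids:
                return False
    return True


def permutation_test(
    table: pd.DataFrame,
    scheme: CVScheme = CVScheme(),
    grid: Sequence[float] = C_GRID,
    spec: InFoldPreprocSpec = InFoldPreprocSpec(),
    B: int = 1000,
    seed: int = 0,
    positive_label: str | Sequence[str] = "ASD",
) -> dict:
    """Label-permutation significance test of the observed BAC.

    Each permutation shuffles the diagnostic labels, reruns the entire
    nested CV with a permutation-specific fold plan, and records the pooled
    BAC; p = (1 + #{BAC_perm >= BAC_obs}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    observed = run_nested_cv(table, scheme, grid, spec, positive_label)
    rng = np.random.default_rng(seed)
    permuted = []
    for b in range(B):
        t = table.copy()
        t["label"] = rng.permutation(t["label"].to_numpy())
        s = replace(scheme, seed=_derive_seed(seed, b))
        permuted.append(
            run_nested_cv(t, s, grid, spec, positive_label).metrics.bac
        )
    permuted = np.asarray(permuted)
    p = (1.0 + np.sum(permuted >= observed.metrics.bac)) / (B + 1.0)
    return {
        "observed_bac": observed.metrics.bac,
        "permuted_bac": permuted,
        "p": float(p),
        "B": B,
        "observed": observed,
    }


def compute_cvr(
    models: Sequence[ModelRecord],
    feature_names: Sequence[str],
    se_cap: float = 100.0,
) -> pd.DataFrame:
    """Cross-validation ratio per feature.

    For every outer (CV2) fold the median of the inner (CV1) weights is
    divided by their standard error; the CVR is the sum of these ratios over
    outer folds divided by the number of outer folds used. Features pruned
    in a fold are excluded from that fold (retained counts are reported);
    zero-SE folds contribute ``sign(median) * se_cap`` and are flagged.
    |CVR| >= 2 roughly corresponds to p <= .05.
    """
    n_feat = len(feature_names)
    groups: dict[tuple[int, int], list[np.ndarray]] = {}
    for rec in models:
        groups.setdefault((rec.outer_perm, rec.outer_fold), []).append(
            rec.weights_full(n_feat)
        )
    rows = []
    for j, name in enumerate(feature_names):
        ratios, zero_se, n_models = [], 0, 0
        for ws in groups.values():
            wj = np.array([w[j] for w in ws])
            wj = wj[~np.isnan(wj)]
            if len(wj) < 2:
                continue
            n_models += len(wj)
            med = float(np.median(wj))
            se = float(np.std(wj, ddof=1)) / math.sqrt(len(wj))
            if se == 0.0:
                zero_se += 1
                ratios.append(math.copysign(se_cap, med) if med else 0.0)
            else:
                ratios.append(med / se)
        cvr = float(np.sum(ratios) / len(ratios)) if ratios else float("nan")
        rows.append(
            {"feature": name, "cvr": cvr, "n_folds": len(ratios),
             "n_models": n_models, "zero_se_folds": zero_se}
        )
    return pd.DataFrame(rows).set_index("feature")


def sign_consistency(
    models: Sequence[ModelRecord],
    feature_names: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sign-based consistency of feature weights across the model ensemble.

    For each feature the number of positive weights among the models that
    retained it is tested against a fair coin (two-sided binomial); the
    score is -log10(p), so 1.3 corresponds to p = .05. Significance flags
    use Benjamini-Hochberg FDR control at ``alpha`` across features.
    """
    from statsmodels.stats.multitest import multipletests

    if len(models) < 2:
        raise ValueError("need at least 2 models in the ensemble")
    n_feat = len(feature_names)
    W = np.vstack([rec.weights_full(n_feat) for rec in models])
    rows = []
    for j, name in enumerate(feature_names):
        wj = W[:, j]
        wj = wj[~np.isnan(wj)]
        m = len(wj)
        n_pos = int(np.sum(wj > 0))
        if m == 0:
            rows.append({"feature": name, "n_models": 0, "n_positive": 0,
                         "p": np.nan, "neg_log10_p": np.nan})
            continue
        p = float(stats.binomtest(n_pos, m, 0.5).pvalue)
        rows.append(
            {"feature": name, "n_models": m, "n_positive": n_pos, "p": p,
             "neg_log10_p": -math.log10(p) if p > 0 else float("inf")}
        )
    df = pd.DataFrame(rows).set_index("feature")
    valid = df["p"].notna()
    flags = np.zeros(len(df), dtype=bool)
    if valid.any():
        flags[valid.to_numpy()] = multipletests(
            df.loc[valid, "p"].to_numpy(), alpha=alpha, method="fdr_bh"
        )[0]
    df["fdr_significant"] = flags
    return df
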