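"""SMOTE balancing, stepwise selection, regression classifier and the
repeated random-subsampling evaluation.

Each group pair is evaluated with stratified 90/10 train/test splits
repeated (by default) 1000 times.  Per repetition the training minority is
oversampled with SMOTE to the majority count, forward stepwise selection
and the classifier are fitted on training rows only, and the untouched test
rows produce the confusion counts.  The classifier is linear least-squares
regression of 0/1 labels thresholded at 0.5 (a logistic variant is a config
switch).  The second-listed (disease / progressive) group of a pair is the
positive class for sensitivity/specificity; CCR is reported as mean ± SD
over repetitions, SS/SP pooled over all test predictions (per-repetition
averages are logged alongside).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .features import FeatureTable


@dataclass(frozen=True)
class SplitScheme:
    train_fraction: float = 0.9
    n_repetitions: int = 1000
    seed: int = 0
    max_redraws: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")


@dataclass
class ClassifierModel:
    selected_features: list[str]
    coefficients: np.ndarray  # includes intercept as element 0
    threshold: float = 0.5
    kind: str = "linear"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite classifier coefficients")


@dataclass
class EvaluationResult:
    group_pair: tuple[str, str]
    method: str
    ccr_mean: float
    ccr_sd: float
    sensitivity: float  # pooled over all test predictions
    specificity: float
    sensitivity_mean: float  # per-repetition average
    specificity_mean: float
    n_repetitions: int
    n_redraws: int
    confusion: np.ndarray  # pooled [[TN, FP], [FN, TP]]
    selection_counts: dict[str, int] = field(default_factory=dict)
    per_repetition_ccr: np.ndarray | None = None


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(
    minority: np.ndarray,
    majority_count: int,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Oversample the minority rows to ``majority_count`` with SMOTE.

    Each synthetic sample is a + lam·(b − a) with lam ~ U(0, 1), a a random
    minority row and b one of its k nearest minority neighbours (Euclidean).
    The original rows are always returned unchanged, first.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim == 1:
        minority = minority[:, None]
    n = len(minority)
    if n < 2:
        raise ValueError("SMOTE needs a minority of at least 2 samples")
    if majority_count <= n:
        return minority.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = min(k_neighbors, n - 1)
    tree = cKDTree(minority)
    _, nbr = tree.query(minority, k=k + 1)
    nbr = np.atleast_2d(nbr)[:, 1:]  # drop self
    n_new = majority_count - n
    a_idx = rng.integers(0, n, size=n_new)
    b_idx = nbr[a_idx, rng.integers(0, k, size=n_new)]
    lam = rng.random(n_new)[:, None]
    synthetic = minority[a_idx] + lam * (minority[b_idx] - minority[a_idx])
    return np.vstack([minority, synthetic])


# ---------------------------------------------------------------------------
# Regression classifier


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_regression(
    X: np.ndarray, y01: np.ndarray, kind: str = "linear", ridge: float = 1e-8
) -> np.ndarray:
    """Least-squares fit of 0/1 labels on features (intercept included).

    Singular designs fall back to a tiny fixed ridge penalty.  ``logistic``
    fits by a few Newton steps (config switch; same decision threshold).
    """
    A = _design(np.atleast_2d(X))
    y = np.asarray(y01, dtype=float)
    if kind == "linear":
        coef, _res, rank, _sv = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            AtA = A.T @ A + ridge * np.eye(A.shape[1])
            coef = np.linalg.solve(AtA, A.T @ y)
        return coef
    if kind == "logistic":
        coef = np.zeros(A.shape[1])
        for _ in range(25):
            z = np.clip(A @ coef, -30, 30)
            p = 1.0 / (1.0 + np.exp(-z))
            W = np.maximum(p * (1 - p), 1e-6)
            H = (A * W[:, None]).T @ A + ridge * np.eye(A.shape[1])
            g = A.T @ (y - p)
            step = np.linalg.solve(H, g)
            coef = coef + step
            if np.abs(step).max() < 1e-8:
                break
        return coef
    raise ValueError(f"unknown classifier kind {kind!r}")


def predict_regression(
    coef: np.ndarray, X: np.ndarray, threshold: float = 0.5, kind: str = "linear"
) -> np.ndarray:
    A = _design(np.atleast_2d(X))
    score = A @ coef
    if kind == "logistic":
        score = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
    return (score >= threshold).astype(int)


def fit_predict_regression(
    train_X: np.ndarray,
    train_y01: np.ndarray,
    test_X: np.ndarray,
    kind: str = "linear",
) -> np.ndarray:
    coef = fit_regression(train_X, train_y01, kind=kind)
    return predict_regression(coef, test_X, kind=kind)


def _training_ccr(X: np.ndarray, y: np.ndarray, cols: Sequence[int], kind: str) -> float:
    Xs = X[:, list(cols)]
    coef = fit_regression(Xs, y, kind=kind)
    pred = predict_regression(coef, Xs, kind=kind)
    return float((pred == y).mean())


def stepwise_select(
    train_X: np.ndarray,
    train_y01: np.ndarray,
    max_features: int | None = None,
    kind: str = "linear",
) -> list[int]:
    """Greedy forward selection maximizing training CCR.

    Stops when no candidate improves the CCR or ``max_features`` is
    reached; ties break toward the lowest column index, so the result is
    deterministic for a given input.
    """
    X = np.atleast_2d(train_X)
    n_features = X.shape[1]
    if n_features == 0:
        raise ValueError("no candidate features")
    max_features = max_features or n_features
    selected: list[int] = []
    best_ccr = -np.inf
    while len(selected) < max_features:
        best_j, best_new = None, best_ccr
        for j in range(n_features):
            if j in selected:
                continue
            ccr = _training_ccr(X, train_y01, selected + [j], kind)
            if ccr > best_new + 1e-12:
                best_new, best_j = ccr, j
        if best_j is None:
            break
        selected.append(best_j)
        best_ccr = best_new
    if not selected:  # no single feature beats -inf is impossible; keep safe
        selected = [0]
    return selected


# ---------------------------------------------------------------------------
# Repeated random-subsampling evaluation


def fit_split(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    rng: np.random.Generator,
    use_stepwise: bool = True,
    smote_k: int = 5,
    classifier: str = "linear",
) -> tuple[list[int], np.ndarray]:
    """SMOTE-balance, select and fit on training rows only; returns the
    selected column indices and the fitted coefficients.  Exposed separately
    so information isolation from test rows can be asserted directly."""
    n1 = int(ytr.sum())
    n0 = len(ytr) - n1
    if n0 != n1:
        minority_label = 1 if n1 < n0 else 0
        maj = max(n0, n1)
        bal = smote_balance(Xtr[ytr == minority_label], maj, smote_k, rng)
        Xtr = np.vstack([Xtr[ytr != minority_label], bal])
        ytr = np.concatenate(
            [ytr[ytr != minority_label], np.full(len(bal), minority_label)]
        )
    if use_stepwise and Xtr.shape[1] > 1:
        cols = stepwise_select(Xtr, ytr, kind=classifier)
    else:
        cols = list(range(Xtr.shape[1]))
    coef = fit_regression(Xtr[:, cols], ytr, kind=classifier)
    return cols, coef


def _stratified_split(
    idx_a: np.ndarray, idx_b: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for idx in (idx_a, idx_b):
        perm = rng.permutation(idx)
        n_test = max(1, int(round(len(idx) * (1.0 - train_fraction))))
        n_test = min(n_test, len(idx) - 1)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.concatenate(train), np.concatenate(test)


def evaluate_repeated_splits(
    table: FeatureTable,
    group_pair: tuple[str, str],
    scheme: SplitScheme | None = None,
    features: Sequence[str] | None = None,
    method: str = "all",
    use_stepwise: bool = True,
    smote_k: int = 5,
    classifier: str = "linear",
    keep_per_repetition: bool = False,
) -> EvaluationResult:
    """Repeated stratified 90/10 evaluation of one group pair.

    SMOTE, feature selection and fitting touch training rows only; the test
    rows are untouched until prediction.  The positive class for SS/SP is
    the second-listed group.  Repetitions with an empty test class are
    redrawn (counted, capped).
    """
    scheme = scheme or SplitScheme()
    features = list(features or table.feature_names)
    sub = table.subset(group_pair).dropna_rows(features)
    g = sub.df["group"].to_numpy()
    idx_a = np.where(g == group_pair[0])[0]
    idx_b = np.where(g == group_pair[1])[0]
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("need at least 3 subjects per group")
    X = sub.values(features)
    y = (g == group_pair[1]).astype(int)  # positive = disease/progressive group

    ss = np.random.SeedSequence(scheme.seed)
    child_seeds = ss.spawn(scheme.n_repetitions)
    ccrs = np.empty(scheme.n_repetitions)
    pooled = np.zeros((2, 2), dtype=np.int64)  # [true][pred]
    rep_ss, rep_sp = [], []
    selection_counts: dict[str, int] = {}
    n_redraws = 0
    for r in range(scheme.n_repetitions):
        rng = np.random.default_rng(child_seeds[r])
        for _attempt in range(scheme.max_redraws):
            train_idx, test_idx = _stratified_split(idx_a, idx_b, scheme.train_fraction, rng)
            if len(set(y[test_idx])) == 2 and len(set(y[train_idx])) == 2:
                break
            n_redraws += 1
        cols, coef = fit_split(
            X[train_idx], y[train_idx], rng,
            use_stepwise=use_stepwise and len(features) > 1,
            smote_k=smote_k, classifier=classifier,
        )
        for c in cols:
            selection_counts[features[c]] = selection_counts.get(features[c], 0) + 1
        pred = predict_regression(coef, X[test_idx][:, cols], kind=classifier)
        truth = y[test_idx]
        ccrs[r] = float((pred == truth).mean())
        for t_val in (0, 1):
            for p_val in (0, 1):
                pooled[t_val, p_val] += int(((truth == t_val) & (pred == p_val)).sum())
        pos = truth == 1
        neg = ~pos
        rep_ss.append(float((pred[pos] == 1).mean()) if pos.any() else np.nan)
        rep_sp.append(float((pred[neg] == 0).mean()) if neg.any() else np.nan)

    tn, fp = pooled[0]
    fn, tp = pooled[1]
    return EvaluationResult(
        group_pair=tuple(group_pair),
        method=method,
        ccr_mean=float(ccrs.mean()),
        ccr_sd=float(ccrs.std(ddof=0)),
        sensitivity=float(tp / max(tp + fn, 1)),
        specificity=float(tn / max(tn + fp, 1)),
        sensitivity_mean=float(np.nanmean(rep_ss)),
        specificity_mean=float(np.nanmean(rep_sp)),
        n_repetitions=scheme.n_repetitions,
        n_redraws=n_redraws,
        confusion=pooled,
        selection_counts=selection_counts,
        per_repetition_ccr=ccrs if keep_per_repetition else None,
    )


DEFAULT_PAIRS = (
    ("C", "FTD"), ("AD", "FTD"), ("SMCI", "FTD"), ("PMCI", "FTD"),
    ("C", "AD"), ("SMCI", "AD"), ("PMCI", "AD"),
    ("C", "PMCI"), ("SMCI", "PMCI"), ("C", "SMCI"),
)


def method_feature_columns(table: FeatureTable, method: str) -> list[str]:
    """Feature subsets matching the reporting methods HV | TBM | VBM | VBMmod | all."""
    if method == "all":
        return list(table.feature_names)
    prefixes = {
        "HV": ("HV_",),
        "TBM": ("TBM_",),
        "VBM": ("VBM_",),
        "VBMmod": ("VBMmod_",),
    }
    if method not in prefixes:
        raise ValueError(f"unknown method {method!r}")
    if method == "VBM":
        return [f for f in table.feature_names if f.startswith("VBM_")]
    return [f for f in table.feature_names if f.startswith(prefixes[method])]
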