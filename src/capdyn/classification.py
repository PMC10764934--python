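"""Nested cross-validated RBF-SVM classification of dynamic metrics.

Features are the dynamic metrics that differ between groups at raw p < alpha
(dwell time, occurrence rate, persistence probabilities, trajectory
entropies). Classification uses a Gaussian-kernel SVM inside nested
stratified cross-validation: the outer loop estimates performance, the inner
loop grid-searches (C, gamma) by accuracy; feature standardization is fitted
on each outer training fold only and applied to its test fold. Significance
of the observed accuracy/AUC is assessed by re-running the whole nested CV
on label permutations.

The default "as-paper" mode selects features from statistics computed on the
full cohort before cross-validating, which leaks the selection step; "strict"
mode repeats selection inside each outer training fold and is the honest
generalization estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))
SELECTABLE_FAMILIES = ("dwell", "occurrence", "persistence", "traj_entropy")


@dataclass
class FoldResult:
    fold: int
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    f1: float
    ppv: float
    npv: float
    best_c: float
    best_gamma: float


@dataclass
class ClassifierReport:
    contrast: str
    features: list[str]
    folds: list[FoldResult]
    seed: int
    grid: dict[str, list[float]]
    inspection: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(f, name) for f in self.folds]))

    def summary(self) -> dict[str, float]:
        return {
            m: self.mean(m)
            for m in ("accuracy", "auc", "sensitivity", "specificity", "f1", "ppv", "npv")
        }


def select_features(
    stat_table: pd.DataFrame,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = SELECTABLE_FAMILIES,
) -> list[tuple[str, int, int | None]]:
    """Metric/path identifiers with raw p < alpha from the selectable
    metric families (off-diagonal transition probabilities excluded unless
    listed in ``metrics``)."""
    sel = stat_table[stat_table["metric"].isin(metrics) & (stat_table["p"] < alpha)]
    feats = [
        (row.metric, int(row.cap_from), None if pd.isna(row.cap_to) else int(row.cap_to))
        for row in sel.itertuples()
    ]
    if not feats:
        raise ValueError(
            f"no feature with p < {alpha}; relax alpha or use all metrics"
        )
    return feats


def feature_matrix(
    long_df: pd.DataFrame,
    features: list[tuple[str, int, int | None]],
    subject_ids: list[str],
) -> np.ndarray:
    """Subjects x features matrix extracted from the long metrics table."""
    wide = long_df.pivot_table(
        index="subject_id",
        columns=["metric", "cap_from", "cap_to"],
        values="value",
        dropna=False,
    )
    cols = []
    for metric, cf, ct in features:
        key = (metric, cf, np.nan if ct is None else ct)
        # pivot stores blank cap_to as NaN; match on (metric, cap_from) then cap_to
        matches = [
            c
            for c in wide.columns
            if c[0] == metric
            and c[1] == cf
            and ((ct is None and pd.isna(c[2])) or (ct is not None and c[2] == ct))
        ]
        if not matches:
            raise KeyError(f"feature {key} not present in metrics table")
        cols.append(wide[matches[0]])
    mat = pd.concat(cols, axis=1).loc[subject_ids]
    return mat.to_numpy(dtype=float)


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())

    def safe(a: float, b: float) -> float:
        return a / b if b > 0 else np.nan

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    ppv = safe(tp, tp + fp)
    npv = safe(tn, tn + fn)
    f1 = safe(2 * tp, 2 * tp + fp + fn)
    auc = roc_auc_score(y_true, scores) if len(np.unique(y_true)) == 2 else np.nan
    return {
        "accuracy": (tp + tn) / y_true.size,
        "auc": float(auc),
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
        "ppv": ppv,
        "npv": npv,
    }


def _grid_search_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    c_grid: tuple[float, ...],
    gamma_grid: tuple[float, ...],
    inner_folds: int,
    seed: int,
) -> tuple[float, float]:
    """Best (C, gamma) by mean inner-CV accuracy; single-point grids skip
    the inner loop. Ties go to the first grid point in (C, gamma) order."""
    if len(c_grid) == 1 and len(gamma_grid) == 1:
        return c_grid[0], gamma_grid[0]
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(inner.split(x, y))
    best, best_acc = (c_grid[0], gamma_grid[0]), -1.0
    for c in c_grid:
        for g in gamma_grid:
            accs = []
            for tr, te in splits:
                scaler = StandardScaler().fit(x[tr])
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(scaler.transform(x[tr]), y[tr])
                accs.append(clf.score(scaler.transform(x[te]), y[te]))
            acc = float(np.mean(accs))
            if acc > best_acc:
                best, best_acc = (c, g), acc
    return best


def nested_cv_svm(
    features: np.ndarray,
    labels: np.ndarray,
    outer_folds: int = 5,
    inner_folds: int = 5,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
    contrast: str = "",
    feature_names: list[str] | None = None,
    inspect: bool = False,
) -> ClassifierReport:
    """Nested stratified CV with an RBF-SVM and accuracy-driven grid search.

    Standardization parameters are learned on each outer training fold and
    applied unchanged to its test fold. With ``inspect=True`` the report
    records per-fold train indices and fitted scaler moments so leakage can
    be audited externally.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("feature matrix must be 2-D with at least one column")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    inspection: dict = {"train_indices": [], "scaler_mean": [], "scaler_scale": []}
    for i, (tr, te) in enumerate(outer.split(x, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"a class is absent in outer fold {i}")
        c, g = _grid_search_accuracy(x[tr], y[tr], c_grid, gamma_grid, inner_folds, seed + i)
        scaler = StandardScaler().fit(x[tr])
        clf = SVC(C=c, gamma=g, kernel="rbf")
        clf.fit(scaler.transform(x[tr]), y[tr])
        xte = scaler.transform(x[te])
        pred = clf.predict(xte)
        scores = clf.decision_function(xte)
        m = _binary_metrics(y[te], pred, scores)
        folds.append(FoldResult(fold=i, best_c=c, best_gamma=g, **m))
        if inspect:
            inspection["train_indices"].append(tr.copy())
            inspection["scaler_mean"].append(scaler.mean_.copy())
            inspection["scaler_scale"].append(scaler.scale_.copy())
    return ClassifierReport(
        contrast=contrast,
        features=feature_names or [f"f{i}" for i in range(x.shape[1])],
        folds=folds,
        seed=seed,
        grid={"C": list(c_grid), "gamma": list(gamma_grid)},
        inspection=inspection if inspect else {},
    )


def permutation_test(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    **cv_kwargs,
) -> dict:
    """Permutation significance of nested-CV accuracy and AUC.

    The label vector is permuted ``n_perm`` times and the full nested CV
    re-run each time; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y = np.asarray(labels).astype(int)
    observed = nested_cv_svm(features, y, seed=seed, **cv_kwargs)
    obs_acc, obs_auc = observed.mean("accuracy"), observed.mean("auc")
    rng = np.random.default_rng(seed)
    null_acc = np.empty(n_perm)
    null_auc = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(y)
        rep = nested_cv_svm(features, perm, seed=seed, **cv_kwargs)
        null_acc[b] = rep.mean("accuracy")
        null_auc[b] = rep.mean("auc")
    p_acc = (1 + (null_acc >= obs_acc).sum()) / (n_perm + 1)
    p_auc = (1 + (null_auc >= obs_auc).sum()) / (n_perm + 1)
    return {
        "observed_accuracy": obs_acc,
        "observed_auc": obs_auc,
        "p_accuracy": float(p_acc),
        "p_auc": float(p_auc),
        "null_accuracy": null_acc,
        "null_auc": null_auc,
        "report": observed,
    }
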