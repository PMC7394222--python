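"""Random-forest classification with stratified leave-one-pair-out CV.

With a balanced two-class cohort of n pairs, each fold holds out one
subject from each class (deterministic pairing by sorted subject id),
trains a random forest on the remaining 2(n-1) subjects and scores the
pair.  Performance is the per-fold mean of six standard metrics; feature
relevance is the per-fold-normalized Gini importance summed over folds.
Significance is assessed against label-permutation surrogates using the
mean +/- 2 SD rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .errors import InvalidDesignError, InvalidParameterError

__all__ = [
    "CVReport",
    "DEFAULT_GRID",
    "compute_metrics",
    "loocv_rfc",
    "grid_search",
    "permutation_null",
]

METRICS = ("ACC", "SEN", "SPE", "PPV", "NPV", "ROC_AUC")

# trees x max-features grid; the sqrt entry is round(sqrt(21)) = 5 for the
# full 21-feature table, so "sqrt" is listed symbolically and resolved per table
DEFAULT_GRID = {
    "n_estimators": (100, 250, 500, 1000),
    "max_features": (1, "sqrt", 5, None),
}
DEFAULT_HYPERPARAMS = {"n_estimators": 500, "max_features": "sqrt"}


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold metrics (%), their means, and
    cumulative Gini importances (each fold's importances sum to 1)."""

    per_fold: pd.DataFrame  # folds x metrics, NaN where undefined
    means: dict  # metric -> mean over folds where defined
    importance: pd.Series  # summed over folds
    hyperparams: dict = field(default_factory=dict)


def compute_metrics(
    tp: int, fp: int, tn: int, fn: int,
    scores: np.ndarray | None = None,
    score_labels: np.ndarray | None = None,
) -> dict:
    """Six standard report measures in percent.

    Ratios with zero denominator are returned as NaN ("undefined") and are
    excluded from fold averaging by the caller.  ROC-AUC is the rank
    (Mann-Whitney) statistic of ``scores`` against binary
    ``score_labels`` (1 = positive class).
    """
    total = tp + fp + tn + fn
    if total < 1:
        raise InvalidParameterError("empty confusion matrix")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    out = {
        "ACC": ratio(tp + tn, total),
        "SEN": ratio(tp, tp + fn),
        "SPE": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "ROC_AUC": float("nan"),
    }
    if scores is not None and score_labels is not None:
        y = np.asarray(score_labels).astype(bool)
        s = np.asarray(scores, dtype=float)
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        if n_pos and n_neg:
            r = rankdata(s)  # midranks handle tied scores
            auc = (r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
            out["ROC_AUC"] = 100.0 * float(auc)
    return out


def _split_groups(ft: pd.DataFrame, label_col: str = "group"):
    if label_col not in ft.columns:
        raise InvalidDesignError(f"feature table needs a '{label_col}' column")
    labels = ft[label_col]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise InvalidDesignError("exactly two classes required")
    neg, pos = classes  # e.g. HC (negative), SZ (positive)
    idx_neg = sorted(ft.index[labels == neg])
    idx_pos = sorted(ft.index[labels == pos])
    if len(idx_neg) != len(idx_pos):
        raise InvalidDesignError("classes must be balanced for paired CV")
    return neg, pos, idx_neg, idx_pos


def loocv_rfc(
    ft: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
    label_col: str = "group",
) -> CVReport:
    """Stratified leave-one-pair-out cross-validation of a random forest.

    The i-th fold holds out the i-th subject (by sorted id) of each class;
    metrics are computed on the two held-out subjects, so per-fold ACC is
    0, 50 or 100%.  Undefined per-fold ratios (e.g. PPV when nothing was
    predicted positive) are excluded from the means.
    """
    hp = dict(DEFAULT_HYPERPARAMS if hyperparams is None else hyperparams)
    neg, pos, idx_neg, idx_pos = _split_groups(ft, label_col)
    feat_cols = [c for c in ft.columns if c != label_col]
    x = ft[feat_cols].to_numpy(dtype=float)
    y = (ft[label_col] == pos).to_numpy()
    pos_index = {sid: i for i, sid in enumerate(ft.index)}
    rng = np.random.default_rng(seed)
    rows, importances = [], []
    for held_neg, held_pos in zip(idx_neg, idx_pos):
        test = np.array([pos_index[held_neg], pos_index[held_pos]])
        train = np.setdiff1d(np.arange(len(ft)), test)
        clf = RandomForestClassifier(
            random_state=int(rng.integers(0, 2**31 - 1)), **hp
        )
        clf.fit(x[train], y[train])
        prob_pos = clf.predict_proba(x[test])[:, list(clf.classes_).index(True)]
        pred = prob_pos >= 0.5
        truth = y[test]
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        tn = int(np.sum(~pred & ~truth))
        fn = int(np.sum(~pred & truth))
        rows.append(compute_metrics(tp, fp, tn, fn, prob_pos, truth))
        importances.append(clf.feature_importances_)
    per_fold = pd.DataFrame(rows)
    means = {m: float(per_fold[m].mean(skipna=True)) for m in METRICS}
    importance = pd.Series(np.sum(importances, axis=0), index=feat_cols)
    return CVReport(per_fold, means, importance, hp)


def grid_search(
    ft: pd.DataFrame,
    grid: dict | None = None,
    seed: int = 0,
    label_col: str = "group",
) -> dict:
    """Exhaustive hyperparameter search maximizing mean CV accuracy.

    Ties break toward fewer trees, then fewer features per split.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    n_feat = len([c for c in ft.columns if c != label_col])

    def mf_rank(mf):  # for tie-breaking: effective feature count
        if mf is None:
            return n_feat
        if mf == "sqrt":
            return int(round(np.sqrt(n_feat)))
        return int(mf)

    best = None
    for n_est in grid["n_estimators"]:
        for mf in grid["max_features"]:
            hp = {"n_estimators": int(n_est), "max_features": mf}
            acc = loocv_rfc(ft, hp, seed=seed, label_col=label_col).means["ACC"]
            key = (-acc, n_est, mf_rank(mf))
            if best is None or key < best[0]:
                best = (key, hp)
    return best[1]


def permutation_null(
    ft: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    hyperparams: dict | None = None,
    label_col: str = "group",
) -> dict:
    """Label-permutation significance of the CV metrics.

    The full cross-validation is repeated on ``n_perm`` copies of the
    table with labels randomly permuted among subjects (features intact,
    class balance preserved by construction).  Each real metric is flagged
    significant when it exceeds the permutation mean + 2 SD.
    """
    report = loocv_rfc(ft, hyperparams, seed=seed, label_col=label_col)
    rng = np.random.default_rng(seed)
    null_rows = []
    labels = ft[label_col].to_numpy()
    for _ in range(n_perm):
        permuted = ft.copy()
        permuted[label_col] = rng.permutation(labels)
        rep = loocv_rfc(
            permuted, hyperparams, seed=int(rng.integers(0, 2**31 - 1)),
            label_col=label_col,
        )
        null_rows.append(rep.means)
    null = pd.DataFrame(null_rows)
    out = {"observed": report.means, "null_mean": {}, "null_sd": {}, "significant": {}}
    for m in METRICS:
        mu = float(null[m].mean(skipna=True))
        sd = float(null[m].std(skipna=True, ddof=1))
        out["null_mean"][m] = mu
        out["null_sd"][m] = sd
        out["significant"][m] = bool(report.means[m] > mu + 2.0 * sd)
    return out
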