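"""Outlier filtering, feature selection and classifier evaluation.

The analysis workflow mirrors a standard tabular-ML pipeline for a small
two-class cohort (progressors vs non-progressors):

1. local-outlier-factor (LOF) screening on the pooled standardized cohort
   (20 neighbors, Euclidean, 4% contamination) with the flagged cases removed;
2. per-feature z-score normalization (fit on training folds inside CV);
3. feature selection by a binary decision tree scored with information gain
   ratio, honoring minimum-leaf / minimum-split / depth / majority-stop rules;
4. evaluation of the tree, Gaussian Naive Bayes and L2 logistic regression by
   stratified 5-fold cross-validation with AUC, CA, precision, sensitivity,
   specificity and F1;
5. comparison of classifiers by Venn counts of (mis)classified cases and the
   correlated Bayesian t-test on per-fold scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import LocalOutlierFactor

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "TreeNode",
    "TreeModel",
    "CVReport",
    "ComparisonReport",
    "lof_filter",
    "normalize",
    "induce_tree",
    "crossvalidate",
    "performance",
    "compare_bayesian",
    "venn_counts",
]

POSITIVE_LABEL = "PROG"
NEGATIVE_LABEL = "NON-PROG"

TREE_PARAMS_DEFAULT = {
    "min_leaf": 3,  # minimum instances in each child
    "min_split": 5,  # do not split nodes smaller than this
    "max_depth": 100,
    "majority_stop": 0.95,  # stop splitting once majority reaches this
}


def _feature_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    """Numeric feature columns of a feature matrix (label dropped)."""
    return matrix.drop(columns=["label"], errors="ignore").select_dtypes(
        include=[np.number]
    )


def lof_filter(
    matrix: pd.DataFrame,
    neighbors: int = 20,
    metric: str = "euclidean",
    contamination: float = 0.04,
) -> tuple[pd.DataFrame, list]:
    """Remove the round(contamination * n) most anomalous cases by LOF.

    LOF scores are computed on the pooled cohort (both classes together) with
    Euclidean distances on internally standardized features; exactly
    ``round(contamination * n)`` cases with the worst scores are flagged.
    Returns (retained matrix, flagged ids).
    """
    x = _feature_frame(matrix)
    n = len(x)
    if n <= neighbors:
        raise ValueError(f"need more cases ({n}) than neighbors ({neighbors})")
    values = x.to_numpy(dtype=float)
    # standardize before distances; missing entries -> column means (0 after)
    mu = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (values - mu) / sd
    z = np.nan_to_num(z, nan=0.0)
    lof = LocalOutlierFactor(n_neighbors=neighbors, metric=metric)
    lof.fit(z)
    scores = -lof.negative_outlier_factor_  # higher = more anomalous
    n_flag = int(round(contamination * n))
    flagged_pos = np.argsort(-scores, kind="stable")[:n_flag]
    flagged_ids = list(matrix.index[flagged_pos])
    retained = matrix.drop(index=flagged_ids)
    return retained, flagged_ids


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score every numeric feature column (mean 0, variance 1).

    Zero-variance columns are dropped with a warning.  The label and any
    non-numeric columns pass through unchanged.
    """
    out = matrix.copy()
    for col in _feature_frame(matrix).columns:
        values = out[col].to_numpy(dtype=float)
        sd = np.nanstd(values)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping zero-variance feature {col!r}")
            out = out.drop(columns=[col])
            continue
        out[col] = (values - np.nanmean(values)) / sd
    return out


# --- gain-ratio binary decision tree -----------------------------------------

@dataclass
class TreeNode:
    counts: dict  #: class -> count at this node
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  #: branch with feature <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class TreeModel:
    """Binary decision tree scored by information gain ratio."""

    root: TreeNode
    selected_features: list = field(default_factory=list)
    classes: tuple = (NEGATIVE_LABEL, POSITIVE_LABEL)

    def _leaf_for(self, row: pd.Series) -> TreeNode:
        node = self.root
        while not node.is_leaf:
            value = row[node.feature]
            node = node.left if value <= node.threshold else node.right
        return node

    def predict_proba_row(self, row: pd.Series) -> dict:
        counts = self._leaf_for(row).counts
        total = sum(counts.values())
        # Laplace-smoothed leaf relative frequencies
        return {
            c: (counts.get(c, 0) + 1) / (total + len(self.classes))
            for c in self.classes
        }

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        return np.array(
            [max(p, key=p.get) for p in (self.predict_proba_row(r) for _, r in x.iterrows())]
        )

    def predict_proba(self, x: pd.DataFrame, positive: str = POSITIVE_LABEL) -> np.ndarray:
        return np.array([self.predict_proba_row(r)[positive] for _, r in x.iterrows()])


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _best_split(x: np.ndarray, y: np.ndarray, columns, min_leaf: int):
    """Best (gain_ratio, feature_index, threshold) over all candidate splits."""
    n = len(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    parent_counts = np.bincount(y_idx, minlength=len(classes))
    h_parent = _entropy(parent_counts)
    best = None
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.any(~np.isfinite(col)):
            continue
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        sorted_y = y_idx[order]
        left_counts = np.zeros(len(classes), dtype=int)
        for i in range(n - 1):
            left_counts[sorted_y[i]] += 1
            if sorted_vals[i] == sorted_vals[i + 1]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            right_counts = parent_counts - left_counts
            gain = h_parent - (
                n_left / n * _entropy(left_counts)
                + n_right / n * _entropy(right_counts)
            )
            if gain <= 1e-12:
                continue
            split_info = _entropy(np.array([n_left, n_right]))
            ratio = gain / split_info
            threshold = (sorted_vals[i] + sorted_vals[i + 1]) / 2.0
            cand = (ratio, -j, -threshold)  # ties: lower index, lower threshold
            if best is None or cand > best[0]:
                best = (cand, j, threshold)
    if best is None:
        return None
    return best[0][0], best[1], best[2]


def induce_tree(matrix: pd.DataFrame, params: dict | None = None) -> TreeModel:
    """Greedy gain-ratio binary tree over a labeled feature matrix.

    Stopping rules (all honored): children must contain at least ``min_leaf``
    instances; nodes smaller than ``min_split`` are not split; depth is capped
    at ``max_depth``; nodes whose majority class reaches ``majority_stop`` are
    not split; a split must have strictly positive information gain.
    ``selected_features`` lists the distinct split features in breadth-first
    first-use order.
    """
    params = {**TREE_PARAMS_DEFAULT, **(params or {})}
    if "label" not in matrix.columns:
        raise ValueError("matrix must carry a 'label' column")
    x_frame = _feature_frame(matrix)
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to induce a tree")
    columns = list(x_frame.columns)
    x = x_frame.to_numpy(dtype=float)
    y = matrix["label"].to_numpy()
    classes = tuple(sorted(np.unique(y)))

    def counts_of(idx: np.ndarray) -> dict:
        vals, cnts = np.unique(y[idx], return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))

    root = TreeNode(counts=counts_of(np.arange(len(y))))
    selected: list = []
    queue: list[tuple[TreeNode, np.ndarray, int]] = [(root, np.arange(len(y)), 0)]
    while queue:  # breadth-first, so selection order matches level order
        node, idx, depth = queue.pop(0)
        n_node = len(idx)
        majority = max(node.counts.values()) / n_node
        if (
            n_node < params["min_split"]
            or depth >= params["max_depth"]
            or majority >= params["majority_stop"]
        ):
            continue
        found = _best_split(x[idx], y[idx], columns, params["min_leaf"])
        if found is None:
            continue
        _, j, threshold = found
        node.feature = columns[j]
        node.threshold = float(threshold)
        if node.feature not in selected:
            selected.append(node.feature)
        mask = x[idx, j] <= threshold
        left_idx, right_idx = idx[mask], idx[~mask]
        node.left = TreeNode(counts=counts_of(left_idx))
        node.right = TreeNode(counts=counts_of(right_idx))
        queue.append((node.left, left_idx, depth + 1))
        queue.append((node.right, right_idx, depth + 1))
    return TreeModel(root=root, selected_features=selected, classes=classes)


# --- cross-validation and metrics --------------------------------------------

@dataclass
class CVReport:
    classifier: str
    seed: int
    fold_confusions: list  #: per-fold {"TP","TN","FP","FN"}
    pooled_confusion: dict  #: pooled counts with PROG positive
    metrics: dict  #: the six measures, weighted convention + PROG-positive
    fold_metrics: list  #: per-fold metric dicts (for Bayesian comparison)
    predictions: pd.DataFrame  #: per-case label, prediction, PROG score, fold

    def fold_scores(self, measure: str) -> np.ndarray:
        return np.array([m[measure] for m in self.fold_metrics])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    return {
        "TP": int(np.sum((y_true == POSITIVE_LABEL) & (y_pred == POSITIVE_LABEL))),
        "TN": int(np.sum((y_true == NEGATIVE_LABEL) & (y_pred == NEGATIVE_LABEL))),
        "FP": int(np.sum((y_true == NEGATIVE_LABEL) & (y_pred == POSITIVE_LABEL))),
        "FN": int(np.sum((y_true == POSITIVE_LABEL) & (y_pred == NEGATIVE_LABEL))),
    }


def performance(confusion: dict, y_true=None, scores=None) -> dict:
    """The six performance measures from a confusion matrix (+ scores for AUC).

    Reports both conventions: class-weighted precision/recall(sensitivity)/
    specificity/F1 (under the plain metric names; weighted recall is
    identically CA), and PROG-positive sensitivity with NON-PROG specificity
    under ``*_prog`` keys.  AUC needs ``y_true`` and PROG scores; it is NaN
    when they are absent or one class is missing.
    """
    tp, tn, fp, fn = (confusion[k] for k in ("TP", "TN", "FP", "FN"))
    n = tp + tn + fp + fn
    n_pos, n_neg = tp + fn, tn + fp

    def _safe(num, den):
        return num / den if den > 0 else float("nan")

    ca = _safe(tp + tn, n)
    prec_pos = _safe(tp, tp + fp)
    prec_neg = _safe(tn, tn + fn)
    rec_pos = _safe(tp, n_pos)  # PROG-positive sensitivity
    rec_neg = _safe(tn, n_neg)  # NON-PROG specificity
    f1_pos = _safe(2 * prec_pos * rec_pos, prec_pos + rec_pos)
    f1_neg = _safe(2 * prec_neg * rec_neg, prec_neg + rec_neg)

    def _weighted(v_pos, v_neg):
        if n == 0 or math.isnan(v_pos) or math.isnan(v_neg):
            return float("nan")
        return (n_pos * v_pos + n_neg * v_neg) / n

    auc = float("nan")
    if y_true is not None and scores is not None and n_pos > 0 and n_neg > 0:
        auc = float(roc_auc_score(np.asarray(y_true) == POSITIVE_LABEL, scores))
    return {
        "AUC": auc,
        "CA": ca,
        "precision": _weighted(prec_pos, prec_neg),
        "sensitivity": _weighted(rec_pos, rec_neg),  # == CA identically
        # weighted specificity: specificity of each class weighted by support
        "specificity": _weighted(rec_neg, rec_pos),
        "F1": _weighted(f1_pos, f1_neg),
        "precision_prog": prec_pos,
        "sensitivity_prog": rec_pos,
        "specificity_prog": rec_neg,
        "F1_prog": f1_pos,
    }


def _make_classifier(name: str):
    if name == "tree":
        return None  # handled natively
    if name == "naive_bayes":
        return GaussianNB()
    if name == "logistic_l2":
        # default penalty is ridge (L2); cost strength C = 1
        return LogisticRegression(C=1.0, max_iter=10000)
    raise ValueError(f"unknown classifier {name!r}")


def crossvalidate(
    classifier: str, matrix: pd.DataFrame, k: int = 5, seed: int = 0
) -> CVReport:
    """Stratified k-fold cross-validation of one classifier.

    Normalization is fit on the training folds only.  Returns per-fold and
    pooled confusion matrices, per-case predictions with PROG scores, and the
    metrics both fold-averaged and pooled (the ``metrics`` dict holds
    fold-averaged values plus ``AUC_pooled``/``CA_pooled``).
    """
    if len(matrix) < k:
        raise ValueError("fewer cases than folds")
    x_all = _feature_frame(matrix)
    y_all = matrix["label"].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_confusions, fold_metrics, pred_rows = [], [], []
    for fold, (tr, te) in enumerate(skf.split(x_all, y_all)):
        if len(np.unique(y_all[tr])) < 2:
            raise RuntimeError(f"fold {fold} is missing a class after stratification")
        mu = x_all.iloc[tr].mean()
        sd = x_all.iloc[tr].std(ddof=0).replace(0.0, 1.0)
        x_tr = (x_all.iloc[tr] - mu) / sd
        x_te = (x_all.iloc[te] - mu) / sd
        if classifier == "tree":
            model = induce_tree(x_tr.assign(label=y_all[tr]))
            y_pred = model.predict(x_te)
            score = model.predict_proba(x_te)
        else:
            model = _make_classifier(classifier)
            model.fit(x_tr.to_numpy(), y_all[tr])
            pos_col = list(model.classes_).index(POSITIVE_LABEL)
            score = model.predict_proba(x_te.to_numpy())[:, pos_col]
            y_pred = model.predict(x_te.to_numpy())
        conf = _confusion(y_all[te], y_pred)
        fold_confusions.append(conf)
        fold_metrics.append(performance(conf, y_all[te], score))
        for case, truth, pred, s in zip(matrix.index[te], y_all[te], y_pred, score):
            pred_rows.append(
                {"id": case, "label": truth, "predicted": pred,
                 "score_prog": float(s), "fold": fold}
            )
    predictions = pd.DataFrame(pred_rows).set_index("id").loc[matrix.index]
    pooled_conf = _confusion(
        predictions["label"].to_numpy(), predictions["predicted"].to_numpy()
    )
    pooled = performance(
        pooled_conf, predictions["label"].to_numpy(),
        predictions["score_prog"].to_numpy(),
    )
    metrics = {}
    for key in fold_metrics[0]:
        vals = np.array([m[key] for m in fold_metrics], dtype=float)
        metrics[key] = (
            float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
        )
    metrics["AUC_pooled"] = pooled["AUC"]
    metrics["CA_pooled"] = pooled["CA"]
    return CVReport(
        classifier=classifier,
        seed=seed,
        fold_confusions=fold_confusions,
        pooled_confusion=pooled_conf,
        metrics=metrics,
        fold_metrics=fold_metrics,
        predictions=predictions,
    )


def compare_bayesian(scores_a, scores_b, rho: float | None = None) -> float:
    """Correlated Bayesian t-test probability that A's mean score exceeds B's.

    Paired per-fold scores from the same k-fold split are correlated; the
    posterior of the mean difference is a Student t with k-1 degrees of
    freedom and variance inflated by the correlation heuristic rho = 1/k.
    Returns P(A > B) in [0, 1]; by construction P(A>B) + P(B>A) = 1 (no rope).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length paired score vectors")
    k = a.size
    d = a - b
    if rho is None:
        rho = 1.0 / k
    mean = d.mean()
    var = d.var(ddof=1)
    if var == 0.0:
        return 0.5 if mean == 0.0 else (1.0 if mean > 0 else 0.0)
    scale = math.sqrt(var * (1.0 / k + rho / (1.0 - rho)))
    return float(1.0 - stats.t.cdf(0.0, df=k - 1, loc=mean, scale=scale))


@dataclass
class ComparisonReport:
    """Pairwise win-probabilities per measure and Venn region counts."""

    pairwise: dict  #: measure -> DataFrame P(row > column)
    venn_correct: dict  #: 7 region counts for correctly classified cases
    venn_misclassified: dict


def venn_counts(correctness: dict[str, set]) -> dict[str, int]:
    """Region counts of a 3-set Venn diagram from named case-id sets.

    ``correctness`` maps exactly three classifier names to sets of case ids;
    keys of the result use ``"A"``, ``"B"``, ``"C"`` in the sorted order of
    the classifier names (``"A_only", "AB", ..., "ABC"``).
    """
    if len(correctness) != 3:
        raise ValueError("need exactly three classifiers")
    names = sorted(correctness)
    a, b, c = (set(correctness[n]) for n in names)
    return {
        "names": names,
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }


def compare_classifiers(
    reports: dict[str, CVReport],
    measures: tuple = ("AUC", "CA", "precision", "sensitivity", "specificity", "F1"),
) -> ComparisonReport:
    """Full pairwise comparison of cross-validated classifiers."""
    names = list(reports)
    if len(names) != 3:
        raise ValueError("comparison is defined for exactly three classifiers")
    ids = set(reports[names[0]].predictions.index)
    for name in names[1:]:
        if set(reports[name].predictions.index) != ids:
            raise ValueError("classifiers were evaluated on different cases")
    pairwise = {}
    for measure in measures:
        table = pd.DataFrame(np.nan, index=names, columns=names)
        for row in names:
            for col in names:
                if row != col:
                    table.loc[row, col] = compare_bayesian(
                        reports[row].fold_scores(measure),
                        reports[col].fold_scores(measure),
                    )
        pairwise[measure] = table
    correct, wrong = {}, {}
    for name in names:
        preds = reports[name].predictions
        ok = preds["label"] == preds["predicted"]
        correct[name] = set(preds.index[ok])
        wrong[name] = set(preds.index[~ok])
    return ComparisonReport(
        pairwise=pairwise,
        venn_correct=venn_counts(correct),
        venn_misclassified=venn_counts(wrong),
    )
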