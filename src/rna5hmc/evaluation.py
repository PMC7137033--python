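"""Evaluation: confusion metrics, stratified k-fold CV, ROC/PR/AUC, and
position-wise nucleotide enrichment.

Metrics are the standard four: sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP), accuracy ACC = (TP+TN)/N, and the Matthews correlation
coefficient.  Per-fold metrics are averaged arithmetically; ROC/PR curves are
computed on the held-out scores pooled across folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from rna5hmc import feature_selection, model as model_mod
from rna5hmc.feature_encoding import DESCRIPTORS, encode_dataset
from rna5hmc.feature_selection import SelectionResult
from rna5hmc.model import ModelConfig, classify, predict_scores, train
from rna5hmc.sequence_io import LabeledDataset, SiteWindow


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    per_fold: list[dict[str, float | None]]
    mean: dict[str, float | None]
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    pr_points: np.ndarray  # (n, 2) columns recall, precision
    auc: float
    selection: SelectionResult | None = None
    pooled_scores: np.ndarray | None = None
    pooled_labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "mean": self.mean,
            "auc": self.auc,
            "n_folds": len(self.per_fold),
        }


def confusion(predicted: Sequence[int], actual: Sequence[int]) -> ConfusionCounts:
    """Confusion counts for binary predictions against binary truth."""
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.shape != act.shape:
        raise ValueError("predicted and actual must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (act == 1))),
        TN=int(np.sum((pred == 0) & (act == 0))),
        FP=int(np.sum((pred == 1) & (act == 0))),
        FN=int(np.sum((pred == 0) & (act == 1))),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sn, Sp, ACC, MCC from confusion counts.

    A zero factor in the MCC denominator yields MCC = 0 (standard
    convention); an undefined Sn or Sp (empty class) is reported as None
    rather than 0.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    n = counts.total
    if n == 0:
        raise ValueError("all-zero confusion counts")
    sn = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / n
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {"Sn": sn, "Sp": sp, "ACC": acc, "MCC": mcc}


def stratified_kfold(
    labels: Sequence[int], k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Disjoint, seeded, stratified fold index sets covering all samples."""
    y = np.asarray(labels)
    for c in np.unique(y):
        if (y == c).sum() < k:
            raise ValueError(f"class {c} has fewer than k={k} members")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in splitter.split(np.zeros(len(y)), y)]


def roc_pr_auc(
    scores: Sequence[float], actual: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points, PR points, and trapezoidal ROC AUC from a threshold sweep.

    Tied scores are grouped (one sweep point per distinct score); the ROC
    starts at (0, 0) and ends at (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(actual)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    roc_points = np.column_stack([fpr, tpr])
    pr_points = np.column_stack([recall[::-1], precision[::-1]])
    return roc_points, pr_points, auc


def _mean_metrics(per_fold: list[dict[str, float | None]]) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for key in ("Sn", "Sp", "ACC", "MCC"):
        vals = [m[key] for m in per_fold if m[key] is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


def cross_validate(
    dataset: LabeledDataset,
    descriptors: Sequence[str] = DESCRIPTORS,
    selection: str | Sequence[int] | None = None,
    model_config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
    nested: bool = False,
    grid: bool = False,
    sfs_step: int = 10,
    sfs_refine: bool = False,
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full pipeline.

    ``selection`` may be ``"sfs"`` (run ANOVA ranking + SFS), an explicit
    feature index set, or None (use all columns of the chosen descriptors).
    By default SFS runs once on the full dataset before the folds — this
    replicates the original protocol but leaks selection information into the
    estimate; ``nested=True`` reruns ranking + SFS inside each training fold
    for an honest estimate.  With ``grid=True`` the (C, gamma) grid search is
    run per training fold; otherwise the fixed hyperparameters of
    ``model_config`` are used.
    """
    if model_config is None:
        model_config = ModelConfig(seed=seed)
    matrix = encode_dataset(dataset, descriptors)
    X = matrix.values
    y = np.asarray(dataset.labels)

    fixed_cols: np.ndarray | None = None
    selection_result: SelectionResult | None = None
    run_sfs = isinstance(selection, str) and selection == "sfs"
    if selection is not None and not run_sfs:
        fixed_cols = np.asarray(list(selection), dtype=int)
    if run_sfs and not nested:
        f = feature_selection.anova_f_values(X, y)
        ranking = feature_selection.rank_features(f)
        selection_result = feature_selection.sfs_select(
            X, y, ranking, step=sfs_step, model_config=model_config, seed=seed,
            refine=sfs_refine,
        )
        fixed_cols = selection_result.optimal_indices

    folds = stratified_kfold(y, k=k, seed=seed)
    all_idx = np.arange(len(y))
    per_fold: list[dict[str, float | None]] = []
    pooled_scores = np.empty(len(y))
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            raise ValueError("a fold's training part is single-class")

        cols = fixed_cols
        if run_sfs and nested:
            f = feature_selection.anova_f_values(X[train_idx], y_train)
            ranking = feature_selection.rank_features(f)
            sel = feature_selection.sfs_select(
                X[train_idx], y_train, ranking, step=sfs_step,
                model_config=model_config, seed=seed, refine=sfs_refine,
            )
            cols = sel.optimal_indices
        if cols is None:
            cols = np.arange(X.shape[1])

        X_train, X_test = X[np.ix_(train_idx, cols)], X[np.ix_(test_idx, cols)]
        c, g = None, None
        if grid:
            c, g, _ = model_mod.grid_search(X_train, y_train, model_config, cv_folds=k)
        fitted = train(X_train, y_train, model_config, c=c, gamma=g)
        scores = predict_scores(fitted, X_test)
        pooled_scores[test_idx] = scores
        per_fold.append(metrics(confusion(classify(scores, threshold), y[test_idx])))

    roc_points, pr_points, auc = roc_pr_auc(pooled_scores, y)
    return EvalReport(
        per_fold=per_fold,
        mean=_mean_metrics(per_fold),
        roc_points=roc_points,
        pr_points=pr_points,
        auc=auc,
        selection=selection_result,
        pooled_scores=pooled_scores,
        pooled_labels=y,
    )


def position_enrichment(
    positives: Sequence[SiteWindow], negatives: Sequence[SiteWindow]
) -> pd.DataFrame:
    """Per-position, per-nucleotide frequency comparison of two window sets.

    For each (1-based position, nucleotide): frequency in positives, in
    negatives, their difference, a two-proportion z-test p-value, and the
    Bonferroni-adjusted p-value across all L x 4 tests.
    """
    if not positives or not negatives:
        raise ValueError("both window sets must be non-empty")
    L = len(positives[0].seq)
    if any(len(w.seq) != L for w in positives) or any(len(w.seq) != L for w in negatives):
        raise ValueError("all windows must share one length")

    n_pos, n_neg = len(positives), len(negatives)
    rows = []
    n_tests = L * 4
    for p in range(L):
        for nt in "ACGU":
            k_pos = sum(1 for w in positives if w.seq[p] == nt)
            k_neg = sum(1 for w in negatives if w.seq[p] == nt)
            f_pos, f_neg = k_pos / n_pos, k_neg / n_neg
            pooled = (k_pos + k_neg) / (n_pos + n_neg)
            se = math.sqrt(pooled * (1 - pooled) * (1 / n_pos + 1 / n_neg))
            if se == 0:
                p_value = 1.0
            else:
                z = (f_pos - f_neg) / se
                p_value = float(2 * norm.sf(abs(z)))
            rows.append(
                {
                    "position": p + 1,
                    "nucleotide": nt,
                    "freq_pos": f_pos,
                    "freq_neg": f_neg,
                    "difference": f_pos - f_neg,
                    "p_value": p_value,
                    "p_bonferroni": min(1.0, p_value * n_tests),
                }
            )
    return pd.DataFrame(rows)
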