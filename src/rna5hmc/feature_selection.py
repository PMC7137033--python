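"""Two-stage feature-space optimization.

Stage one ranks features by the one-way ANOVA F-value (between-class mean
square over within-class mean square, df_B = K - 1, df_W = N - K).  Stage two
runs a sequential forward search over nested prefixes of the ranking, scoring
each prefix by mean cross-validated accuracy on a fixed fold partition and
keeping the smallest prefix that attains the maximum accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from rna5hmc.feature_encoding import FeatureMatrix


@dataclass(frozen=True)
class FeatureRanking:
    """Permutation of feature indices in descending F-value order.

    Ties are broken by ascending original index.  Features that separate the
    classes perfectly (zero within-class variance, nonzero between-class
    variance) carry the +inf sentinel and rank above all finite values.
    """

    order: np.ndarray
    f_values: np.ndarray

    def __post_init__(self) -> None:
        order = np.asarray(self.order)
        if sorted(order.tolist()) != list(range(len(order))):
            raise ValueError("order is not a permutation")


@dataclass
class SelectionResult:
    """SFS trajectory and the chosen optimal prefix."""

    trajectory: list[tuple[int, float]]  # (prefix size, mean CV accuracy)
    optimal_indices: np.ndarray  # prefix of the ranking order
    optimal_acc: float

    @property
    def optimal_size(self) -> int:
        return len(self.optimal_indices)

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory, columns=["n_features", "cv_accuracy"])


def anova_f_values(matrix: FeatureMatrix | np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """Per-feature one-way ANOVA F-values for a binary-labeled sample matrix.

    F = MSB / MSW with MSB = SSB/(K-1) and MSW = SSW/(N-K).  Features constant
    within each group but differing between groups get +inf; globally constant
    features get 0.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    K = len(classes)
    N = len(y)
    if X.shape[0] != N:
        raise ValueError("matrix rows and labels length mismatch")
    counts = np.array([(y == c).sum() for c in classes])
    if np.any(counts < 2):
        raise ValueError("each class needs at least 2 samples")

    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c, n_c in zip(classes, counts):
        Xc = X[y == c]
        mean_c = Xc.mean(axis=0)
        ssb += n_c * (mean_c - grand) ** 2
        ssw += ((Xc - mean_c) ** 2).sum(axis=0)

    msb = ssb / (K - 1)
    msw = ssw / (N - K)
    f = np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        nonzero_w = msw > 0
        f[nonzero_w] = msb[nonzero_w] / msw[nonzero_w]
        # zero within-class variance: perfectly separating -> +inf sentinel;
        # globally constant (msb == 0 too) -> 0
        f[~nonzero_w & (msb > 0)] = np.inf
    return f


def rank_features(f_values: np.ndarray) -> FeatureRanking:
    """Stable descending sort of F-values; ties resolved by ascending index."""
    f = np.asarray(f_values, dtype=float)
    order = np.lexsort((np.arange(len(f)), -f))
    return FeatureRanking(order=order, f_values=f)


def report_top_features(
    ranking: FeatureRanking, names: Sequence[str], top_n: int
) -> pd.DataFrame:
    """Importance table of the ``top_n`` highest-F features (name, F-value)."""
    if top_n > len(names):
        raise ValueError("top_n exceeds the number of features")
    idx = ranking.order[:top_n]
    return pd.DataFrame(
        {
            "rank": np.arange(1, top_n + 1),
            "feature": [names[i] for i in idx],
            "f_value": ranking.f_values[idx],
        }
    )


def _prefix_sizes(n_features: int, step: int) -> list[int]:
    sizes = list(range(step, n_features + 1, step))
    if not sizes or sizes[-1] != n_features:
        sizes.append(n_features)
    return sizes


def sfs_select(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    ranking: FeatureRanking,
    step: int = 10,
    cv_folds: int = 5,
    model_config: "ModelConfig | None" = None,
    seed: int = 0,
    refine: bool = False,
) -> SelectionResult:
    """Sequential forward search over nested prefixes of the ranking.

    Prefixes of sizes step, 2*step, ..., plus the full dimension are each
    scored by mean CV accuracy of the classifier on one fixed seeded fold
    partition, so scores are comparable across prefixes.  The smallest prefix
    attaining the maximum accuracy wins.  With ``refine``, a second step-1
    pass scans the +/-(step-1) neighborhood of the coarse optimum (the
    stated coarse schedule cannot land on sizes between grid points).
    """
    from rna5hmc.model import ModelConfig, make_estimator  # local: avoid cycle

    if step < 1:
        raise ValueError("step must be >= 1")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if model_config is None:
        model_config = ModelConfig(seed=seed)
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    n_features = X.shape[1]

    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(X, y))  # fixed across all prefix evaluations

    def score_prefix(size: int) -> float:
        cols = ranking.order[:size]
        accs = []
        for train_idx, test_idx in folds:
            est = make_estimator(model_config)
            est.fit(X[np.ix_(train_idx, cols)], y[train_idx])
            accs.append(float(np.mean(est.predict(X[np.ix_(test_idx, cols)]) == y[test_idx])))
        return float(np.mean(accs))

    scores: dict[int, float] = {}
    for size in _prefix_sizes(n_features, step):
        scores[size] = score_prefix(size)

    def best_size() -> int:
        best = max(scores.values())
        return min(s for s, a in scores.items() if a == best)

    if refine and step > 1:
        center = best_size()
        lo = max(1, center - step + 1)
        hi = min(n_features, center + step - 1)
        for size in range(lo, hi + 1):
            if size not in scores:
                scores[size] = score_prefix(size)

    trajectory = sorted(scores.items())
    opt = best_size()
    return SelectionResult(
        trajectory=[(s, a) for s, a in trajectory],
        optimal_indices=ranking.order[:opt].copy(),
        optimal_acc=scores[opt],
    )
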