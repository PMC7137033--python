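"""RBF-kernel SVM with grid-searched hyperparameters and calibrated scores.

The classifier searches integer powers of two for the penalty C
(log2 C in -2..5) and kernel width gamma (log2 gamma in -5..2) by mean CV
accuracy on a fixed seeded partition.  Scores are probability-like (Platt-style
sigmoid calibration, the default) so the 0.5 decision threshold is meaningful;
with calibration off, raw margins are min-max mapped onto [0, 1] using the
training margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from rna5hmc.feature_encoding import FeatureMatrix

MODEL_FORMAT_VERSION = 1

VALID_KERNELS = ("rbf", "poly", "polynomial", "sigmoid")

_SKLEARN_KERNEL = {"rbf": "rbf", "poly": "poly", "polynomial": "poly", "sigmoid": "sigmoid"}


@dataclass(frozen=True)
class ModelConfig:
    kernel: str = "rbf"
    log2_c_range: tuple[int, int] = (-2, 5)  # inclusive
    log2_g_range: tuple[int, int] = (-5, 2)  # inclusive
    probability_calibration: bool = True
    standardize: bool = True
    seed: int = 0
    # fixed hyperparameters used when no grid search is requested
    c: float = 1.0
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.kernel not in VALID_KERNELS:
            raise ValueError(f"kernel must be one of {VALID_KERNELS}")
        for lo, hi in (self.log2_c_range, self.log2_g_range):
            if hi < lo:
                raise ValueError("hyperparameter ranges must be non-empty")


@dataclass
class TrainedModel:
    config: ModelConfig
    c: float
    gamma: float | str
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    # training-margin extremes, for the no-calibration score mapping
    margin_range: tuple[float, float] | None = None

    def _check_names(self, names: Sequence[str]) -> None:
        if tuple(names) != self.feature_names:
            raise ValueError("feature names differ from the training feature names")


def make_estimator(
    config: ModelConfig,
    c: float | None = None,
    gamma: float | str | None = None,
    probability: bool = False,
) -> Pipeline:
    """Standardization (optional) + SVC pipeline, deterministic under the seed.

    ``probability`` is off by default: selection and grid search only need
    hard predictions, and the Platt calibration fit is ~5x the cost.
    """
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    svc_kwargs = dict(
        kernel=_SKLEARN_KERNEL[config.kernel],
        C=config.c if c is None else c,
        gamma=config.gamma if gamma is None else gamma,
        random_state=config.seed,
    )
    if probability:
        # only set explicitly when needed: sklearn >= 1.9 warns on any
        # explicit value while the parameter is in its deprecation window
        svc_kwargs["probability"] = True
    steps.append(("svc", SVC(**svc_kwargs)))
    return Pipeline(steps)


def grid_search(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    config: ModelConfig | None = None,
    cv_folds: int = 5,
) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive (C, gamma) search over 2**i x 2**j by mean CV accuracy.

    Returns the best (c, gamma) — ties resolved toward smaller c, then
    smaller gamma — plus the full accuracy grid for inspection.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if config is None:
        config = ModelConfig()
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    y = np.asarray(labels)

    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=config.seed)
    folds = list(splitter.split(X, y))

    rows = []
    best: tuple[float, float, float] | None = None  # (acc, c, g)
    for i in range(config.log2_c_range[0], config.log2_c_range[1] + 1):
        for j in range(config.log2_g_range[0], config.log2_g_range[1] + 1):
            c, g = 2.0**i, 2.0**j
            accs = []
            for train_idx, test_idx in folds:
                est = make_estimator(config, c=c, gamma=g)
                est.fit(X[train_idx], y[train_idx])
                accs.append(float(np.mean(est.predict(X[test_idx]) == y[test_idx])))
            acc = float(np.mean(accs))
            rows.append({"log2_c": i, "log2_g": j, "c": c, "gamma": g, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, c, g)
    grid = pd.DataFrame(rows)
    assert best is not None
    return best[1], best[2], grid


def train(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    config: ModelConfig | None = None,
    c: float | None = None,
    gamma: float | str | None = None,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the classifier on the full given training data.

    Standardization parameters are learned from this data only; refitting with
    the same seed reproduces identical predictions.
    """
    if config is None:
        config = ModelConfig()
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        names = matrix.names if feature_names is None else tuple(feature_names)
    else:
        X = np.asarray(matrix, dtype=float)
        names = tuple(feature_names) if feature_names is not None else tuple(
            f"f{i}" for i in range(X.shape[1])
        )
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    pipeline = make_estimator(config, c=c, gamma=gamma, probability=config.probability_calibration)
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates SVC(probability=True); the replacement
        # (CalibratedClassifierCV) changes the internal CV/calibration scheme,
        # so keep the classic Platt fit while it exists.
        warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")
        pipeline.fit(X, y)

    margin_range = None
    if not config.probability_calibration:
        margins = pipeline.decision_function(X)
        margin_range = (float(margins.min()), float(margins.max()))
    return TrainedModel(
        config=config,
        c=float(pipeline.named_steps["svc"].C),
        gamma=pipeline.named_steps["svc"].gamma,
        pipeline=pipeline,
        feature_names=names,
        margin_range=margin_range,
    )


def predict_scores(
    model: TrainedModel,
    matrix: FeatureMatrix | np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Score each row in [0, 1]; higher means more likely a true site."""
    if isinstance(matrix, FeatureMatrix):
        model._check_names(matrix.names)
        X = matrix.values
    else:
        X = np.asarray(matrix, dtype=float)
        if feature_names is not None:
            model._check_names(feature_names)
        elif X.shape[1] != len(model.feature_names):
            raise ValueError("feature dimension differs from the training dimension")
    if model.config.probability_calibration:
        classes = list(model.pipeline.named_steps["svc"].classes_)
        return model.pipeline.predict_proba(X)[:, classes.index(1)]
    lo, hi = model.margin_range  # type: ignore[misc]
    margins = model.pipeline.decision_function(X)
    if hi == lo:
        return np.full(len(margins), 0.5)
    return np.clip((margins - lo) / (hi - lo), 0.0, 1.0)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strictly-greater-than thresholding: score > threshold -> positive (1)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    return (scores > threshold).astype(int)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize to a single versioned archive file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": asdict(model.config),
        "c": model.c,
        "gamma": model.gamma,
        "pipeline": model.pipeline,
        "feature_names": model.feature_names,
        "margin_range": model.margin_range,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive format version {version!r} != supported {MODEL_FORMAT_VERSION}"
        )
    cfg = payload["config"]
    cfg["log2_c_range"] = tuple(cfg["log2_c_range"])
    cfg["log2_g_range"] = tuple(cfg["log2_g_range"])
    return TrainedModel(
        config=ModelConfig(**cfg),
        c=payload["c"],
        gamma=payload["gamma"],
        pipeline=payload["pipeline"],
        feature_names=tuple(payload["feature_names"]),
        margin_range=payload["margin_range"],
    )
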