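"""Random-forest classification of bins as phage or bacterial.

The model is an ensemble of 50 decision trees (configurable) over the
three core features, with leaf pruning realised as a minimum number of
samples per leaf (default 2) — the lightest-touch regulariser consistent
with otherwise-default forest parameters.  Feature importances are mean
impurity decrease, normalised to sum to 1; they approximate the
information-gain weighting of an ID3-style forest while using CART trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import CORE_FEATURE_NAMES

DEFAULT_N_TREES = 50
DEFAULT_LEAF_MIN = 2
DEFAULT_DECISION_THRESHOLD = 0.5
MODEL_SCHEMA_VERSION = 1

PHAGE, BACTERIA = "phage", "bacteria"


class ModelFormatError(RuntimeError):
    """A persisted model could not be loaded or is incompatible."""


@dataclass(frozen=True)
class Prediction:
    bin_id: str
    phage_probability: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.phage_probability <= 1.0:
            raise ValueError("phage_probability must be in [0, 1]")
        if self.label not in (PHAGE, BACTERIA):
            raise ValueError(f"label must be {PHAGE!r} or {BACTERIA!r}")


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to reapply it."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    training_seed: int
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD

    @property
    def importances(self) -> np.ndarray:
        imp = self.forest.feature_importances_
        total = imp.sum()
        return imp / total if total > 0 else imp

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators


def _as_matrix(features, feature_names) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValueError(
            f"feature matrix must have {len(feature_names)} columns "
            f"({', '.join(feature_names)}); got shape {X.shape}"
        )
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    return X


def train(
    features,
    labels: Sequence[str],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    leaf_min: int = DEFAULT_LEAF_MIN,
    feature_names: Sequence[str] = CORE_FEATURE_NAMES,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> TrainedModel:
    """Fit the forest on labelled feature rows.

    ``labels`` are ``"phage"``/``"bacteria"`` strings; both classes must
    be present with at least two rows each.  A fixed seed makes the model
    bit-reproducible.
    """
    feature_names = tuple(feature_names)
    X = _as_matrix(features, feature_names)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"training requires both classes; got only {classes.tolist()}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training rows")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        min_samples_leaf=leaf_min,
        random_state=seed,
    )
    forest.fit(X, y)
    return TrainedModel(
        forest=forest,
        feature_names=feature_names,
        training_seed=seed,
        decision_threshold=decision_threshold,
    )


def predict(model: TrainedModel, features, bin_ids: Sequence[str] | None = None) -> list[Prediction]:
    """Apply a trained model; probability is the fraction of trees voting phage."""
    X = _as_matrix(features, model.feature_names)
    if bin_ids is None:
        bin_ids = [f"bin_{i}" for i in range(len(X))]
    phage_col = list(model.forest.classes_).index(PHAGE)
    probs = model.forest.predict_proba(X)[:, phage_col]
    return [
        Prediction(
            bin_id=bid,
            phage_probability=float(p),
            label=PHAGE if p >= model.decision_threshold else BACTERIA,
        )
        for bid, p in zip(bin_ids, probs)
    ]


def cross_validate(
    features,
    labels: Sequence[str],
    k: int = 20,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    leaf_min: int = DEFAULT_LEAF_MIN,
) -> dict:
    """Stratified k-fold cross-validation (default k = 20).

    Returns per-fold metrics (from the benchmark scorer, phage positive)
    plus their mean and standard deviation.
    """
    from .simulation_benchmark import ConfusionCounts, score

    X = _as_matrix(features, CORE_FEATURE_NAMES)
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} rows, too few for k={k}; use smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(X, y):
        m = train(X[train_idx], y[train_idx], n_trees=n_trees, seed=seed, leaf_min=leaf_min)
        preds = predict(m, X[test_idx])
        truth = y[test_idx]
        tp = sum(p.label == PHAGE and t == PHAGE for p, t in zip(preds, truth))
        fp = sum(p.label == PHAGE and t == BACTERIA for p, t in zip(preds, truth))
        tn = sum(p.label == BACTERIA and t == BACTERIA for p, t in zip(preds, truth))
        fn = sum(p.label == BACTERIA and t == PHAGE for p, t in zip(preds, truth))
        folds.append(score(ConfusionCounts(tp, fp, tn, fn), allow_undefined=True))
    agg = {}
    for name in ("TPR", "SPC", "ACC", "F1"):
        vals = np.array([getattr(f, name) for f in folds], dtype=float)
        vals = vals[~np.isnan(vals)]
        agg[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return {"folds": folds, "aggregate": agg, "k": k}


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "forest": model.forest,
        "feature_names": model.feature_names,
        "training_seed": model.training_seed,
        "decision_threshold": model.decision_threshold,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ModelFormatError(f"{path}: not a model archive (no schema_version)")
    if payload["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ModelFormatError(
            f"{path}: schema version {payload['schema_version']} "
            f"incompatible with supported version {MODEL_SCHEMA_VERSION}"
        )
    return TrainedModel(
        forest=payload["forest"],
        feature_names=tuple(payload["feature_names"]),
        training_seed=payload["training_seed"],
        decision_threshold=payload["decision_threshold"],
    )
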