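"""Gradient-boosted true/false variant classification.

The filter is an XGBoost binary-probability booster trained on labeled
feature vectors exactly as assembled — the natural class imbalance of a
call set is part of the signal and is never rebalanced.  Missing feature
values (NaN) are consumed natively by the tree learner.  A call is
FILTERED when its probability of being a true variant is strictly below
the threshold (default 0.5).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xgboost as xgb

from fvc.features import FEATURE_NAMES, FeatureVector
from fvc.truthset import LabeledExample

RETAINED = "RETAINED"
FILTERED = "FILTERED"

DEFAULT_PARAMS: dict = {
    "objective": "binary:logistic",
    "eval_metric": "logloss",
    "tree_method": "hist",
    "nthread": 1,
}
DEFAULT_NUM_ROUNDS = 100


def _schema_hash(schema: list[str]) -> str:
    return hashlib.sha256("\n".join(schema).encode()).hexdigest()[:16]


@dataclass
class FilterModel:
    """A trained booster plus the metadata needed to apply it safely."""

    booster: xgb.Booster
    schema: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    threshold: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if len(self.schema) != len(FEATURE_NAMES):
            raise ValueError(f"schema must list {len(FEATURE_NAMES)} features")

    def save(self, path: str | Path) -> Path:
        """Serialize to a portable single-file JSON bundle."""
        bundle = {
            "format": "fvc-model-bundle",
            "version": 1,
            "schema": self.schema,
            "schema_hash": _schema_hash(self.schema),
            "threshold": self.threshold,
            "meta": self.meta,
            "booster": json.loads(self.booster.save_raw("json").decode()),
        }
        path = Path(path)
        path.write_text(json.dumps(bundle))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FilterModel":
        bundle = json.loads(Path(path).read_text())
        if bundle.get("format") != "fvc-model-bundle":
            raise ValueError(f"{path}: not a model bundle")
        if _schema_hash(bundle["schema"]) != bundle["schema_hash"]:
            raise ValueError(f"{path}: schema hash mismatch — corrupted bundle")
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(bundle["booster"]).encode()))
        return cls(booster=booster, schema=bundle["schema"],
                   threshold=bundle["threshold"], meta=bundle["meta"])


def examples_to_matrix(examples: list[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into (X, y) with NaN encoding missing values."""
    X = np.array([ex.features.as_array() for ex in examples], dtype=float)
    y = np.array([1.0 if ex.label else 0.0 for ex in examples], dtype=float)
    return X, y


def train(examples: list[LabeledExample], params: dict | None = None,
          seed: int = 0, num_rounds: int = DEFAULT_NUM_ROUNDS,
          threshold: float = 0.5) -> FilterModel:
    """Train the filter on labeled examples, imbalance preserved.

    Deterministic for a fixed seed and parameter set.  Raises on
    single-class input or NaN labels.
    """
    if not examples:
        raise ValueError("no training examples")
    X, y = examples_to_matrix(examples)
    if np.isnan(y).any():
        raise ValueError("NaN labels in training data")
    n_true, n_false = int(y.sum()), int((1 - y).sum())
    if n_true == 0 or n_false == 0:
        raise ValueError(
            f"training data must contain both classes (true={n_true}, false={n_false})")

    merged = dict(DEFAULT_PARAMS)
    if params:
        merged.update(params)
    merged["seed"] = int(seed)
    dtrain = xgb.DMatrix(X, label=y, feature_names=FEATURE_NAMES, missing=np.nan)
    booster = xgb.train(merged, dtrain, num_boost_round=num_rounds)
    meta = {
        "seed": int(seed),
        "params": {k: v for k, v in merged.items()},
        "num_rounds": num_rounds,
        "n_true": n_true,
        "n_false": n_false,
        "sample_ids": sorted({ex.sample_id for ex in examples}),
        "source_caller": None,
        "n_examples": len(examples),
    }
    return FilterModel(booster=booster, schema=list(FEATURE_NAMES),
                       threshold=threshold, meta=meta)


def _check_schema(model: FilterModel, fv: FeatureVector) -> None:
    have = set(fv.values)
    want = set(model.schema)
    if have != want:
        raise ValueError(
            f"feature schema mismatch: missing={sorted(want - have)} "
            f"extra={sorted(have - want)}")


def score_batch(model: FilterModel, vectors: list[FeatureVector],
                source_caller: str | None = None) -> np.ndarray:
    """Probability of being a true variant for each vector, in order."""
    for fv in vectors:
        _check_schema(model, fv)
    trained_on = model.meta.get("source_caller")
    if source_caller and trained_on and source_caller != trained_on:
        warnings.warn(
            f"model was trained on {trained_on} calls but is scoring "
            f"{source_caller} calls; per-pipeline models are recommended",
            UserWarning, stacklevel=2)
    if not vectors:
        return np.empty(0)
    X = np.array([fv.as_array() for fv in vectors], dtype=float)
    dm = xgb.DMatrix(X, feature_names=model.schema, missing=np.nan)
    return np.clip(model.booster.predict(dm), 0.0, 1.0)


def score(model: FilterModel, fv: FeatureVector) -> float:
    """Probability in [0, 1] that one call is a true variant."""
    return float(score_batch(model, [fv])[0])


def classify(score_value: float, threshold: float = 0.5) -> str:
    """FILTERED iff score < threshold (strict); boundary scores are retained."""
    if not (0.0 <= score_value <= 1.0):
        raise ValueError(f"score {score_value} outside [0, 1]")
    if math.isnan(score_value):
        raise ValueError("score is NaN")
    return FILTERED if score_value < threshold else RETAINED


def feature_importance(model: FilterModel) -> list[tuple[str, float]]:
    """All 20 features ranked by gain, descending; untouched features get
    importance 0; ties broken by schema order."""
    if model.booster is None:
        raise ValueError("model has no trained booster")
    raw = model.booster.get_score(importance_type="gain")
    order = {name: i for i, name in enumerate(model.schema)}
    pairs = [(name, float(raw.get(name, 0.0))) for name in model.schema]
    pairs.sort(key=lambda p: (-p[1], order[p[0]]))
    return pairs
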