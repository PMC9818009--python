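"""Welfare-state prediction from acoustic feature vectors.

Two routes are provided:

* the fixed decision-rule tree distilled from the broiler-chick study
  (root split on the mass-normalized energy unit, then flock size, then
  spectral centroid), and
* retrainable classifiers (kNN, decision tree, random forest) over the
  four attributes (bird weight, number of chicks, energy unit, spectral
  centroid) with a stratified train/test split.

The rule tree never consults the bird weight: only attributes that help
the classification enter the rules.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from . import labels

#: attribute order the trained models consume
FEATURE_COLUMNS = ["weight_kg", "n_chicks", "energy_unit_kcal_per_kg", "centroid"]

#: aliases accepted when classifying loose mappings with the rule tree
_RULE_KEYS = {
    "energy_unit": ("energy_unit", "energy_unit_kcal_per_kg"),
    "n_chicks": ("n_chicks",),
    "centroid": ("centroid", "centroid_khz"),
}


@dataclass(frozen=True)
class FeatureVector:
    """One classification instance."""

    weight: float
    n_chicks: int
    energy_unit: float
    centroid: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive (kg/bird)")
        if self.n_chicks < 1:
            raise ValueError("n_chicks must be >= 1")
        if self.energy_unit < 0:
            raise ValueError("energy_unit must be non-negative")


@dataclass(frozen=True)
class RuleTree:
    """Thresholds of the printed welfare decision rules.

    energy unit above ``energy_threshold`` kcal/kg marks distress; else a
    flock above ``n_chicks_threshold`` birds is normal; else a spectral
    centroid above ``centroid_threshold`` (kHz convention) marks distress
    and at or below it normal. All comparisons are strict, so boundary
    values fall to the else branch.
    """

    energy_threshold: float = 0.203
    n_chicks_threshold: float = 6
    centroid_threshold: float = 2.03

    def __post_init__(self) -> None:
        for name in ("energy_threshold", "n_chicks_threshold", "centroid_threshold"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")


def _rule_value(f: Any, key: str) -> float:
    if isinstance(f, FeatureVector):
        return float(getattr(f, key))
    for alias in _RULE_KEYS[key]:
        if isinstance(f, Mapping) and alias in f:
            v = f[alias]
        elif isinstance(f, pd.Series) and alias in f.index:
            v = f[alias]
        else:
            continue
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            raise ValueError(f"attribute {alias!r} is missing or not finite")
        return float(v)
    raise ValueError(f"feature vector is missing required attribute {key!r}")


def rule_tree_classify(f: FeatureVector | Mapping | pd.Series, tree: RuleTree = RuleTree()) -> str:
    """Apply the decision rules to one instance.

    Bird weight is intentionally not consulted.
    """
    if _rule_value(f, "energy_unit") > tree.energy_threshold:
        return labels.DISTRESS
    if _rule_value(f, "n_chicks") > tree.n_chicks_threshold:
        return labels.NORMAL
    if _rule_value(f, "centroid") > tree.centroid_threshold:
        return labels.DISTRESS
    return labels.NORMAL


def rule_tree_classify_table(table: pd.DataFrame, tree: RuleTree = RuleTree()) -> pd.Series:
    """Vectorized convenience over a feature table."""
    return pd.Series(
        [rule_tree_classify(row, tree) for _, row in table.iterrows()],
        index=table.index,
        name="predicted_label",
    )


_METHODS = ("knn", "decision_tree", "random_forest")


def _build_estimator(method: str, seed: int, hyper: dict[str, Any]):
    if method == "knn":
        k = hyper.pop("n_neighbors", 5)
        return Pipeline(
            [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=k, **hyper))]
        )
    if method == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **hyper)
    if method == "random_forest":
        n = hyper.pop("n_estimators", 100)
        return RandomForestClassifier(n_estimators=n, random_state=seed, **hyper)
    raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")


@dataclass
class TrainedModel:
    """A fitted classifier plus its split descriptor."""

    method: str
    estimator: Any = field(repr=False)
    seed: int
    train_fraction: float
    feature_columns: list[str]
    train_index: np.ndarray = field(repr=False)
    test_index: np.ndarray = field(repr=False)
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> dict[str, Any]:
        return {
            "format_version": 1,
            "method": self.method,
            "seed": self.seed,
            "train_fraction": self.train_fraction,
            "feature_columns": self.feature_columns,
            "n_train": int(len(self.train_index)),
            "n_test": int(len(self.test_index)),
            "hyperparameters": self.hyperparameters,
        }

    def save_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def _feature_matrix(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s) {missing}")
    X = table[columns].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = [c for c in columns if not np.all(np.isfinite(table[c].to_numpy(dtype=float)))]
        raise ValueError(f"non-finite values in feature column(s) {bad}")
    return X


def train_classifier(
    table: pd.DataFrame,
    method: str = "random_forest",
    train_fraction: float = 0.8,
    seed: int = 0,
    **hyperparameters: Any,
) -> TrainedModel:
    """Fit a classifier on a labeled feature table.

    The split is stratified by class (preserving class proportions) and
    deterministic for a fixed seed. Requires at least 10 labeled rows with
    both welfare classes present; intermediate labels must be resolved
    first (see :func:`peepwatch.synth.binarize_labels`).
    """
    if "label" not in table.columns:
        raise ValueError("feature table has no 'label' column")
    y = table["label"].to_numpy()
    present = set(np.unique(y))
    unknown = present - set(labels.BINARY_LABELS)
    if unknown:
        raise ValueError(
            f"unresolved or unknown label(s) {sorted(unknown)}; "
            "resolve the intermediate class before training"
        )
    if len(table) < 10:
        raise ValueError("need at least 10 labeled rows to train")
    if len(present) < 2:
        raise ValueError("training requires both welfare classes to be present")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")

    X = _feature_matrix(table, FEATURE_COLUMNS)
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=y
    )
    hyper = dict(hyperparameters)
    estimator = _build_estimator(method, seed, dict(hyper))
    estimator.fit(X[train_idx], y[train_idx])
    return TrainedModel(
        method=method,
        estimator=estimator,
        seed=seed,
        train_fraction=train_fraction,
        feature_columns=list(FEATURE_COLUMNS),
        train_index=train_idx,
        test_index=test_idx,
        hyperparameters=hyper,
    )


def _as_matrix(m: TrainedModel, f: FeatureVector | Mapping | pd.Series | pd.DataFrame) -> np.ndarray:
    if isinstance(f, FeatureVector):
        return np.array([[f.weight, f.n_chicks, f.energy_unit, f.centroid]], dtype=float)
    if isinstance(f, pd.DataFrame):
        return _feature_matrix(f, m.feature_columns)
    if isinstance(f, pd.Series):
        f = f.to_dict()
    if isinstance(f, Mapping):
        row = {}
        for col in m.feature_columns:
            aliases = (col, "energy_unit") if col == "energy_unit_kcal_per_kg" else (col,)
            for a in aliases:
                if a in f:
                    row[col] = f[a]
                    break
            else:
                raise ValueError(f"feature vector is missing required attribute {col!r}")
        X = np.array([[row[c] for c in m.feature_columns]], dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("feature vector contains missing or non-finite values")
        return X
    raise TypeError(f"cannot build a feature matrix from {type(f).__name__}")


def predict(m: TrainedModel, f: FeatureVector | Mapping | pd.Series | pd.DataFrame):
    """Predict welfare class(es) for one instance or a table.

    Returns a single label for a single instance, or an array of labels
    for a DataFrame.
    """
    X = _as_matrix(m, f)
    out = m.estimator.predict(X)
    return out if isinstance(f, pd.DataFrame) else str(out[0])


def holdout_predictions(m: TrainedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Predictions on the model's held-out rows of the table it was split
    on, including the predicted distress probability."""
    test = table.iloc[m.test_index]
    X = _feature_matrix(test, m.feature_columns)
    y_pred = m.estimator.predict(X)
    proba = m.estimator.predict_proba(X)
    distress_col = list(m.estimator.classes_).index(labels.DISTRESS)
    return pd.DataFrame(
        {
            "row_id": m.test_index,
            "true_label": test["label"].to_numpy(),
            "predicted_label": y_pred,
            "prob_distress": proba[:, distress_col],
        }
    )
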