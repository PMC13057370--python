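"""Migration-state classification of T-cell morphometry.

The binary task merges the "attached" and "in process" stages (apical-side
cells) into one ``attached_process`` category against ``transmigrated``
(cells emerged below the endothelial monolayer); the legacy 3-class task
keeps them separate.  The classifier is a small multilayer perceptron —
an input layer, three dense hidden layers and a single sigmoid output unit
(softmax for the 3-class variant) — trained on standardized features with
early stopping.

Also provided:

* signed per-feature relevance (connection-weight products through the
  network, Olden-style), cross-checkable against permutation importance;
* supervised between-group analysis (BGA): principal axes of the
  size-weighted group centroids in standardized feature space, with the
  between-group variance fraction as a separability summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .morphometry import FEATURE_NAMES

__all__ = [
    "ATTACHED", "IN_PROCESS", "TRANSMIGRATED", "ATTACHED_PROCESS",
    "merge_to_binary",
    "MLPSpec", "TrainTestSplit", "EvaluationReport", "RelevanceReport",
    "MLPMigrationClassifier", "BetweenGroupOrdination",
    "split_train_test", "train", "predict", "evaluate",
    "feature_relevance", "bga_ordination",
]

ATTACHED = "attached"
IN_PROCESS = "in_process"
TRANSMIGRATED = "transmigrated"
ATTACHED_PROCESS = "attached_process"

_THREE_CLASS = (ATTACHED, IN_PROCESS, TRANSMIGRATED)


def merge_to_binary(labels) -> np.ndarray:
    """Deterministic merge attached + in_process -> attached_process."""
    labels = np.asarray(labels, dtype=object)
    out = np.where(np.isin(labels, (ATTACHED, IN_PROCESS)),
                   ATTACHED_PROCESS, labels)
    bad = set(out) - {ATTACHED_PROCESS, TRANSMIGRATED}
    if bad:
        raise ValueError(f"unknown migration labels: {sorted(bad)}")
    return out.astype(str)


@dataclass
class MLPSpec:
    """Architecture and training settings of the migration MLP.

    The network is input + exactly three dense hidden layers + one output
    unit (sigmoid) for the binary task or three (softmax) for the 3-class
    task.  Defaults: 64/32/16 rectified-linear hidden units, Adam at 1e-3,
    batch 32, up to 200 epochs with early stopping (patience 10) on an
    internal validation fold.
    """

    hidden_layers: tuple = (64, 32, 16)
    activation: str = "relu"
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(v) for v in self.hidden_layers)
        if len(self.hidden_layers) != 3:
            raise ValueError("the architecture uses exactly three hidden layers")
        if any(v < 1 for v in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")


@dataclass
class TrainTestSplit:
    train: pd.DataFrame
    test: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        if len(self.train) == 0 or len(self.test) == 0:
            raise ValueError("both split halves must be non-empty")
        if ("cell_id" in self.train.columns
                and set(self.train["cell_id"]) & set(self.test["cell_id"])):
            raise ValueError("train and test share cell_ids")


@dataclass
class EvaluationReport:
    """Confusion matrix (rows = true class) and derived accuracies."""

    confusion: pd.DataFrame
    per_class_accuracy: dict
    overall_accuracy: float
    n_test: int

    def to_json(self) -> str:
        return json.dumps({
            "confusion": self.confusion.to_dict(),
            "per_class_accuracy": self.per_class_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "n_test": self.n_test,
        }, indent=2)


@dataclass
class RelevanceReport:
    """Signed per-feature relevance; positive pushes toward 'transmigrated'."""

    table: pd.DataFrame          # feature, relevance, |relevance| rank, perm
    method: str
    sign_defined: bool

    def ranking(self) -> list:
        return self.table.sort_values(
            "relevance", key=np.abs, ascending=False)["feature"].tolist()


def _extract_xy(table: pd.DataFrame, feature_names, need_labels: bool):
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    X = table[list(feature_names)].to_numpy(dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    y = None
    if need_labels:
        if "class" not in table.columns:
            raise ValueError("table has no 'class' column")
        y = table["class"].to_numpy(dtype=object)
    return X, y


class MLPMigrationClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style MLP over morphometric features.

    Features are standardized with statistics fitted on the training rows
    only.  After :meth:`fit`, prediction runs through the package's own
    forward pass on the stored weight tensors, so a model reloaded from its
    JSON file replays predictions exactly.

    Parameters mirror :class:`MLPSpec`; fitted attributes carry trailing
    underscores (``classes_``, ``coefs_``, ``intercepts_``,
    ``scaler_mean_``, ``scaler_scale_``, ``training_history_``).
    """

    def __init__(self, hidden_layers=(64, 32, 16), activation="relu",
                 epochs=200, batch_size=32, learning_rate=1e-3,
                 early_stop_patience=10, random_state=0):
        self.hidden_layers = hidden_layers
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    # -- core API ----------------------------------------------------------
    def fit(self, X, y):
        X, y = self._coerce(X, y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        spec = MLPSpec(self.hidden_layers, self.activation, self.epochs,
                       self.batch_size, self.learning_rate,
                       self.early_stop_patience, self.random_state)
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        # early stopping needs an internal stratified validation fold; on
        # very small training sets that fold cannot hold every class, so
        # training falls back to the full epoch budget
        n_val = int(np.floor(0.1 * len(X)))
        class_counts = np.array([(y == c).sum() for c in classes])
        use_early_stop = n_val >= 2 * len(classes) and class_counts.min() >= 4
        net = MLPClassifier(
            hidden_layer_sizes=spec.hidden_layers,
            activation=spec.activation,
            solver="adam",
            learning_rate_init=spec.learning_rate,
            batch_size=min(spec.batch_size, len(X)),
            max_iter=spec.epochs,
            early_stopping=use_early_stop,
            n_iter_no_change=spec.early_stop_patience,
            validation_fraction=0.1,
            random_state=spec.seed,
        )
        net.fit(Xs, y)
        self.classes_ = net.classes_
        self.coefs_ = [w.copy() for w in net.coefs_]
        self.intercepts_ = [b.copy() for b in net.intercepts_]
        self.scaler_mean_ = scaler.mean_.copy()
        self.scaler_scale_ = scaler.scale_.copy()
        self.training_history_ = {
            "loss": list(map(float, net.loss_curve_)),
            "validation_score": (list(map(float, net.validation_scores_))
                                 if use_early_stop else []),
            "n_epochs": int(net.n_iter_),
        }
        self.out_activation_ = net.out_activation_
        return self

    def _coerce(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            feats = [c for c in FEATURE_NAMES if c in X.columns]
            if hasattr(self, "feature_names_in_"):
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise ValueError(f"missing feature columns: {missing}")
                feats = list(self.feature_names_in_)
            elif not feats:
                raise ValueError("DataFrame holds no known feature columns")
            else:
                self.feature_names_in_ = np.asarray(feats, dtype=object)
            if y is None and "class" in X.columns:
                y = X["class"].to_numpy(dtype=object)
            X = X[feats].to_numpy(dtype=np.float64)
        else:
            X = np.asarray(X, dtype=np.float64)
            if X.ndim != 2:
                raise ValueError("X must be 2-D")
            if not hasattr(self, "feature_names_in_"):
                self.feature_names_in_ = np.asarray(
                    [f"f{i}" for i in range(X.shape[1])], dtype=object)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        if y is not None:
            y = np.asarray(y, dtype=object)
        return X, y

    def _forward(self, X):
        act = (X - self.scaler_mean_) / self.scaler_scale_
        relu = self.activation == "relu"
        for i, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            act = act @ W + b
            if i < len(self.coefs_) - 1:
                act = np.maximum(act, 0.0) if relu else np.tanh(act)
        if act.shape[1] == 1:  # single sigmoid unit
            p1 = 1.0 / (1.0 + np.exp(-act[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        act -= act.max(axis=1, keepdims=True)
        e = np.exp(act)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X):
        check_is_fitted(self, "coefs_")
        X, _ = self._coerce(X)
        return self._forward(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        if proba.shape[1] == 2:
            # documented decision rule: P(positive class) >= 0.5
            return np.where(proba[:, 1] >= 0.5,
                            self.classes_[1], self.classes_[0])
        return self.classes_[np.argmax(proba, axis=1)]

    # -- persistence -------------------------------------------------------
    def to_json(self, path=None) -> str:
        check_is_fitted(self, "coefs_")
        payload = {
            "schema": "temflow-mlp/1",
            "params": self.get_params(),
            "feature_names": list(self.feature_names_in_),
            "classes": list(self.classes_),
            "scaler_mean": self.scaler_mean_.tolist(),
            "scaler_scale": self.scaler_scale_.tolist(),
            "coefs": [w.tolist() for w in self.coefs_],
            "intercepts": [b.tolist() for b in self.intercepts_],
            "training_history": self.training_history_,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MLPMigrationClassifier":
        if isinstance(source, Path) or (
                isinstance(source, str) and not source.lstrip().startswith("{")):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        if payload.get("schema") != "temflow-mlp/1":
            raise ValueError(f"unknown model schema {payload.get('schema')!r}")
        params = payload["params"]
        params["hidden_layers"] = tuple(params["hidden_layers"])
        model = cls(**params)
        model.feature_names_in_ = np.asarray(payload["feature_names"],
                                             dtype=object)
        model.classes_ = np.asarray(payload["classes"], dtype=object)
        model.scaler_mean_ = np.asarray(payload["scaler_mean"])
        model.scaler_scale_ = np.asarray(payload["scaler_scale"])
        model.coefs_ = [np.asarray(w) for w in payload["coefs"]]
        model.intercepts_ = [np.asarray(b) for b in payload["intercepts"]]
        model.training_history_ = payload["training_history"]
        return model


# ---------------------------------------------------------------------------
# Functional wrappers over the estimator

def split_train_test(table: pd.DataFrame, test_fraction: float = 0.5,
                     seed: int = 0) -> TrainTestSplit:
    """Stratified, reproducible train/test split of a labelled table."""
    if "class" not in table.columns:
        raise ValueError("table has no 'class' column")
    counts = table["class"].value_counts()
    if (counts < 2).any():
        low = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 rows: {low}")
    n_test = int(round(test_fraction * len(table)))
    tr, te = train_test_split(table, test_size=n_test, stratify=table["class"],
                              random_state=seed)
    return TrainTestSplit(tr.reset_index(drop=True), te.reset_index(drop=True),
                          seed)


def train(table_train: pd.DataFrame,
          spec: MLPSpec | None = None) -> MLPMigrationClassifier:
    spec = spec or MLPSpec()
    model = MLPMigrationClassifier(
        hidden_layers=spec.hidden_layers, activation=spec.activation,
        epochs=spec.epochs, batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        early_stop_patience=spec.early_stop_patience, random_state=spec.seed)
    return model.fit(table_train, None)


def predict(model: MLPMigrationClassifier, table: pd.DataFrame) -> pd.DataFrame:
    """Per-row class probabilities and predicted label."""
    proba = model.predict_proba(table)
    labels = model.predict(table)
    out = pd.DataFrame({f"p_{c}": proba[:, i]
                        for i, c in enumerate(model.classes_)})
    out["predicted"] = labels
    if "cell_id" in table.columns:
        out.insert(0, "cell_id", table["cell_id"].to_numpy())
    return out


def evaluate(model: MLPMigrationClassifier,
             table_test: pd.DataFrame) -> EvaluationReport:
    """Confusion matrix, per-true-class recall and overall accuracy."""
    if len(table_test) == 0:
        raise ValueError("empty test table")
    _, y_true = _extract_xy(table_test, model.feature_names_in_, True)
    y_pred = model.predict(table_test)
    classes = list(model.classes_)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    per_class = {}
    for c in classes:
        row_sum = int(conf.loc[c].sum())
        per_class[c] = float(conf.loc[c, c] / row_sum) if row_sum else float("nan")
    overall = float(np.trace(conf.to_numpy()) / len(y_true))
    return EvaluationReport(conf, per_class, overall, len(y_true))


def feature_relevance(model: MLPMigrationClassifier,
                      table: pd.DataFrame | None = None,
                      n_permutations: int = 10,
                      seed: int = 0) -> RelevanceReport:
    """Signed relevance by connection-weight products.

    The product of the weight matrices through the network (ignoring
    activations) gives each input's net signed pull on the output unit;
    positive relevance pushes toward the 'transmigrated' class.  When a
    labelled table is supplied, permutation-importance magnitudes are added
    as an independent cross-check column.  For a multiclass model the sign is
    undefined and only magnitudes are reported (flagged).
    """
    check_is_fitted(model, "coefs_")
    W = model.coefs_[0]
    for nxt in model.coefs_[1:]:
        W = W @ nxt
    binary = W.shape[1] == 1
    if binary:
        relevance = W[:, 0]
    else:
        relevance = np.abs(W).sum(axis=1)
    out = pd.DataFrame({"feature": list(model.feature_names_in_),
                        "relevance": relevance})
    if table is not None:
        X, y = _extract_xy(table, model.feature_names_in_, True)
        res = permutation_importance(
            model, X, y, n_repeats=n_permutations, random_state=seed)
        out["permutation_importance"] = res.importances_mean
    out["rank"] = out["relevance"].abs().rank(ascending=False).astype(int)
    return RelevanceReport(out, method="connection_weight_product",
                           sign_defined=binary)


class BetweenGroupOrdination(BaseEstimator, TransformerMixin):
    """Supervised between-group analysis (BGA).

    Features are standardized; the principal axes of the size-weighted group
    centroids define the ordination, samples are projected onto them, and the
    between-group variance fraction (between-group dispersion over total
    dispersion of the scores) summarizes class separability — near 0 for
    overlapping groups, near 1 for well-separated ones.
    """

    def __init__(self, n_axes: int = 2):
        self.n_axes = n_axes

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=object)
        groups = np.unique(y)
        if len(groups) < 2:
            raise ValueError("BGA requires at least two groups")
        for g in groups:
            if (y == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - mean) / sd
        n = len(Z)
        centroids = np.vstack([Z[y == g].mean(axis=0) for g in groups])
        weights = np.array([(y == g).sum() / n for g in groups])
        B = (centroids * weights[:, None]).T @ centroids
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        # the centroid matrix has rank at most g - 1, so axes beyond that
        # carry no between-group signal and are never kept
        k = min(self.n_axes, X.shape[1], len(groups) - 1)
        self.mean_ = mean
        self.scale_ = sd
        self.groups_ = groups
        self.group_centroids_ = centroids
        self.loadings_ = eigvec[:, order[:k]]
        self.eigenvalues_ = eigval[order[:k]]
        scores = Z @ self.loadings_
        group_scores = centroids @ self.loadings_
        between = float((weights[:, None] * group_scores ** 2).sum())
        total = float((scores ** 2).mean(axis=0).sum())
        self.between_variance_fraction_ = between / total if total > 0 else 0.0
        self.scores_ = scores
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        Z = (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_
        return Z @ self.loadings_


@dataclass
class BGAResult:
    group_centroids: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    between_variance_fraction: float
    groups: np.ndarray
    feature_names: list


def bga_ordination(table: pd.DataFrame, label_col: str = "class",
                   n_axes: int = 2) -> BGAResult:
    """BGA of a labelled feature table (functional wrapper)."""
    feats = [c for c in FEATURE_NAMES if c in table.columns]
    if not feats:
        raise ValueError("table holds no known feature columns")
    X = table[feats].to_numpy(dtype=np.float64)
    y = table[label_col].to_numpy(dtype=object)
    est = BetweenGroupOrdination(n_axes=n_axes).fit(X, y)
    return BGAResult(est.group_centroids_, est.loadings_, est.scores_,
                     est.between_variance_fraction_, est.groups_, feats)
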