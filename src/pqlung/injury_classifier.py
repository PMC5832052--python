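"""Two-layer feed-forward ANN separating injured from noninjured lung.

The classifier is a small multilayer perceptron: 9 texture features in,
18 logistic (sigmoid) hidden units, one logistic output — a capacity
found adequate empirically for this task.  Features are z-scored with
training-set statistics before entering the network (sigmoid units
saturate on raw HU scales); the scaler travels with the model.

Training caps at 5000 iterations with early stopping on a validation
split (patience 50 checks).  The labelled dataset is divided into
disjoint stratified train/validation/test partitions, 70/15/15 by
default.  Evaluation reports the ROC curve, trapezoid-rule AUC and a
confusion matrix at the operating threshold.

The estimator follows a fit/predict shape: ``AnnClassifier.fit`` returns
a trained :class:`AnnModel` whose weights, scaler and training record
are inspectable and serialisable to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .texture_features import FEATURE_NAMES, FeatureDataset, FeatureVector, feature_map
from .volume_io import BinaryMask, CTVolume, MaskRole

__all__ = [
    "AnnModel",
    "AnnClassifier",
    "EvalReport",
    "split_dataset",
    "train",
    "predict",
    "predict_proba",
    "classify_volume",
    "evaluate",
]

DEFAULT_HIDDEN = 18
DEFAULT_MAX_ITER = 5000
DEFAULT_SPLIT = (0.70, 0.15, 0.15)
EARLY_STOP_PATIENCE = 50


@dataclass
class TrainingRecord:
    n_train: int
    n_val: int
    iterations_run: int
    seed: int
    converged: bool
    final_loss: float


@dataclass
class AnnModel:
    """Weights, scaler and provenance of a trained network."""

    w_hidden: np.ndarray          # (9, hidden)
    b_hidden: np.ndarray          # (hidden,)
    w_out: np.ndarray             # (hidden, 1)
    b_out: np.ndarray             # (1,)
    scaler_mean: np.ndarray       # (9,)
    scaler_sd: np.ndarray         # (9,)
    training_record: TrainingRecord | None = None
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        for name in ("w_hidden", "b_hidden", "w_out", "b_out", "scaler_mean", "scaler_sd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.w_hidden.shape[0] != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} input features")

    @property
    def hidden_size(self) -> int:
        return self.w_hidden.shape[1]

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Injury probability: sigmoid(W_out . sigmoid(W_h z + b_h) + b_out)."""
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain NaN/inf")
        z = (X - self.scaler_mean) / self.scaler_sd
        h = _sigmoid(z @ self.w_hidden + self.b_hidden)
        return _sigmoid(h @ self.w_out + self.b_out).ravel()

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "format": "pqlung-ann-1",
            "activation": self.activation,
            "feature_names": list(FEATURE_NAMES),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
        }
        if self.training_record is not None:
            payload["training_record"] = self.training_record.__dict__
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AnnModel":
        payload = json.loads(Path(path).read_text())
        rec = payload.get("training_record")
        return cls(
            w_hidden=payload["w_hidden"], b_hidden=payload["b_hidden"],
            w_out=payload["w_out"], b_out=payload["b_out"],
            scaler_mean=payload["scaler_mean"], scaler_sd=payload["scaler_sd"],
            training_record=TrainingRecord(**rec) if rec else None,
            activation=payload.get("activation", "sigmoid"),
        )


@dataclass
class EvalReport:
    roc_points: np.ndarray        # (n, 2) of (fpr, tpr)
    auc: float
    confusion: np.ndarray         # 2x2 [[TN, FP], [FN, TP]]
    threshold: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        return {"auc": self.auc, "threshold": self.threshold,
                "accuracy": self.accuracy, "confusion": self.confusion.tolist()}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


# ---------------------------------------------------------------------------
# Splitting and training
# ---------------------------------------------------------------------------

def split_dataset(dataset: FeatureDataset, fractions=DEFAULT_SPLIT,
                  seed: int = 0) -> tuple[FeatureDataset, FeatureDataset, FeatureDataset]:
    """Disjoint stratified train/validation/test partitions.

    Fractions are normalised to sum to 1.  Splits are stratified on the
    label when both classes allow it, and deterministic given the seed.
    """
    frac = np.asarray(fractions, dtype=float)
    if frac.min() < 0 or frac.sum() <= 0:
        raise ValueError(f"invalid fractions {fractions}")
    frac = frac / frac.sum()
    n = len(dataset)
    n_val = int(round(frac[1] * n))
    n_test = int(round(frac[2] * n))
    idx = np.arange(n)

    def _take(pool: np.ndarray, size: int, seed_: int) -> tuple[np.ndarray, np.ndarray]:
        if size == 0:
            return pool[:0], pool
        if size >= len(pool):
            return pool, pool[:0]
        strat = dataset.labels[pool]
        if len(np.unique(strat)) < 2 or np.bincount(strat).min() < 2:
            strat = None
        rest, taken = train_test_split(pool, test_size=size, random_state=seed_,
                                       stratify=strat)
        return np.sort(taken), np.sort(rest)

    test_idx, pool = _take(idx, n_test, seed)
    val_idx, train_idx = _take(pool, n_val, seed + 1)

    def _sub(sel: np.ndarray, tag: str) -> FeatureDataset:
        return FeatureDataset(
            dataset.features[sel], dataset.labels[sel],
            coords=None if dataset.coords is None else dataset.coords[sel],
            provenance=f"{dataset.provenance}[{tag}]",
        )

    return _sub(train_idx, "train"), _sub(val_idx, "val"), _sub(test_idx, "test")


class AnnClassifier:
    """Estimator wrapper: configure once, fit on a FeatureDataset."""

    def __init__(self, hidden: int = DEFAULT_HIDDEN, max_iter: int = DEFAULT_MAX_ITER,
                 seed: int = 0):
        self.hidden = hidden
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, train_set: FeatureDataset,
            val_set: FeatureDataset | None = None) -> AnnModel:
        y = train_set.labels
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        X, y = train_set.features, y
        if val_set is not None and len(val_set) > 0:
            # sklearn draws its own validation split; hand it train+val with
            # the fraction sized so the held-out part equals our val set
            X = np.vstack([X, val_set.features])
            y = np.concatenate([y, val_set.labels])
            val_fraction = len(val_set) / len(y)
        else:
            val_fraction = 0.1
        scaler = StandardScaler().fit(X)
        # guard zero-variance features (constant phantoms)
        sd = np.where(scaler.scale_ <= 0, 1.0, scaler.scale_)
        Z = (X - scaler.mean_) / sd
        net = MLPClassifier(
            hidden_layer_sizes=(self.hidden,), activation="logistic",
            solver="adam", max_iter=self.max_iter,
            # standardized inputs tolerate an aggressive initial step; the
            # sklearn default (1e-3) stalls under early stopping
            learning_rate_init=0.03,
            early_stopping=True, validation_fraction=val_fraction,
            n_iter_no_change=EARLY_STOP_PATIENCE, random_state=self.seed,
        )
        net.fit(Z, y)
        record = TrainingRecord(
            n_train=len(train_set), n_val=0 if val_set is None else len(val_set),
            iterations_run=int(net.n_iter_), seed=self.seed,
            converged=int(net.n_iter_) < self.max_iter,
            final_loss=float(net.loss_),
        )
        return AnnModel(
            w_hidden=net.coefs_[0], b_hidden=net.intercepts_[0],
            w_out=net.coefs_[1], b_out=net.intercepts_[1],
            scaler_mean=scaler.mean_, scaler_sd=sd,
            training_record=record,
        )


def train(dataset: FeatureDataset, hidden: int = DEFAULT_HIDDEN,
          max_iter: int = DEFAULT_MAX_ITER, seed: int = 0,
          fractions=DEFAULT_SPLIT) -> tuple[AnnModel, EvalReport]:
    """Split, fit, and evaluate on the held-out test partition."""
    train_set, val_set, test_set = split_dataset(dataset, fractions, seed=seed)
    model = AnnClassifier(hidden=hidden, max_iter=max_iter, seed=seed).fit(train_set, val_set)
    report = evaluate(model, test_set) if len(test_set) else None
    return model, report


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def predict_proba(model: AnnModel, features: np.ndarray) -> np.ndarray:
    """Injury probabilities for an (n, 9) feature array."""
    return model.forward(features)


def predict(model: AnnModel, vector: FeatureVector | np.ndarray) -> float:
    """Injury probability for a single feature vector, in (0, 1)."""
    arr = vector.to_array() if isinstance(vector, FeatureVector) else np.asarray(vector)
    return float(model.forward(arr.reshape(1, -1))[0])


def classify_volume(model: AnnModel, volume: CTVolume, lung: BinaryMask,
                    threshold: float = 0.5) -> BinaryMask:
    """Per-pixel injury decision over all in-lung pixels.

    The candidate mask is {p in lung : P(injured | features(p)) >= threshold};
    by construction it is a subset of the lung mask.
    """
    lung.check_aligned(volume)
    if not lung.bits.any():
        raise ValueError("empty lung mask")
    coords, feats = feature_map(volume, lung)
    probs = model.forward(feats)
    bits = np.zeros(volume.shape, dtype=bool)
    keep = probs >= threshold
    bits[tuple(coords[keep].T)] = True
    return BinaryMask(bits, MaskRole.injured_candidate,
                      source_scan_id=volume.scan_id, spacing_mm=volume.spacing_mm)


def evaluate(model: AnnModel, test: FeatureDataset,
             threshold: float = 0.5) -> EvalReport:
    """ROC over all thresholds, trapezoid AUC, confusion at `threshold`."""
    if len(test) == 0:
        raise ValueError("empty test set")
    if len(np.unique(test.labels)) < 2:
        raise ValueError("ROC undefined on a single-class test set")
    scores = model.forward(test.features)
    fpr, tpr, _ = roc_curve(test.labels, scores)
    cm = confusion_matrix(test.labels, (scores >= threshold).astype(int), labels=[0, 1])
    return EvalReport(
        roc_points=np.column_stack([fpr, tpr]),
        auc=float(_trapezoid_auc(fpr, tpr)),
        confusion=cm, threshold=threshold,
    )
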