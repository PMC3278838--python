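"""Prediction models PM1-PM5: a small feed-forward sigmoid network.

Five model configurations differ only in which feature blocks they see:

====  =================  ========
PM    blocks             features
====  =================  ========
PM1   BPC                40
PM2   ATOM                5
PM3   BPC + AC           65
PM4   BPC + ATOM         45
PM5   BPC + AC + ATOM    70
====  =================  ========

The classifier is a two-layer feed-forward network — one hidden layer of
23 sigmoid units and one sigmoid output unit coding 1 = amyloidogenic —
trained by full-batch backpropagation on the cross-entropy loss with
validation-based early stopping.  Data are split 60/20/20 into
train/validation/test, stratified by class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

PM_BLOCKS: dict[str, tuple[str, ...]] = {
    "PM1": ("BPC",),
    "PM2": ("ATOM",),
    "PM3": ("BPC", "AC"),
    "PM4": ("BPC", "ATOM"),
    "PM5": ("BPC", "AC", "ATOM"),
}

#: Feature counts for the canonical 40-BPC / 5-AC-property configuration.
PM_DIMENSIONS = {"PM1": 40, "PM2": 5, "PM3": 65, "PM4": 45, "PM5": 70}


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class PMConfig:
    """One prediction-model configuration (blocks, dimensions, training)."""

    pm_id: str
    blocks: tuple[str, ...]
    expected_dim: int
    bpc_properties: tuple[str, ...] = ()
    ac_properties: tuple[str, ...] = ()
    hidden_units: int = 23
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    max_epochs: int = 2000
    learning_rate: float = 0.1
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.fractions[1] <= 0:
            raise ValueError("a validation fraction is required for early stopping")


def build_pm(
    pm_id: str,
    selected_bpc: Sequence[str] = (),
    ac_accessions: Sequence[str] = (),
    max_lag: int = 5,
    **training_kwargs,
) -> PMConfig:
    """Assemble a PM configuration from selected property accessions."""
    if pm_id not in PM_BLOCKS:
        raise ValueError(f"unknown model id {pm_id!r}; expected one of {sorted(PM_BLOCKS)}")
    blocks = PM_BLOCKS[pm_id]
    dim = 0
    if "BPC" in blocks:
        if not selected_bpc:
            raise ValueError(f"{pm_id} needs BPC accessions")
        dim += len(selected_bpc)
    if "AC" in blocks:
        if not ac_accessions:
            raise ValueError(f"{pm_id} needs AC accessions")
        dim += len(ac_accessions) * max_lag
    if "ATOM" in blocks:
        dim += 5
    return PMConfig(
        pm_id=pm_id,
        blocks=blocks,
        expected_dim=dim,
        bpc_properties=tuple(selected_bpc) if "BPC" in blocks else (),
        ac_properties=tuple(ac_accessions) if "AC" in blocks else (),
        **training_kwargs,
    )


def split_data(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
):
    """Seeded stratified train/validation/test split at the given fractions."""
    if fractions[1] <= 0 or fractions[2] <= 0:
        raise ValueError("validation and test fractions must be positive")
    y = np.asarray(labels)
    idx = np.arange(len(y))
    train_idx, rest_idx = train_test_split(
        idx, train_size=fractions[0], stratify=y, random_state=seed
    )
    rel_test = fractions[2] / (fractions[1] + fractions[2])
    val_idx, test_idx = train_test_split(
        rest_idx, test_size=rel_test, stratify=y[rest_idx], random_state=seed
    )
    parts = []
    for part in (train_idx, val_idx, test_idx):
        if len(np.unique(y[part])) < 2:
            raise ValueError(
                "a partition lost one class entirely; provide more data"
            )
        parts.append((matrix.iloc[part], y[part]))
    return tuple(parts)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class SigmoidNetClassifier(ClassifierMixin, BaseEstimator):
    """One-hidden-layer sigmoid network trained by backpropagation.

    Full-batch gradient descent on the binary cross-entropy with a
    geometrically decaying learning rate; training stops early when the
    validation loss has not improved for ``patience`` epochs (the weights
    from the best validation epoch are kept).  Deterministic for a fixed
    ``random_state``: weights initialize uniformly in [-0.5, 0.5].
    """

    def __init__(
        self,
        hidden_units: int = 23,
        learning_rate: float = 0.1,
        lr_decay: float = 0.9995,
        max_epochs: int = 2000,
        patience: int = 50,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y, validation=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if validation is None:
            from sklearn.model_selection import train_test_split as _tts

            X, Xv, y, yv = _tts(
                X, y, test_size=0.2, stratify=y, random_state=self.random_state
            )
        else:
            Xv, yv = validation
            Xv = np.asarray(Xv, dtype=float)
            yv = np.asarray(yv, dtype=float).ravel()

        n, d = X.shape
        rng = np.random.default_rng(self.random_state)
        W1 = rng.uniform(-0.5, 0.5, size=(d, self.hidden_units))
        b1 = rng.uniform(-0.5, 0.5, size=self.hidden_units)
        w2 = rng.uniform(-0.5, 0.5, size=self.hidden_units)
        b2 = float(rng.uniform(-0.5, 0.5))

        lr = self.learning_rate
        best = (np.inf, W1.copy(), b1.copy(), w2.copy(), b2, 0)
        stale = 0
        self.loss_curve_ = []
        self.validation_loss_curve_ = []

        for epoch in range(self.max_epochs):
            h = _sigmoid(X @ W1 + b1)
            p = _sigmoid(h @ w2 + b2)
            loss = _bce(y, p)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite training loss at epoch {epoch} (lr={lr:.3g})"
                )
            # dL/dz2 = p - y for sigmoid + cross-entropy
            delta2 = (p - y) / n
            grad_w2 = h.T @ delta2
            grad_b2 = float(delta2.sum())
            delta1 = np.outer(delta2, w2) * h * (1 - h)
            grad_W1 = X.T @ delta1
            grad_b1 = delta1.sum(axis=0)
            w2 -= lr * grad_w2
            b2 -= lr * grad_b2
            W1 -= lr * grad_W1
            b1 -= lr * grad_b1
            lr *= self.lr_decay

            hv = _sigmoid(Xv @ W1 + b1)
            pv = _sigmoid(hv @ w2 + b2)
            val_loss = _bce(yv, pv)
            self.loss_curve_.append(loss)
            self.validation_loss_curve_.append(val_loss)
            if val_loss < best[0] - 1e-9:
                best = (val_loss, W1.copy(), b1.copy(), w2.copy(), b2, epoch)
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break

        _, W1, b1, w2, b2, stop_epoch = best
        self.coefs_ = [W1, w2.reshape(-1, 1)]
        self.intercepts_ = [b1, np.array([b2])]
        self.n_iter_ = len(self.loss_curve_)
        self.stop_epoch_ = stop_epoch
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        h = _sigmoid(X @ self.coefs_[0] + self.intercepts_[0])
        return _sigmoid(h @ self.coefs_[1].ravel() + self.intercepts_[1][0])

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1 - p, p])

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return classify(self.decision_function(X), threshold)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels from sigmoid scores: 1 iff score >= threshold.

    The boundary is inclusive (a score exactly at threshold is called
    positive, matching the 1 = positive target coding); the threshold is
    clamped to [0, 1].
    """
    threshold = min(max(threshold, 0.0), 1.0)
    return (np.asarray(scores) >= threshold).astype(int)


def train_ann(train, validation, config: PMConfig) -> "TrainedModel":
    """Train the configured network; partitions are (matrix, labels) pairs."""
    Xt, yt = train
    Xv, yv = validation
    Xt = pd.DataFrame(Xt)
    if Xt.shape[1] != config.expected_dim:
        raise ValueError(
            f"{config.pm_id} expects {config.expected_dim} features, got {Xt.shape[1]}"
        )
    net = SigmoidNetClassifier(
        hidden_units=config.hidden_units,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        patience=config.patience,
        random_state=config.seed,
    )
    net.fit(Xt.to_numpy(), np.asarray(yt), validation=(pd.DataFrame(Xv).to_numpy(), np.asarray(yv)))
    return TrainedModel(
        config=config, net=net, feature_manifest=[str(c) for c in Xt.columns]
    )


@dataclass
class TrainedModel:
    """A fitted network plus the feature manifest it expects.

    Normalization parameters may be attached so that raw feature rows can
    be scaled exactly as the training data were.
    """

    config: PMConfig
    net: SigmoidNetClassifier
    feature_manifest: list[str]
    normalization: "object | None" = None  # encoding.NormalizationParams

    def predict_scores(self, matrix: pd.DataFrame) -> np.ndarray:
        cols = [str(c) for c in matrix.columns]
        if cols != self.feature_manifest:
            missing = [c for c in self.feature_manifest if c not in cols]
            extra = [c for c in cols if c not in self.feature_manifest]
            raise ValueError(
                f"feature manifest mismatch (missing={missing[:5]}, extra={extra[:5]})"
            )
        return self.net.decision_function(matrix.to_numpy())

    def predict_labels(self, matrix: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return classify(self.predict_scores(matrix), threshold)

    def to_json(self) -> str:
        net = self.net
        payload = {
            "pm_id": self.config.pm_id,
            "blocks": list(self.config.blocks),
            "hidden_units": self.config.hidden_units,
            "seed": self.config.seed,
            "feature_manifest": self.feature_manifest,
            "weights": {
                "W1": net.coefs_[0].tolist(),
                "b1": net.intercepts_[0].tolist(),
                "w2": net.coefs_[1].ravel().tolist(),
                "b2": float(net.intercepts_[1][0]),
            },
            "normalization": json.loads(self.normalization.to_json())
            if self.normalization is not None
            else None,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        from .encoding import NormalizationParams

        d = json.loads(text)
        manifest = list(d["feature_manifest"])
        config = PMConfig(
            pm_id=d["pm_id"],
            blocks=tuple(d["blocks"]),
            expected_dim=len(manifest),
            hidden_units=d["hidden_units"],
            seed=d["seed"],
        )
        net = SigmoidNetClassifier(
            hidden_units=d["hidden_units"], random_state=d["seed"]
        )
        w = d["weights"]
        net.coefs_ = [np.asarray(w["W1"]), np.asarray(w["w2"]).reshape(-1, 1)]
        net.intercepts_ = [np.asarray(w["b1"]), np.array([w["b2"]])]
        net.classes_ = np.array([0, 1])
        net.n_features_in_ = len(manifest)
        norm = None
        if d.get("normalization") is not None:
            norm = NormalizationParams.from_json(json.dumps(d["normalization"]))
        return cls(config=config, net=net, feature_manifest=manifest, normalization=norm)
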