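"""Training (ADADELTA) and penultimate-layer feature extraction.

Supervised extractors are trained with categorical cross-entropy; the
autoencoder with mean squared reconstruction error.  After training, the
classification head (or decoder) is discarded and the feature layer's
inference-mode activations become the frame representation handed to the
SVM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import SpecError, TrainingError
from ..io import FeatureMatrix
from ..segment import FrameSet
from .layers import Param
from .models import Model


class Adadelta:
    """ADADELTA with decay rho=0.95, eps=1e-6 and learning-rate multiplier 1."""

    def __init__(self, params: list[Param], rho: float = 0.95,
                 eps: float = 1e-6, lr: float = 1.0):
        self.params = params
        self.rho, self.eps, self.lr = rho, eps, lr
        self._Eg = [None] * len(params)
        self._Ed = [None] * len(params)

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            if self._Eg[i] is None:
                self._Eg[i] = np.zeros_like(p.value)
                self._Ed[i] = np.zeros_like(p.value)
            g = p.grad
            self._Eg[i] = self.rho * self._Eg[i] + (1 - self.rho) * g * g
            dx = -np.sqrt(self._Ed[i] + self.eps) / np.sqrt(self._Eg[i] + self.eps) * g
            self._Ed[i] = self.rho * self._Ed[i] + (1 - self.rho) * dx * dx
            p.value += self.lr * dx

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


@dataclass
class TrainedExtractor:
    """A trained model together with its training log."""

    model: Model
    history: list[float]          # mean loss per epoch
    seed: int


def _as_arrays(frames: FrameSet | np.ndarray,
               labels: np.ndarray | None) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(frames, FrameSet):
        return frames.data, frames.labels if labels is None else np.asarray(labels)
    return np.asarray(frames, dtype=float), None if labels is None else np.asarray(labels)


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def train_supervised(model: Model, frames: FrameSet | np.ndarray,
                     labels: np.ndarray | None = None, epochs: int = 50,
                     batch_size: int = 256, seed: int = 0) -> TrainedExtractor:
    """Train a softmax-headed extractor; returns the model with its loss log."""
    X, y = _as_arrays(frames, labels)
    if y is None:
        raise TrainingError("supervised training needs labels")
    if X.shape[1:] != (model.T, model.S):
        raise SpecError(f"frames {X.shape[1:]} do not match model "
                        f"({model.T}, {model.S})")
    if len(np.unique(y)) < 2:
        raise TrainingError("need at least two classes to train")
    rng = np.random.default_rng(seed)
    opt = Adadelta(model.params())
    history: list[float] = []
    for _ in range(epochs):
        losses = []
        for idx in _epoch_batches(len(X), batch_size, rng):
            logits = model.forward(X[idx], train=True)
            loss = model.loss.forward(logits, y[idx])
            opt.zero_grad()
            model.backward(model.loss.backward())
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedExtractor(model=model, history=history, seed=seed)


def train_autoencoder(model: Model, frames: FrameSet | np.ndarray,
                      epochs: int = 50, batch_size: int = 256,
                      seed: int = 0) -> TrainedExtractor:
    """Train the autoencoder to reconstruct its (flattened) input frames."""
    if model.family != "ae":
        raise SpecError("train_autoencoder requires an autoencoder model")
    X, _ = _as_arrays(frames, None)
    if X.shape[1:] != (model.T, model.S):
        raise SpecError(f"frames {X.shape[1:]} do not match model "
                        f"({model.T}, {model.S})")
    flat = X.reshape(len(X), -1)
    rng = np.random.default_rng(seed)
    opt = Adadelta(model.params())
    history: list[float] = []
    for _ in range(epochs):
        losses = []
        for idx in _epoch_batches(len(X), batch_size, rng):
            recon = model.forward(X[idx], train=True)
            loss = model.loss.forward(recon, flat[idx])
            opt.zero_grad()
            model.backward(model.loss.backward())
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedExtractor(model=model, history=history, seed=seed)


def extract_features(extractor: TrainedExtractor,
                     frames: FrameSet | np.ndarray,
                     batch_size: int = 512) -> FeatureMatrix | np.ndarray:
    """Feature-layer activations for every frame, order preserved.

    Batch statistics are never used at this stage (the input normalization
    layer switches to its running averages), so features are invariant to
    frame order and batch composition.  Returns a :class:`FeatureMatrix`
    when given a :class:`FrameSet`, else a bare array.
    """
    model = extractor.model
    X, _ = _as_arrays(frames, None)
    if X.shape[1:] != (model.T, model.S):
        raise SpecError(f"frames {X.shape[1:]} do not match model "
                        f"({model.T}, {model.S})")
    chunks = [model.feature_forward(X[i:i + batch_size])
              for i in range(0, len(X), batch_size)]
    F = np.concatenate(chunks) if chunks else np.empty((0, model.feature_dim))
    if isinstance(frames, FrameSet):
        return FeatureMatrix(X=F, labels=frames.labels.copy())
    return F
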