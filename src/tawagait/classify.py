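"""Multilayer multiclass SVM trained by stochastic gradient descent.

The classifier scores a feature vector z through a one-hidden-layer
network — ``f(z) = W2 · relu(W1 z + b1) + b2`` — whose c class scores are
then mean-centred so they satisfy the multiclass-SVM sum-to-zero
constraint ``Σ_j f_j(z) = 0`` exactly for every input.  Centring is the
orthogonal projection of the score vector onto the constraint set, so the
constraint holds by construction and stays differentiable.

Training minimises the MAP objective of the multiclass hinge likelihood
with a Gaussian prior on the weights:

    Σ_i Σ_{j ≠ y_i} ( f_j(x_i) + 1/(ψ−1) )_+  +  (α/2) Σ_w w²

where (u)_+ = max(u, 0), ψ > 1 sets the margin 1/(ψ−1) (ψ = 2 recovers
the canonical unit margin) and the prior acts on weights only, not biases.
Every wrong class whose score is within the margin of the constraint
surface is penalised; because the scores are centred, pushing wrong-class
scores down raises the true class's score.

SGD uses minibatches with the data term normalised per sample (so the
learning rate is batch-size independent), a 1/√epoch learning-rate decay,
and a clamped multiplicative weight-decay step for the prior.  All
randomness (initialisation, shuffling) derives from the config seed.

An identity hidden layer (``hidden_width=None``) exposes the plain convex
multiclass SVM, used for convexity and oracle checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["SvmModel", "TrainConfig", "forward", "loss", "loss_and_grad", "train", "predict"]


@dataclass
class TrainConfig:
    """SGD hyperparameters. Defaults are fixed, documented choices."""

    learning_rate: float = 0.01
    epochs: int = 300
    batch_size: int = 32
    alpha: float = 1e-3
    psi: float = 2.0
    hidden_width: int | None = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.psi <= 1:
            raise ValueError("psi must be > 1 (margin 1/(psi-1) must be finite)")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class SvmModel:
    """Two-layer parameter set plus hyperparameters and class list.

    ``W1 is None`` means the hidden layer is the identity (pure linear
    multiclass SVM); otherwise ``W1`` is (hidden, d) and ``W2`` is
    (c, hidden).
    """

    W1: np.ndarray | None
    b1: np.ndarray | None
    W2: np.ndarray
    b2: np.ndarray
    classes: list[int]
    alpha: float
    psi: float
    seed: int

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_features(self) -> int:
        return self.W2.shape[1] if self.W1 is None else self.W1.shape[1]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "W1": None if self.W1 is None else self.W1.tolist(),
            "b1": None if self.b1 is None else self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "classes": [int(c) for c in self.classes],
            "alpha": self.alpha,
            "psi": self.psi,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SvmModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            W1=None if obj["W1"] is None else np.asarray(obj["W1"], dtype=float),
            b1=None if obj["b1"] is None else np.asarray(obj["b1"], dtype=float),
            W2=np.asarray(obj["W2"], dtype=float),
            b2=np.asarray(obj["b2"], dtype=float),
            classes=[int(c) for c in obj["classes"]],
            alpha=float(obj["alpha"]),
            psi=float(obj["psi"]),
            seed=int(obj["seed"]),
        )


def _as_batch(z: np.ndarray) -> tuple[np.ndarray, bool]:
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        return z[None, :], True
    return z, False


def forward(model: SvmModel, z: np.ndarray) -> np.ndarray:
    """Centred class scores; (c,) for a vector, (n, c) for a matrix."""
    Z, single = _as_batch(z)
    if Z.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {Z.shape[1]} does not match model "
            f"({model.n_features})"
        )
    if model.W1 is None:
        H = Z
    else:
        H = np.maximum(Z @ model.W1.T + model.b1, 0.0)
    scores = H @ model.W2.T + model.b2
    scores = scores - scores.mean(axis=1, keepdims=True)  # sum-to-zero
    return scores[0] if single else scores


def _label_indices(classes: Sequence[int], y: np.ndarray) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[int(v)] for v in y])
    except KeyError as e:
        raise ValueError(f"label {e.args[0]} not in model classes {list(classes)}")


def loss(model: SvmModel, X: np.ndarray, y: np.ndarray) -> float:
    """MAP objective: summed multiclass hinge plus (α/2)·Σ weights²."""
    value, _ = loss_and_grad(model, X, y)
    return value


def loss_and_grad(
    model: SvmModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Objective value and its analytic gradient w.r.t. all parameters.

    The data term is the summed hinge of the centred scores; gradients are
    backpropagated through the centring projection and the ReLU.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.atleast_1d(np.asarray(y))
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    yi = _label_indices(model.classes, y)
    n, c = X.shape[0], model.n_classes
    margin = 1.0 / (model.psi - 1.0)

    if model.W1 is None:
        H, pre = X, None
    else:
        pre = X @ model.W1.T + model.b1
        H = np.maximum(pre, 0.0)
    scores = H @ model.W2.T + model.b2
    f = scores - scores.mean(axis=1, keepdims=True)

    viol = f + margin
    active = viol > 0
    active[np.arange(n), yi] = False  # j != y_i only
    data_term = float(viol[active].sum())

    reg = 0.5 * model.alpha * (
        float((model.W2**2).sum())
        + (0.0 if model.W1 is None else float((model.W1**2).sum()))
    )

    A = active.astype(float)
    G = A - A.mean(axis=1, keepdims=True)  # backprop through centring
    grads: dict[str, np.ndarray] = {
        "W2": G.T @ H + model.alpha * model.W2,
        "b2": G.sum(axis=0),
    }
    if model.W1 is not None:
        dH = G @ model.W2
        dpre = dH * (pre > 0)
        grads["W1"] = dpre.T @ X + model.alpha * model.W1
        grads["b1"] = dpre.sum(axis=0)
    return data_term + reg, grads


def _init_model(
    d: int, classes: Sequence[int], config: TrainConfig
) -> SvmModel:
    rng = np.random.default_rng(config.seed)
    c = len(classes)
    if config.hidden_width is None:
        W1 = b1 = None
        fan_in2 = d
    else:
        h = config.hidden_width
        lim1 = 1.0 / np.sqrt(d)
        W1 = rng.uniform(-lim1, lim1, (h, d))
        b1 = np.zeros(h)
        fan_in2 = h
    lim2 = 1.0 / np.sqrt(fan_in2)
    W2 = rng.uniform(-lim2, lim2, (c, fan_in2))
    b2 = np.zeros(c)
    return SvmModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        classes=sorted(int(v) for v in classes),
        alpha=config.alpha, psi=config.psi, seed=config.seed,
    )


def train(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None) -> SvmModel:
    """Fit the model by minibatch SGD; deterministic given the config seed.

    Per step the hinge gradient is averaged over the minibatch and weights
    take a clamped multiplicative decay ``w ← w·max(1 − ηα, 0)``, so α acts
    per-sample and very large α drives the weights to zero rather than
    destabilising the update.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_features)")
    classes = sorted(int(v) for v in np.unique(y))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")

    model = _init_model(X.shape[1], classes, config)
    # alpha=0 inside the step loop: the prior is applied as decoupled decay
    step_model = SvmModel(
        W1=model.W1, b1=model.b1, W2=model.W2, b2=model.b2,
        classes=model.classes, alpha=0.0, psi=model.psi, seed=model.seed,
    )
    rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    batch = min(config.batch_size, n)

    for epoch in range(1, config.epochs + 1):
        lr = config.learning_rate / np.sqrt(epoch)
        decay = max(1.0 - lr * config.alpha, 0.0)
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            _, grads = loss_and_grad(step_model, X[idx], y[idx])
            m = len(idx)
            if step_model.W1 is not None:
                step_model.W1 *= decay
                step_model.W1 -= lr * grads["W1"] / m
                step_model.b1 -= lr * grads["b1"] / m
            step_model.W2 *= decay
            step_model.W2 -= lr * grads["W2"] / m
            step_model.b2 -= lr * grads["b2"] / m

    model.W1, model.b1 = step_model.W1, step_model.b1
    model.W2, model.b2 = step_model.W2, step_model.b2
    return model


def predict(model: SvmModel, z: np.ndarray) -> np.ndarray | int:
    """Argmax class; ties resolve to the lowest class label."""
    scores = forward(model, z)
    if scores.ndim == 1:
        return model.classes[int(np.argmax(scores))]
    idx = np.argmax(scores, axis=1)
    return np.array([model.classes[i] for i in idx])
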