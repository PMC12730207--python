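"""Feed-forward classifier and its training protocol.

A deliberately small network — two hidden layers of 50 and 25 rectified
linear units and a softmax output — trained by minimizing the softmax
cross-entropy with a quasi-Newton (BFGS-family) optimizer.  Training stops
at 1000 iterations, or earlier when the loss or the infinity norm of its
gradient falls below 1e-6.  Inputs are z-scored with statistics fitted on
the training set only (duration in seconds, frequencies in Hz and cepstral
coefficients live on very different scales, and quasi-Newton steps are
scale-sensitive); the standardizer can be disabled for raw-feature
experiments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

__all__ = ["NetworkConfig", "TrainedNetwork", "balance_classes", "train", "predict"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    hidden_sizes: tuple[int, ...] = (50, 25)
    max_iter: int = 1000
    tol: float = 1e-6          # on the loss value and on the gradient inf-norm
    seed: int = 0
    init_scale: float | None = None  # None -> He-style sqrt(2 / fan_in)
    standardize: bool = True
    dtype: str = "float32"     # forward/backward arithmetic; optimizer is float64


@dataclass
class TrainedNetwork:
    weights: list[np.ndarray]      # [W1, b1, W2, b2, W3, b3]
    classes: list                  # ordered label list
    mean: np.ndarray | None        # standardizer shift (None if disabled)
    scale: np.ndarray | None       # standardizer scale
    config: NetworkConfig
    training_log: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    def save(self, path: str | Path) -> None:
        blob = {
            "weights": [w.tolist() for w in self.weights],
            "classes": list(self.classes),
            "mean": None if self.mean is None else self.mean.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "config": {
                "hidden_sizes": list(self.config.hidden_sizes),
                "max_iter": self.config.max_iter,
                "tol": self.config.tol,
                "seed": self.config.seed,
                "standardize": self.config.standardize,
            },
            "training_log": {
                k: (v if not isinstance(v, np.ndarray) else v.tolist())
                for k, v in self.training_log.items()
            },
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedNetwork":
        blob = json.loads(Path(path).read_text())
        cfg = NetworkConfig(
            hidden_sizes=tuple(blob["config"]["hidden_sizes"]),
            max_iter=blob["config"]["max_iter"],
            tol=blob["config"]["tol"],
            seed=blob["config"]["seed"],
            standardize=blob["config"]["standardize"],
        )
        return cls(
            weights=[np.asarray(w) for w in blob["weights"]],
            classes=blob["classes"],
            mean=None if blob["mean"] is None else np.asarray(blob["mean"]),
            scale=None if blob["scale"] is None else np.asarray(blob["scale"]),
            config=cfg,
            training_log=blob["training_log"],
        )


def balance_classes(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample every class to the smallest class count.

    Selection is uniform without replacement with the given seed; the
    returned order is deterministic (sorted original indices).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) == 0:
        raise ValueError("no classes present")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        keep.append(rng.choice(idx, size=n_min, replace=False))
    order = np.sort(np.concatenate(keep))
    return X[order], y[order]


# ---------------------------------------------------------------- internals

def _shapes(n_in: int, hidden: tuple[int, ...], n_out: int):
    sizes = (n_in, *hidden, n_out)
    shapes = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        shapes.append((a, b))
        shapes.append((b,))
    return shapes


def _unpack(theta: np.ndarray, shapes) -> list[np.ndarray]:
    out, pos = [], 0
    for shp in shapes:
        n = int(np.prod(shp))
        out.append(theta[pos : pos + n].reshape(shp))
        pos += n
    return out


def _forward(weights: list[np.ndarray], X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; the last entry is the softmax probability matrix."""
    acts = [X]
    n_layers = len(weights) // 2
    a = X
    for layer in range(n_layers):
        W, b = weights[2 * layer], weights[2 * layer + 1]
        z = a @ W + b
        if layer < n_layers - 1:
            a = np.maximum(z, 0.0)  # ReLU
        else:
            z -= z.max(axis=1, keepdims=True)
            # floor keeps exp() out of the subnormal range (slow, no info)
            ez = np.exp(np.maximum(z, -60.0))
            a = ez / ez.sum(axis=1, keepdims=True)
        acts.append(a)
    return acts


def _loss_grad(theta: np.ndarray, shapes, X: np.ndarray, Y: np.ndarray):
    """Mean cross-entropy and its gradient by backpropagation.

    Arithmetic runs in the dtype of ``X``; loss and gradient are returned
    as float64 for the optimizer.
    """
    weights = _unpack(theta.astype(X.dtype), shapes)
    acts = _forward(weights, X)
    P = acts[-1]
    n = X.shape[0]
    loss = -np.sum(Y * np.log(np.maximum(P, np.finfo(P.dtype).tiny))) / n

    grads = [None] * len(weights)
    delta = (P - Y) / n  # dL/dz at the output
    n_layers = len(weights) // 2
    for layer in range(n_layers - 1, -1, -1):
        a_prev = acts[layer]
        grads[2 * layer] = a_prev.T @ delta
        grads[2 * layer + 1] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ weights[2 * layer].T) * (acts[layer] > 0)
    g = np.concatenate([gr.ravel() for gr in grads]).astype(np.float64)
    return float(loss), g


def _init_theta(shapes, rng: np.random.Generator, scale: float | None) -> np.ndarray:
    parts = []
    for shp in shapes:
        if len(shp) == 2:
            s = scale if scale is not None else np.sqrt(2.0 / shp[0])
            parts.append(rng.standard_normal(shp).ravel() * s)
        else:
            parts.append(np.zeros(shp))
    return np.concatenate(parts)


# ------------------------------------------------------------------- train

def train(config: NetworkConfig, X: np.ndarray, y: np.ndarray) -> TrainedNetwork:
    """Fit the network on labeled feature vectors.

    ``y`` may hold any hashable labels; the class order is the sorted unique
    order.  Raises on non-finite features or fewer than two classes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training data")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")

    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
        Xs = (X - mean) / scale
    else:
        mean = scale = None
        Xs = X

    class_index = {c: i for i, c in enumerate(classes.tolist())}
    dtype = np.dtype(config.dtype)
    Y = np.zeros((X.shape[0], classes.size), dtype=dtype)
    Y[np.arange(X.shape[0]), [class_index[c] for c in y.tolist()]] = 1.0
    Xs = Xs.astype(dtype)

    shapes = _shapes(X.shape[1], config.hidden_sizes, classes.size)
    rng = np.random.default_rng(config.seed)
    theta0 = _init_theta(shapes, rng, config.init_scale)

    losses: list[float] = []
    stop_reason: list[str] = []

    def callback(intermediate_result):
        losses.append(float(intermediate_result.fun))
        if intermediate_result.fun < config.tol:
            stop_reason.append("loss_below_tol")
            raise StopIteration

    res = minimize(
        _loss_grad, theta0, args=(shapes, Xs, Y), jac=True, method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.max_iter,
            "maxfun": 50 * config.max_iter,
            "gtol": config.tol,        # gradient inf-norm rule
            "ftol": 1e-12,             # leave stopping to the explicit rules
        },
    )
    if not stop_reason:
        if res.nit >= config.max_iter:
            stop_reason.append("max_iter")
        elif np.max(np.abs(res.jac)) < config.tol:
            stop_reason.append("gradient_below_tol")
        elif res.fun < config.tol:
            stop_reason.append("loss_below_tol")
        else:
            stop_reason.append(f"optimizer: {res.message}")

    net = TrainedNetwork(
        weights=_unpack(res.x, shapes),
        classes=classes.tolist(),
        mean=mean, scale=scale, config=config,
        training_log={
            "loss": losses,
            "final_loss": float(res.fun),
            "n_iter": int(res.nit),
            "stop_reason": stop_reason[0],
        },
    )
    log.info(
        "trained %d-class network in %d iterations (%s, final loss %.3g)",
        classes.size, res.nit, stop_reason[0], res.fun,
    )
    return net


def predict(
    net: TrainedNetwork, X: np.ndarray, return_proba: bool = False
):
    """Class labels (argmax probability; ties go to the lowest class index).

    With ``return_proba`` also returns the softmax probability rows.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != net.n_features:
        raise ValueError(
            f"feature dimension mismatch: expected {net.n_features}, got {X.shape[1]}"
        )
    if net.mean is not None:
        X = (X - net.mean) / net.scale
    P = _forward(net.weights, X)[-1]
    labels = np.asarray(net.classes)[np.argmax(P, axis=1)]
    return (labels, P) if return_proba else labels
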