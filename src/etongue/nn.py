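"""Feed-forward neural network with hand-written backpropagation.

A small multilayer perceptron: per-layer affine maps followed by
tanh / logistic-sigmoid / ReLU / linear activations, optional inverted
dropout on hidden layers (``keep_prob`` is the probability of KEEPING a
unit), full-batch SGD or Adam training on a mean-squared-error loss
(reported as RMSE).  The backward pass exposes the gradient with respect
to the network output so the deep-kernel module can chain its
marginal-likelihood gradient through the same code path.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


class DivergenceError(RuntimeError):
    pass


def _logsig(z):
    return 1.0 / (1.0 + np.exp(-z))


#: activation -> (f(z), f'(z) expressed via the activation value a)
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda a, z: 1.0 - a ** 2),
    "logsig": (_logsig, lambda a, z: a * (1.0 - a)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a, z: (z > 0).astype(float)),
    "linear": (lambda z: z, lambda a, z: np.ones_like(z)),
}


@dataclass
class AnnParams:
    """Weights, biases, activation tags and dropout keep-probabilities."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activations: list[str]
    keep_probs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.keep_probs:
            self.keep_probs = [1.0] * len(self.weights)
        if not (len(self.weights) == len(self.biases) == len(self.activations)
                == len(self.keep_probs)):
            raise ValueError("per-layer lists must have equal length")
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape[1] != b.shape[0]:
                raise ValueError(f"layer {i}: bias width mismatch")
            if i > 0 and self.weights[i - 1].shape[1] != W.shape[0]:
                raise ValueError(f"layer {i}: input width mismatch")
        for a in self.activations:
            if a not in ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        for p in self.keep_probs:
            if not 0 < p <= 1:
                raise ValueError("keep probabilities must be in (0, 1]")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [W.shape[1] for W in self.weights]

    def flat(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W, b in zip(self.weights, self.biases):
            out += [W, b]
        return out

    def copy(self) -> "AnnParams":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {"weights": [W.tolist() for W in self.weights],
                "biases": [b.tolist() for b in self.biases],
                "activations": list(self.activations),
                "keep_probs": list(self.keep_probs)}

    @classmethod
    def from_dict(cls, d: dict) -> "AnnParams":
        return cls([np.array(W, float) for W in d["weights"]],
                   [np.array(b, float) for b in d["biases"]],
                   list(d["activations"]), list(d["keep_probs"]))


def init_params(layer_sizes: Sequence[int], activations: Sequence[str],
                keep_probs: Optional[Sequence[float]] = None,
                rng: Optional[np.random.Generator] = None) -> AnnParams:
    """Glorot-uniform initialization."""
    rng = rng or np.random.default_rng(0)
    Ws, bs = [], []
    for fan_in, fan_out in zip(layer_sizes, layer_sizes[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        Ws.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
        bs.append(np.zeros(fan_out))
    kp = list(keep_probs) if keep_probs is not None else [1.0] * len(Ws)
    return AnnParams(Ws, bs, list(activations), kp)


def forward_cache(X: np.ndarray, params: AnnParams, train_mode: bool = False,
                  rng: Optional[np.random.Generator] = None):
    """Forward pass keeping intermediates for backprop.

    Inverted dropout is applied to every layer's activation except the
    output layer, only when ``train_mode`` is true.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != params.weights[0].shape[0]:
        raise ValueError(f"input width {X.shape[1]} does not match network "
                         f"input {params.weights[0].shape[0]}")
    a = X
    acts, pre, masks = [X], [], []
    n_layers = len(params.weights)
    for i, (W, b, name) in enumerate(zip(params.weights, params.biases,
                                         params.activations)):
        z = a @ W + b
        f, _ = ACTIVATIONS[name]
        a = f(z)
        if train_mode and i < n_layers - 1 and params.keep_probs[i] < 1.0:
            if rng is None:
                raise ValueError("train_mode dropout requires an rng")
            mask = (rng.random(a.shape) < params.keep_probs[i]).astype(float)
            a = a * mask / params.keep_probs[i]
            masks.append(mask)
        else:
            masks.append(None)
        pre.append(z)
        acts.append(a)
    return a, (acts, pre, masks)


def ann_forward(x: np.ndarray, params: AnnParams, train_mode: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Network output; 1-D input gives a 1-D output."""
    squeeze = np.asarray(x).ndim == 1
    out, _ = forward_cache(x, params, train_mode, rng)
    return out[0] if squeeze else out


def backward(params: AnnParams, cache, dL_dout: np.ndarray):
    """Backpropagate an upstream output gradient.

    Returns (grad_weights, grad_biases, dL_dinput) — exactly the
    chain-rule derivatives dC/dW and dC/db of the layered affine +
    activation composition.
    """
    acts, pre, masks = cache
    gW = [np.zeros_like(W) for W in params.weights]
    gb = [np.zeros_like(b) for b in params.biases]
    delta = np.atleast_2d(dL_dout)
    for i in reversed(range(len(params.weights))):
        name = params.activations[i]
        _, dfn = ACTIVATIONS[name]
        if masks[i] is not None:
            delta = delta * masks[i] / params.keep_probs[i]
        delta = delta * dfn(acts[i + 1] if masks[i] is None
                            else ACTIVATIONS[name][0](pre[i]), pre[i])
        gW[i] = acts[i].T @ delta
        gb[i] = delta.sum(axis=0)
        delta = delta @ params.weights[i].T
    return gW, gb, delta


def mse_loss_and_grads(params: AnnParams, X: np.ndarray, Y: np.ndarray,
                       train_mode: bool = False,
                       rng: Optional[np.random.Generator] = None):
    """Half mean-squared-error objective and its parameter gradients."""
    Y = np.atleast_2d(np.asarray(Y, float))
    out, cache = forward_cache(X, params, train_mode, rng)
    resid = out - Y
    loss = 0.5 * float((resid ** 2).mean())
    dL_dout = resid / resid.size
    gW, gb, _ = backward(params, cache, dL_dout)
    return loss, gW, gb


# -- optimizers -----------------------------------------------------------------

class Adam:
    def __init__(self, shapes, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, values, grads):
        self.t += 1
        out = []
        for i, (x, g) in enumerate(zip(values, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(x - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


class Sgd:
    def __init__(self, shapes, lr=0.01):
        self.lr = lr

    def step(self, values, grads):
        return [x - self.lr * g for x, g in zip(values, grads)]


def make_optimizer(tag: str, shapes, lr: float):
    tag = tag.lower()
    if tag == "adam":
        return Adam(shapes, lr)
    if tag == "sgd":
        return Sgd(shapes, lr)
    raise ValueError(f"unknown optimizer {tag!r} (use 'Adam' or 'SGD')")


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    max_epochs: int = 300
    optimizer: str = "Adam"
    loss: str = "rmse"
    seed: int = 0
    early_stop_goal: float = 1e-6
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.max_epochs > 1000:
            raise ValueError("max_epochs capped at 1000")


def train_ann(X: np.ndarray, Y: np.ndarray, arch: AnnParams | None = None,
              cfg: TrainConfig | None = None,
              hidden: Sequence[int] = (64, 32),
              hidden_activation: str = "tanh",
              output_activation: str = "linear",
              keep_prob: float = 1.0) -> AnnParams:
    """Full-batch gradient training; returns the best-validation parameters.

    A seeded fraction of the rows is held out for validation-based early
    selection; the returned parameters are those with the lowest
    validation loss along the trajectory (deterministic given the seed).
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
        raise ValueError("non-finite training data")
    rng = np.random.default_rng(cfg.seed)
    if arch is None:
        sizes = [X.shape[1], *hidden, Y.shape[1]]
        acts = [hidden_activation] * len(hidden) + [output_activation]
        kp = [keep_prob] * len(hidden) + [1.0]
        arch = init_params(sizes, acts, kp, rng)
    params = arch.copy()

    n = X.shape[0]
    n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 5 else 0
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    flat = params.flat()
    opt = make_optimizer(cfg.optimizer, [p.shape for p in flat],
                         cfg.learning_rate)
    best = (np.inf, params.copy())
    for epoch in range(cfg.max_epochs):
        loss, gW, gb = mse_loss_and_grads(params, Xtr, Ytr,
                                          train_mode=True, rng=rng)
        if not np.isfinite(loss):
            raise DivergenceError(
                f"training diverged at epoch {epoch} "
                f"(learning_rate={cfg.learning_rate})")
        grads = [g for pair in zip(gW, gb) for g in pair]
        new_flat = opt.step(params.flat(), grads)
        for i in range(len(params.weights)):
            params.weights[i] = new_flat[2 * i]
            params.biases[i] = new_flat[2 * i + 1]
        if n_val:
            pred = ann_forward(Xval, params)
            vloss = 0.5 * float(((pred - Yval) ** 2).mean())
        else:
            vloss = loss
        if vloss < best[0]:
            best = (vloss, params.copy())
        if vloss < cfg.early_stop_goal:
            break
    return best[1]
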