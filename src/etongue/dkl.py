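"""Deep kernel learning: a GP whose kernel acts on learned network features.

The base RBF kernel is composed with a neural feature map g(x, w):

    k_deep(x, x') = k_RBF(g(x, w), g(x', w) | l, sigma^2)

One shared network maps the 17 enriched sensor features to a low-
dimensional feature space (width sized by PCA explained variance,
default 8); each target ion gets its own GP head (length-scale and noise)
over that shared space.  All parameters {w, l_j, sigma_j^2} are learned
jointly by gradient ascent on the summed per-ion log marginal likelihood,
with the likelihood gradient backpropagated through the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .gp import GpState, KernelSpec, _rbf_objective_and_grads, gp_predict
from .nn import (AnnParams, DivergenceError, TrainConfig, ann_forward,
                 backward, forward_cache, init_params, make_optimizer)


@dataclass
class DklState:
    """Fitted deep-kernel model: shared network plus per-ion GP heads.

    Targets are standardized per ion internally (the GP prior mean is
    zero); ``y_means``/``y_stds`` undo the transform at prediction time.
    """

    net: AnnParams
    specs: list[KernelSpec]
    Z_train: np.ndarray
    Y_std: np.ndarray
    y_means: np.ndarray
    y_stds: np.ndarray
    heads: list[GpState] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Z_train = np.atleast_2d(np.asarray(self.Z_train, float))
        self.Y_std = np.atleast_2d(np.asarray(self.Y_std, float))
        if len(self.specs) != self.Y_std.shape[1]:
            raise ValueError("one kernel spec per target required")
        if not self.heads:
            self.heads = [GpState(spec, self.Z_train, self.Y_std[:, j])
                          for j, spec in enumerate(self.specs)]


def dkl_objective_and_grads(net: AnnParams, log_l: np.ndarray,
                            log_s2: np.ndarray, X: np.ndarray,
                            Y_std: np.ndarray, train_mode: bool = False,
                            rng: Optional[np.random.Generator] = None):
    """Summed per-ion log marginal likelihood and all its gradients.

    Returns (value, grad_weights, grad_biases, d_log_l, d_log_s2).  The
    per-ion feature gradients dL/dZ are accumulated and backpropagated
    through the shared network by the chain rule.
    """
    Z, cache = forward_cache(X, net, train_mode, rng)
    m = Y_std.shape[1]
    total = 0.0
    dZ = np.zeros_like(Z)
    d_ll = np.zeros(m)
    d_ls = np.zeros(m)
    for j in range(m):
        val, dZj, dlj, dsj = _rbf_objective_and_grads(
            Z, Y_std[:, j], log_l[j], log_s2[j])
        total += val
        dZ += dZj
        d_ll[j] = dlj
        d_ls[j] = dsj
    gW, gb, _ = backward(net, cache, dZ)
    return total, gW, gb, d_ll, d_ls


def dkl_fit(X: np.ndarray, Y: np.ndarray,
            hidden: Sequence[int] = (64, 32), n_features: int = 8,
            cfg: Optional[TrainConfig] = None,
            hidden_activation: str = "tanh",
            feature_activation: str = "linear",
            keep_prob: float = 1.0,
            init_length_scale: Optional[float] = None,
            init_noise_var: float = 0.05) -> DklState:
    """Joint maximum-marginal-likelihood training of network and kernels.

    Full-batch Adam (or SGD) ascent on the summed per-ion objective;
    deterministic given ``cfg.seed``.  The parameters with the best
    objective along the trajectory are returned.
    """
    cfg = cfg or TrainConfig(learning_rate=0.01, max_epochs=200)
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n, m = Y.shape
    y_means = Y.mean(axis=0)
    y_stds = Y.std(axis=0)
    y_stds[y_stds == 0] = 1.0
    Y_std = (Y - y_means) / y_stds

    rng = np.random.default_rng(cfg.seed)
    sizes = [X.shape[1], *hidden, n_features]
    acts = [hidden_activation] * len(hidden) + [feature_activation]
    kp = [keep_prob] * len(hidden) + [1.0]
    net = init_params(sizes, acts, kp, rng)
    if init_length_scale is None:
        # median-distance heuristic on the initial feature embedding
        Z0 = ann_forward(X, net)
        d2 = ((Z0[:, None, :] - Z0[None, :, :]) ** 2).sum(-1)
        med = np.sqrt(np.median(d2[np.triu_indices(len(Z0), 1)]))
        init_length_scale = float(med) if med > 0 else 1.0
    log_l = np.full(m, np.log(init_length_scale))
    log_s2 = np.full(m, np.log(init_noise_var))

    def pack():
        return net.flat() + [log_l, log_s2]

    opt = make_optimizer(cfg.optimizer, [p.shape for p in pack()],
                         cfg.learning_rate)
    best_val = -np.inf
    best = (net.copy(), log_l.copy(), log_s2.copy())
    for epoch in range(cfg.max_epochs):
        val, gW, gb, dll, dls = dkl_objective_and_grads(
            net, log_l, log_s2, X, Y_std,
            train_mode=keep_prob < 1.0, rng=rng)
        if not np.isfinite(val):
            raise DivergenceError(f"DKL objective diverged at epoch {epoch} "
                                  f"(learning_rate={cfg.learning_rate})")
        if val > best_val:
            best_val = val
            best = (net.copy(), log_l.copy(), log_s2.copy())
        # ascent: negate gradients for the descent-form optimizers
        grads = [-g for pair in zip(gW, gb) for g in pair] + [-dll, -dls]
        new = opt.step(pack(), grads)
        for i in range(len(net.weights)):
            net.weights[i] = new[2 * i]
            net.biases[i] = new[2 * i + 1]
        log_l, log_s2 = new[-2], new[-1]
        log_s2 = np.maximum(log_s2, np.log(1e-6))

    net, log_l, log_s2 = best
    Z = ann_forward(X, net)
    specs = [KernelSpec("RBF", float(np.exp(log_l[j])),
                        float(np.exp(log_s2[j]))) for j in range(m)]
    return DklState(net, specs, Z, Y_std, y_means, y_stds)


def dkl_predict(state: DklState, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-ion posterior means and variances on the original target scale."""
    Z = ann_forward(np.atleast_2d(np.asarray(X, float)), state.net)
    m = len(state.heads)
    means = np.empty((Z.shape[0], m))
    variances = np.empty((Z.shape[0], m))
    for j, head in enumerate(state.heads):
        mu, var = gp_predict(head, Z)
        means[:, j] = mu * state.y_stds[j] + state.y_means[j]
        variances[:, j] = var * state.y_stds[j] ** 2
    return means, variances
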