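"""Gaussian-process regression with a zero prior mean.

The observation model is y = f(x) + eps, eps ~ N(0, sigma^2).  Kernels:

* RBF (squared exponential): k(x,x') = exp(-|x-x'|^2 / (2 l^2)), k(x,x)=1.
* Dotproduct: k(x,x') = x . x'.
* Spectral mixture (Wilson-Adams): a sum of Q Gaussian-envelope cosine
  components, k(x,x) = sum_q a_q.

The kernel-learning objective is the log marginal likelihood in its
proportional form

    L(theta) = -y^T (K + sigma^2 I)^{-1} y - log|K + sigma^2 I|

whose maximizer coincides with the conventionally 1/2-scaled version.
Factorizations use a Cholesky with a jitter ladder (1e-8 to 1e-4 of the
mean diagonal) before raising a numerical error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, LinAlgError


class NumericalError(RuntimeError):
    pass


@dataclass
class KernelSpec:
    kind: str = "RBF"  # RBF | Dotproduct | SM
    length_scale: float = 1.0
    noise_var: float = 0.01
    sm_weights: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    sm_means: np.ndarray = field(default_factory=lambda: np.zeros((2, 1)))
    sm_scales: np.ndarray = field(default_factory=lambda: np.ones((2, 1)))

    def __post_init__(self) -> None:
        if self.kind not in ("RBF", "Dotproduct", "SM"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")
        if self.noise_var < 0:
            raise ValueError("noise variance must be >= 0")
        self.sm_weights = np.asarray(self.sm_weights, float)
        self.sm_means = np.atleast_2d(np.asarray(self.sm_means, float))
        self.sm_scales = np.atleast_2d(np.asarray(self.sm_scales, float))
        if np.any(self.sm_weights < 0):
            raise ValueError("spectral-mixture weights must be >= 0")

    def copy(self) -> "KernelSpec":
        return KernelSpec(self.kind, self.length_scale, self.noise_var,
                          self.sm_weights.copy(), self.sm_means.copy(),
                          self.sm_scales.copy())

    def to_dict(self) -> dict:
        return {"kind": self.kind, "length_scale": self.length_scale,
                "noise_var": self.noise_var,
                "sm_weights": self.sm_weights.tolist(),
                "sm_means": self.sm_means.tolist(),
                "sm_scales": self.sm_scales.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(d["kind"], d["length_scale"], d["noise_var"],
                   np.array(d["sm_weights"]), np.array(d["sm_means"]),
                   np.array(d["sm_scales"]))


def _sqdist(X: np.ndarray, X2: np.ndarray) -> np.ndarray:
    d = X[:, None, :] - X2[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def kernel_matrix(spec: KernelSpec, X: np.ndarray,
                  X2: Optional[np.ndarray] = None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    X2 = X if X2 is None else np.atleast_2d(np.asarray(X2, float))
    if X.shape[1] != X2.shape[1]:
        raise ValueError("kernel inputs must share dimensionality")
    if spec.kind == "RBF":
        return np.exp(-_sqdist(X, X2) / (2.0 * spec.length_scale ** 2))
    if spec.kind == "Dotproduct":
        return X @ X2.T
    # spectral mixture, product over dimensions
    tau = X[:, None, :] - X2[None, :, :]
    out = np.zeros((X.shape[0], X2.shape[0]))
    for a, mu, sc in zip(spec.sm_weights, spec.sm_means, spec.sm_scales):
        env = np.exp(-2.0 * np.pi ** 2 * np.sum(tau ** 2 * sc ** 2, axis=-1))
        cosine = np.cos(2.0 * np.pi * np.sum(tau * mu, axis=-1))
        out += a * env * cosine
    return out


def kernel_eval(spec: KernelSpec, x: np.ndarray, x2: np.ndarray) -> float:
    x = np.atleast_1d(np.asarray(x, float))
    x2 = np.atleast_1d(np.asarray(x2, float))
    if x.shape != x2.shape:
        raise ValueError("kernel inputs must share dimensionality")
    return float(kernel_matrix(spec, x[None, :], x2[None, :])[0, 0])


def chol_with_jitter(A: np.ndarray):
    """Cholesky factorization, escalating jitter before failing."""
    scale = float(np.mean(np.diag(A))) or 1.0
    for jitter in (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4):
        try:
            return cho_factor(A + jitter * scale * np.eye(A.shape[0]),
                              lower=True)
        except LinAlgError:
            continue
    raise NumericalError("covariance factorization failed even at max jitter")


def gp_log_marginal(X: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """L = -y^T (K+s2 I)^-1 y - log|K+s2 I| (proportional-form objective)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    A = kernel_matrix(spec, X) + spec.noise_var * np.eye(len(y))
    cf = chol_with_jitter(A)
    alpha = cho_solve(cf, y)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return float(-y @ alpha - logdet)


def _rbf_objective_and_grads(Z: np.ndarray, y: np.ndarray,
                             log_l: float, log_s2: float):
    """Objective L and gradients d L / d(Z, log l, log sigma^2) for RBF.

    Returns (L, dZ, d_log_l, d_log_s2).  G = alpha alpha^T - A^{-1} is the
    matrix derivative dL/dA; the feature gradient chains it through
    dK_ij/dz = K_ij (z_j - z_i) / l^2.
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    y = np.asarray(y, float).ravel()
    n = len(y)
    l2 = np.exp(2.0 * log_l)
    s2 = np.exp(log_s2)
    D2 = _sqdist(Z, Z)
    K = np.exp(-D2 / (2.0 * l2))
    A = K + s2 * np.eye(n)
    cf = chol_with_jitter(A)
    alpha = cho_solve(cf, y)
    Ainv = cho_solve(cf, np.eye(n))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    value = float(-y @ alpha - logdet)
    G = np.outer(alpha, alpha) - Ainv
    GK = G * K
    # dL/dZ: rows get 2 * sum_j (G K)_ij (z_j - z_i) / l^2
    W = 2.0 * GK / l2
    dZ = W @ Z - W.sum(axis=1)[:, None] * Z
    d_log_l = float(np.sum(GK * D2) / l2)
    d_log_s2 = float(s2 * np.trace(G))
    return value, dZ, d_log_l, d_log_s2


@dataclass
class GpState:
    """Fitted GP: kernel, stored training data and cached factorization."""

    spec: KernelSpec
    X: np.ndarray
    y: np.ndarray
    _cf: object = None
    _alpha: np.ndarray = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.y = np.asarray(self.y, float).ravel()
        if self.X.shape[0] != len(self.y):
            raise ValueError("training target count must equal input count")
        if self._cf is None:
            A = kernel_matrix(self.spec, self.X) + \
                self.spec.noise_var * np.eye(len(self.y))
            self._cf = chol_with_jitter(A)
            self._alpha = cho_solve(self._cf, self.y)


def gp_fit(X: np.ndarray, y: np.ndarray, init: Optional[KernelSpec] = None,
           n_restarts: int = 2) -> GpState:
    """Maximize the log marginal likelihood over (length-scale, noise).

    RBF only; deterministic multi-start L-BFGS-B in log space with the
    analytic gradient.  Other kernel kinds are used with their given
    parameters (construct a GpState directly).
    """
    init = init or KernelSpec()
    if init.kind != "RBF":
        return GpState(init, X, y)
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()

    def negL(theta):
        val, _, dl, ds = _rbf_objective_and_grads(X, y, theta[0], theta[1])
        return -val, -np.array([dl, ds])

    starts = [(np.log(init.length_scale), np.log(max(init.noise_var, 1e-6)))]
    extra = [(0.0, np.log(0.1)), (np.log(3.0), np.log(0.01))]
    starts += extra[:n_restarts]
    bounds = [(np.log(1e-3), np.log(1e3)), (np.log(1e-6), np.log(10.0))]
    best = None
    for t0 in starts:
        res = optimize.minimize(negL, np.array(t0), jac=True,
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    spec = init.copy()
    spec.length_scale = float(np.exp(best.x[0]))
    spec.noise_var = float(np.exp(best.x[1]))
    return GpState(spec, X, y)


def gp_predict(state: GpState, Xstar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at the query points (zero prior mean)."""
    Xstar = np.atleast_2d(np.asarray(Xstar, float))
    Ks = kernel_matrix(state.spec, Xstar, state.X)
    mean = Ks @ state._alpha
    kss = np.diag(kernel_matrix(state.spec, Xstar))
    # solve L v = Ks^T so that var = kss - sum v^2
    L = np.tril(state._cf[0])
    v = np.linalg.solve(L, Ks.T)
    var = np.maximum(kss - np.einsum("ij,ij->j", v, v), 0.0)
    return mean, var
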