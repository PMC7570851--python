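"""Unified fit/predict wrappers for the three learning machines.

All three regressors share one contract: ``fit(X, Y)`` on scaled features
(rows) against raw mg/L targets (8 columns), ``predict(X)`` returning
mg/L.  Target standardization is handled internally (the GP prior mean is
zero; the ANN trains better on standardized outputs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dkl import DklState, dkl_fit, dkl_predict
from .gp import GpState, KernelSpec, gp_fit, gp_predict
from .nn import AnnParams, TrainConfig, ann_forward, train_ann


class AnnRegressor:
    """Multi-output feed-forward network regressor."""

    def __init__(self, hidden: Sequence[int] = (64, 32),
                 hidden_activation: str = "tanh",
                 output_activation: str = "linear",
                 keep_prob: float = 1.0,
                 learning_rate: float = 0.01, max_epochs: int = 300,
                 optimizer: str = "Adam", seed: int = 0):
        self.hidden = tuple(hidden)
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation
        self.keep_prob = keep_prob
        self.cfg = TrainConfig(learning_rate=learning_rate,
                               max_epochs=max_epochs, optimizer=optimizer,
                               seed=seed)
        self.params: Optional[AnnParams] = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "AnnRegressor":
        Y = np.atleast_2d(np.asarray(Y, float))
        self.y_means = Y.mean(axis=0)
        self.y_stds = Y.std(axis=0)
        self.y_stds[self.y_stds == 0] = 1.0
        Ystd = (Y - self.y_means) / self.y_stds
        self.params = train_ann(
            X, Ystd, cfg=self.cfg, hidden=self.hidden,
            hidden_activation=self.hidden_activation,
            output_activation=self.output_activation,
            keep_prob=self.keep_prob)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model not fitted")
        out = ann_forward(np.atleast_2d(X), self.params)
        return out * self.y_stds + self.y_means


class GpRegressor:
    """Independent isotropic-RBF GP per target ion on the raw feature space."""

    def __init__(self, init_length_scale: float = 1.0,
                 init_noise_var: float = 0.05, seed: int = 0):
        self.init_length_scale = init_length_scale
        self.init_noise_var = init_noise_var
        self.states: Optional[list[GpState]] = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "GpRegressor":
        Y = np.atleast_2d(np.asarray(Y, float))
        self.y_means = Y.mean(axis=0)
        self.y_stds = Y.std(axis=0)
        self.y_stds[self.y_stds == 0] = 1.0
        Ystd = (Y - self.y_means) / self.y_stds
        init = KernelSpec("RBF", self.init_length_scale, self.init_noise_var)
        self.states = [gp_fit(X, Ystd[:, j], init)
                       for j in range(Y.shape[1])]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.states is None:
            raise RuntimeError("model not fitted")
        X = np.atleast_2d(X)
        out = np.empty((X.shape[0], len(self.states)))
        for j, st in enumerate(self.states):
            mu, _ = gp_predict(st, X)
            out[:, j] = mu * self.y_stds[j] + self.y_means[j]
        return out


class DklRegressor:
    """Deep-kernel model: shared feature network, per-ion GP heads."""

    def __init__(self, hidden: Sequence[int] = (64, 32), n_features: int = 8,
                 hidden_activation: str = "tanh",
                 feature_activation: str = "linear",
                 keep_prob: float = 1.0, learning_rate: float = 0.01,
                 max_epochs: int = 200, optimizer: str = "Adam",
                 seed: int = 0):
        self.hidden = tuple(hidden)
        self.n_features = n_features
        self.hidden_activation = hidden_activation
        self.feature_activation = feature_activation
        self.keep_prob = keep_prob
        self.cfg = TrainConfig(learning_rate=learning_rate,
                               max_epochs=max_epochs, optimizer=optimizer,
                               seed=seed)
        self.state: Optional[DklState] = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "DklRegressor":
        self.state = dkl_fit(X, Y, hidden=self.hidden,
                             n_features=self.n_features, cfg=self.cfg,
                             hidden_activation=self.hidden_activation,
                             feature_activation=self.feature_activation,
                             keep_prob=self.keep_prob)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.state is None:
            raise RuntimeError("model not fitted")
        mean, _ = dkl_predict(self.state, X)
        return mean


MODEL_KINDS = ("ANN", "GP", "DKL")


def make_model(kind: str, seed: int = 0, n_features: int = 8, **kwargs):
    """Factory used by cross-validation and the CLI."""
    kind = kind.upper()
    if kind == "ANN":
        return AnnRegressor(seed=seed, **kwargs)
    if kind == "GP":
        return GpRegressor(seed=seed, **kwargs)
    if kind == "DKL":
        return DklRegressor(seed=seed, n_features=n_features, **kwargs)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


# -- single-archive serialization ------------------------------------------------

def archive_model(model, scaler_state, feature_names: Sequence[str],
                  seed: int, path: str | Path) -> None:
    """Serialize a fitted model plus its preprocessing to one JSON archive."""
    d: dict = {"feature_names": list(feature_names), "seed": seed,
               "scaler": scaler_state.to_dict()}
    if isinstance(model, AnnRegressor):
        d["kind"] = "ANN"
        d["params"] = model.params.to_dict()
        d["y_means"], d["y_stds"] = model.y_means.tolist(), model.y_stds.tolist()
    elif isinstance(model, GpRegressor):
        d["kind"] = "GP"
        d["states"] = [{"spec": st.spec.to_dict(), "X": st.X.tolist(),
                        "y": st.y.tolist()} for st in model.states]
        d["y_means"], d["y_stds"] = model.y_means.tolist(), model.y_stds.tolist()
    elif isinstance(model, DklRegressor):
        st = model.state
        d["kind"] = "DKL"
        d["net"] = st.net.to_dict()
        d["specs"] = [s.to_dict() for s in st.specs]
        d["Z_train"] = st.Z_train.tolist()
        d["Y_std"] = st.Y_std.tolist()
        d["y_means"], d["y_stds"] = st.y_means.tolist(), st.y_stds.tolist()
    else:
        raise TypeError(f"cannot archive {type(model).__name__}")
    Path(path).write_text(json.dumps(d))


def load_model(path: str | Path):
    """Inverse of :func:`archive_model`; returns (model, scaler, feature_names)."""
    from .features import ScalerState

    d = json.loads(Path(path).read_text())
    scaler = ScalerState.from_dict(d["scaler"])
    kind = d["kind"]
    if kind == "ANN":
        model = AnnRegressor(seed=d["seed"])
        model.params = AnnParams.from_dict(d["params"])
    elif kind == "GP":
        model = GpRegressor(seed=d["seed"])
        model.states = [GpState(KernelSpec.from_dict(s["spec"]),
                                np.array(s["X"]), np.array(s["y"]))
                        for s in d["states"]]
    elif kind == "DKL":
        model = DklRegressor(seed=d["seed"])
        model.state = DklState(
            AnnParams.from_dict(d["net"]),
            [KernelSpec.from_dict(s) for s in d["specs"]],
            np.array(d["Z_train"]), np.array(d["Y_std"]),
            np.array(d["y_means"]), np.array(d["y_stds"]))
    else:
        raise ValueError(f"unknown archived model kind {kind!r}")
    if kind in ("ANN", "GP"):
        model.y_means = np.array(d["y_means"])
        model.y_stds = np.array(d["y_stds"])
    return model, scaler, d["feature_names"]
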