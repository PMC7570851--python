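"""Standard-addition feature enrichment and preprocessing.

A measurement record is turned into a 17-dimensional feature vector:

    [Ux_1..Ux_8,  (Ux-U0)_1..(Ux-U0)_8,  temperature]

The raw sample-phase block carries the absolute response; the enriched
difference block is invariant to any session-constant additive drift,
which is the whole point of pairing a baseline read with each sample
read.  Features are min-max scaled to [-1, 1] on the training split, and
the learned model's bottleneck width is sized by PCA explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from sklearn.decomposition import PCA

from .ions import CHANNEL_ORDER
from .sensors import MeasurementRecord

N_FEATURES = 17

#: Documented feature ordering.
FEATURE_NAMES = (
    [f"ux_{ch}" for ch in CHANNEL_ORDER]
    + [f"fe_{ch}" for ch in CHANNEL_ORDER]
    + ["temp_C"]
)


def enrich(record: MeasurementRecord) -> np.ndarray:
    """17-vector: 8 raw Ux channels, 8 enriched differences Ux-U0, temperature."""
    out = np.empty(N_FEATURES)
    out[0:8] = record.ux
    out[8:16] = record.ux - record.u0
    out[16] = record.temperature
    return out


def enrich_all(records: Sequence[MeasurementRecord]) -> np.ndarray:
    return np.array([enrich(r) for r in records])


@dataclass
class ScalerState:
    """Per-feature affine map fitted on training data: min -> -1, max -> +1.

    Constant features map to 0 by convention (no division by zero); test
    values outside the training range map outside [-1, 1] (no clipping).
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def to_dict(self) -> dict:
        return {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(np.array(d["minimum"], float), np.array(d["maximum"], float))


def fit_scaler(features: np.ndarray) -> ScalerState:
    features = np.asarray(features, float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("fit_scaler needs at least 2 training rows")
    return ScalerState(features.min(axis=0), features.max(axis=0))


def apply_scaler(state: ScalerState, features: np.ndarray) -> np.ndarray:
    if state is None:
        raise ValueError("scaler has not been fitted")
    features = np.atleast_2d(np.asarray(features, float))
    span = state.maximum - state.minimum
    mid = (state.maximum + state.minimum) / 2.0
    out = np.zeros_like(features)
    ok = span > 0
    out[:, ok] = 2.0 * (features[:, ok] - mid[ok]) / span[ok]
    return out


def select_pc_count(scaled_features: np.ndarray, variance_threshold: float = 0.98) -> int:
    """Smallest number of principal components explaining the threshold variance.

    Used to size the last hidden layer of the deep-kernel network: on the
    default array roughly eight components carry ~98% of the variance,
    matching the eight target ions.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    X = np.asarray(scaled_features, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows to select component count")
    if np.allclose(X, X[0], atol=1e-12):
        warnings.warn("degenerate (constant) feature matrix; returning 1 component")
        return 1
    ratios = PCA().fit(X).explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    # guard against float round-off at threshold 1.0
    return int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
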