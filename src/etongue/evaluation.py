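"""Metrics, 10-fold cross-validation and the three-model comparison.

Metrics per ion: RMSE (mg/L), the coefficient of determination R^2 (about
the mean of the actual values), and the coefficient of variation of
replicate predictions (per-sample SD over the grand mean, in percent).
The comparison harness runs ANN / GP / DKL under identical seeded k-fold
splits, with scaling and bottleneck sizing re-fitted inside each training
fold, and reports medians across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import apply_scaler, enrich_all, fit_scaler, select_pc_count
from .ions import ION_ORDER, SolutionSample, baseline_solution
from .models import make_model
from .sensors import MeasurementRecord, SensorArrayConfig, measure_msam

REPORT_COLUMNS = ["ion", "model", "rmse_mgL", "r2", "cv_pct",
                  "slope", "intercept", "n", "seed"]


@dataclass
class MetricsRow:
    ion: str
    model: str
    rmse: float
    r_squared: float
    cv: float
    slope: float
    intercept: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if np.isfinite(self.cv) and self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2")


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("actual and predicted must be equal-length 1-D")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r_squared(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot about the mean."""
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or len(a) < 2:
        raise ValueError("need >= 2 equal-length points")
    ss_tot = float(((a - a.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined: actual values have zero variance")
    return 1.0 - float(((a - p) ** 2).sum()) / ss_tot


def coeff_variation(replicates: np.ndarray) -> float:
    """Mean per-sample CV of replicate predictions, percent.

    ``replicates`` has shape (n_samples, n_replicates).  Each sample's
    standard deviation (ddof=1) is divided by the grand mean of all
    entries; the per-sample CVs are averaged.
    """
    R = np.atleast_2d(np.asarray(replicates, float))
    if R.shape[1] < 2:
        raise ValueError("need >= 2 replicates per sample")
    grand_mean = float(R.mean())
    if grand_mean == 0:
        raise ValueError("CV undefined: zero grand mean")
    sds = R.std(axis=1, ddof=1)
    return float(np.mean(sds / abs(grand_mean)) * 100.0)


def _targets_matrix(records: Sequence[MeasurementRecord]) -> np.ndarray:
    return np.array([[r.targets[ion] for ion in ION_ORDER] for r in records])


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded balanced partition into k test folds (sizes differ by <= 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(order, k)]


def _replicate_predictions(records, idx, array, model, scaler, seed,
                           n_replicates=3):
    """Re-measure each test sample with fresh noise and predict each replicate."""
    base = baseline_solution(1.0)
    reps = np.empty((len(idx), n_replicates, len(ION_ORDER)))
    for a, i in enumerate(idx):
        rec = records[i]
        sample = SolutionSample({ion: rec.targets[ion] for ion in ION_ORDER},
                                rec.temperature)
        for r in range(n_replicates):
            rep_seed = int(np.random.SeedSequence([seed, int(i), r])
                           .generate_state(1)[0] % 2**31)
            rep = measure_msam(base, sample, array, seed=rep_seed)
            feats = apply_scaler(scaler, enrich_all([rep]))
            reps[a, r] = model.predict(feats)[0]
    return reps


def kfold_cv(records: Sequence[MeasurementRecord], model_kind: str,
             k: int = 10, seed: int = 0,
             array: Optional[SensorArrayConfig] = None,
             n_replicates: int = 3, pc_threshold: float = 0.98,
             model_kwargs: Optional[dict] = None) -> list[MetricsRow]:
    """Out-of-fold evaluation of one model on a measured dataset.

    The feature scaler and the PCA-based bottleneck width are fitted on
    each training fold only.  If an array configuration is supplied, each
    test sample is additionally re-measured ``n_replicates`` times with
    fresh noise for the coefficient-of-variation metric.
    """
    # sort by sample id so metrics are invariant to record order
    records = sorted(records, key=lambda r: r.sample_id)
    n = len(records)
    X_raw = enrich_all(records)
    Y = _targets_matrix(records)
    folds = kfold_split(n, k, seed)
    preds = np.full_like(Y, np.nan, dtype=float)
    rep_blocks = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        scaler = fit_scaler(X_raw[train_idx])
        Xtr = apply_scaler(scaler, X_raw[train_idx])
        Xte = apply_scaler(scaler, X_raw[test_idx])
        fold_seed = int(np.random.SeedSequence([seed, f]).generate_state(1)[0]
                        % 2**31)
        kwargs = dict(model_kwargs or {})
        if model_kind.upper() == "DKL" and "n_features" not in kwargs:
            kwargs["n_features"] = select_pc_count(Xtr, pc_threshold)
        model = make_model(model_kind, seed=fold_seed, **kwargs)
        model.fit(Xtr, Y[train_idx])
        preds[test_idx] = model.predict(Xte)
        if array is not None:
            rep_blocks.append(_replicate_predictions(
                records, test_idx, array, model, scaler, seed, n_replicates))
    reps = np.concatenate(rep_blocks, axis=0) if rep_blocks else None

    rows = []
    for j, ion in enumerate(ION_ORDER):
        lr = stats.linregress(Y[:, j], preds[:, j])
        cv = (coeff_variation(reps[:, :, j]) if reps is not None
              else float("nan"))
        rows.append(MetricsRow(ion, model_kind.upper(),
                               rmse(Y[:, j], preds[:, j]),
                               r_squared(Y[:, j], preds[:, j]), cv,
                               float(lr.slope), float(lr.intercept), n, seed))
    return rows


def rows_to_frame(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.ion, r.model, r.rmse, r.r_squared, r.cv, r.slope, r.intercept,
          r.n, r.seed] for r in rows],
        columns=REPORT_COLUMNS)


def compare_models(dataset_fn: Callable[[int], tuple[Sequence[MeasurementRecord],
                                                     Optional[SensorArrayConfig]]],
                   configs: dict[str, dict], seeds: Sequence[int],
                   k: int = 10) -> dict[str, pd.DataFrame]:
    """Run the seeded multi-model benchmark.

    ``dataset_fn(seed)`` supplies a fresh dataset (and optionally the
    array configuration enabling replicate CVs) per seed; ``configs`` maps
    model tags to keyword arguments.  A failed model run is recorded as a
    NaN cell, not a fatal error.  Returns the per-seed table and the
    per-(ion, model) medians across seeds.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    all_rows: list[pd.DataFrame] = []
    for seed in seeds:
        records, array = dataset_fn(seed)
        for kind, kwargs in configs.items():
            try:
                rows = kfold_cv(records, kind, k=k, seed=seed, array=array,
                                model_kwargs=kwargs)
                all_rows.append(rows_to_frame(rows))
            except Exception as exc:  # record, don't abort the benchmark
                fail = pd.DataFrame(
                    [[ion, kind.upper(), np.nan, np.nan, np.nan, np.nan,
                      np.nan, len(records), seed] for ion in ION_ORDER],
                    columns=REPORT_COLUMNS)
                fail["error"] = str(exc)
                all_rows.append(fail)
    per_seed = pd.concat(all_rows, ignore_index=True)
    median = (per_seed.groupby(["ion", "model"], sort=False)
              [["rmse_mgL", "r2", "cv_pct", "slope", "intercept"]]
              .median().reset_index())
    return {"per_seed": per_seed, "median": median}
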