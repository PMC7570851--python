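"""The default seeded synthetic benchmark: simulate, cross-validate, compare.

Study conditions: the 100-sample, 10-level fractional-factorial design
over the six ISE ions with random phosphate / magnesium / temperature,
measured by the standard-addition protocol on the default array (session
drift 5 mV, electrode noise 0.5 mV), evaluated by 10-fold CV.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, LevelTable, build_dataset
from .evaluation import compare_models
from .sensors import default_array_config

#: Scaled-down model configurations used for desk-scale runs.
DEFAULT_CONFIGS: dict[str, dict] = {
    "ANN": {"hidden": (64, 32), "max_epochs": 300, "learning_rate": 0.01},
    "GP": {},
    "DKL": {"hidden": (64, 32), "max_epochs": 400, "learning_rate": 0.005,
            "keep_prob": 0.95},
}


def default_dataset_fn(n_levels: int = 10):
    """Dataset factory: fresh design randomization and measurement per seed."""
    levels = LevelTable()

    def fn(seed: int):
        spec = DesignSpec(n_levels=n_levels, seed=seed)
        array = default_array_config(session_seed=seed)
        _, records = build_dataset(spec, levels, array)
        return records, array

    return fn


def run_benchmark(seeds: Sequence[int] = (0, 1, 2, 3, 4),
                  n_levels: int = 10, k: int = 10,
                  configs: Optional[dict] = None) -> dict[str, pd.DataFrame]:
    """Three-model comparison on the default synthetic study conditions."""
    return compare_models(default_dataset_fn(n_levels),
                          configs or DEFAULT_CONFIGS, list(seeds), k=k)


def dkl_wins(median: pd.DataFrame) -> int:
    """Number of ions for which the DKL median RMSE is <= both ANN and GP."""
    wide = median.pivot(index="ion", columns="model", values="rmse_mgL")
    return int(((wide["DKL"] <= wide["ANN"]) & (wide["DKL"] <= wide["GP"])).sum())
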