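"""Dataset CSV and array-configuration file handling."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .ions import CHANNEL_ORDER, ION_ORDER
from .sensors import ElectrodeSpec, MeasurementRecord, SensorArrayConfig

#: Bit-exact dataset schema: identifiers, both measurement phases, targets.
CSV_COLUMNS = (
    ["sample_id", "temp_C"]
    + [f"u0_{ch}" for ch in CHANNEL_ORDER]
    + [f"ux_{ch}" for ch in CHANNEL_ORDER]
    + [f"c_{ion}" for ion in ION_ORDER]
)


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {"sample_id": r.sample_id, "temp_C": r.temperature}
        for j, ch in enumerate(CHANNEL_ORDER):
            row[f"u0_{ch}"] = r.u0[j]
            row[f"ux_{ch}"] = r.ux[j]
        targets = r.targets or {}
        for ion in ION_ORDER:
            row[f"c_{ion}"] = targets.get(ion, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        u0 = [row[f"u0_{ch}"] for ch in CHANNEL_ORDER]
        ux = [row[f"ux_{ch}"] for ch in CHANNEL_ORDER]
        targets = {ion: float(row[f"c_{ion}"]) for ion in ION_ORDER}
        out.append(MeasurementRecord(str(row["sample_id"]), u0, ux,
                                     float(row["temp_C"]), targets=targets))
    return out


def write_dataset(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    try:
        records_to_frame(records).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing dataset to {path}: {exc}") from exc


def read_dataset(path: str | Path) -> list[MeasurementRecord]:
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"failed reading dataset from {path}: {exc}") from exc
    return frame_to_records(df)


# -- array configuration (YAML) ------------------------------------------------

def array_config_to_dict(array: SensorArrayConfig) -> dict:
    d = dataclasses.asdict(array)
    return d


def array_config_from_dict(d: dict) -> SensorArrayConfig:
    d = dict(d)
    d["electrodes"] = [ElectrodeSpec(**e) for e in d["electrodes"]]
    return SensorArrayConfig(**d)


def save_array_config(array: SensorArrayConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(array_config_to_dict(array), fh, sort_keys=False)


def load_array_config(path: str | Path) -> SensorArrayConfig:
    with open(path) as fh:
        return array_config_from_dict(yaml.safe_load(fh))
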