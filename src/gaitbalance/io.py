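"""CSV / JSON readers and writers for the pipeline's artifacts.

Signals travel as a CSV (columns t, acc_AP, acc_ML, acc_V) with a sidecar
JSON holding the sampling rate, stride events and generation parameters;
feature tables are plain CSV with ``subject_id`` and ``class`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .indexes import GaitIndexes
from .simdata import TrunkSignal


def write_signal(signal: TrunkSignal, csv_path, meta: dict | None = None) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({
        "t": signal.t, "acc_AP": signal.acc_AP,
        "acc_ML": signal.acc_ML, "acc_V": signal.acc_V,
    }).to_csv(csv_path, index=False)
    sidecar = {
        "fs": signal.fs,
        "stride_events": np.asarray(signal.stride_events).tolist(),
        **(meta or {}),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_signal(csv_path) -> TrunkSignal:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return TrunkSignal(
        t=df["t"].to_numpy(), acc_AP=df["acc_AP"].to_numpy(),
        acc_ML=df["acc_ML"].to_numpy(), acc_V=df["acc_V"].to_numpy(),
        stride_events=np.asarray(meta["stride_events"], dtype=int),
        fs=float(meta["fs"]),
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise ValueError(f"{path}: feature table must have a 'class' column")
    return df


def indexes_row(ix: GaitIndexes, subject_id: str, label: str) -> dict:
    return {"subject_id": subject_id, "class": label, **ix.as_dict()}
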