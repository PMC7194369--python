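"""Tabular I/O for long-format longitudinal data and run metadata sidecars."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mixed import LongitudinalDataset

__all__ = ["load_dataset", "save_dataset", "write_sidecar"]


def load_dataset(
    path,
    subject_col: str = "subject",
    time_col: str = "time",
    value_col: str = "value",
) -> LongitudinalDataset:
    """Read a delimited long-format file into a dataset.

    Rows with missing or non-numeric time/value fields are dropped (the count
    is logged); subject order of first appearance is preserved.
    """
    df = pd.read_csv(path)
    return LongitudinalDataset.from_dataframe(
        df, subject_col=subject_col, time_col=time_col, value_col=value_col
    )


def save_dataset(data: LongitudinalDataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        return super().default(o)


def write_sidecar(path, **metadata) -> Path:
    """Write a JSON metadata sidecar next to an output file: the run's
    configuration, seed and key fitted quantities, so a run can be replayed."""
    p = Path(str(path) + ".meta.json")
    p.write_text(json.dumps(metadata, indent=2, cls=_Encoder))
    return p
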