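"""Published benchmark tables from the 29-patient GBM follow-up study.

The pipeline was designed around a cohort whose raw data are not
publicly deposited, but whose per-time-point balanced error rates (for
the six best supervised classifiers, on the complete-feature and
imputed-feature variants) and per-time-point sample counts are
published.  These tables ship with the package as plain CSV so that the
weighted-BER machinery can be validated end-to-end against the printed
summary row, and as a worked example of the offset-labelled table
format.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .metrics import parse_offset_label

_PKG = "relapsemri.data.reference"


def _path(name: str) -> Path:
    return Path(resources.files(_PKG) / name)


def ber_table_path(variant: str) -> Path:
    """Path of the shipped per-offset BER table for a dataset variant."""
    if variant not in ("complete", "imputed"):
        raise ValueError(f"unknown variant {variant!r}")
    return _path(f"ber_all_{variant}.csv")


def sample_counts(variant: str) -> dict[int, int]:
    """Per-offset patient counts for a dataset variant."""
    if variant not in ("complete", "imputed"):
        raise ValueError(f"unknown variant {variant!r}")
    frame = pd.read_csv(_path("samples_per_timepoint.csv"))
    return {
        parse_offset_label(row["time_point"]): int(row[variant])
        for _, row in frame.iterrows()
    }


def ber_table(variant: str) -> pd.DataFrame:
    return pd.read_csv(ber_table_path(variant))
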