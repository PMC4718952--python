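"""Validated CSV I/O for measured datasets (tidy long format, RFC-4180)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding import DialysisGeometry, LevelScale
from .simulate import DATASET_COLUMNS, MeasuredDataset

__all__ = ["DatasetValidationError", "read_dataset", "write_dataset"]


class DatasetValidationError(ValueError):
    """Schema or row-level validation failure, with offending line numbers."""


def read_dataset(
    path,
    geometry: DialysisGeometry | None = None,
    i50_scale: LevelScale = "buffer-initial",
) -> MeasuredDataset:
    """Read and validate a measured-concentration CSV.

    Line numbers in error messages are 1-based file lines (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise DatasetValidationError(f"{path}: file does not exist")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DatasetValidationError(f"{path}: file is empty") from None
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetValidationError(f"{path}: missing columns {missing}")

    problems: list[str] = []
    conc = pd.to_numeric(frame["conc_nM"], errors="coerce")
    for idx in frame.index[conc.isna()]:
        problems.append(f"line {idx + 2}: conc_nM is missing or not numeric")
    for idx in frame.index[conc < 0]:
        problems.append(f"line {idx + 2}: conc_nM is negative ({conc[idx]:g})")
    bad_chamber = ~frame["chamber"].isin(["sample", "buffer"])
    for idx in frame.index[bad_chamber]:
        problems.append(f"line {idx + 2}: chamber must be 'sample' or 'buffer'")
    if problems:
        raise DatasetValidationError(f"{path}: " + "; ".join(problems))

    frame["conc_nM"] = conc.astype(float)
    return MeasuredDataset(frame, geometry or DialysisGeometry(), i50_scale)


def write_dataset(dataset: MeasuredDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)
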