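"""Dataset interchange: validated delimited-text reading and writing.

Datasets are comma-separated UTF-8 tables with a header row and columns
participant, trial, bits, n_cues, outcome, choice, rt, condition — one
row per trial.  Response times are in seconds and serialized at
millisecond precision (three decimals, ties away from zero).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .environment import NEGATIVE, POSITIVE, round_half_away
from .simulate import DATASET_COLUMNS

__all__ = ["read_dataset", "write_dataset", "DatasetFormatError"]


class DatasetFormatError(ValueError):
    """Raised for malformed dataset files, naming the offending row/field."""


def _fail(row: int, field: str, message: str):
    # row index is 1-based over data rows (header excluded)
    raise DatasetFormatError(f"row {row}, field '{field}': {message}")


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a trial-level dataset.

    Enforces the schema, rt > 0, outcome/choice labels, n_cues matching
    the pattern, and pattern admissibility (the all-absent pattern
    0...0 and all-present pattern 1...1 are excluded from the task).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"bits": str, "participant": str, "condition": str})
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing columns: {missing}")
    df = df[DATASET_COLUMNS]

    for i, rec in enumerate(df.itertuples(index=False), start=1):
        bits = str(rec.bits)
        if not bits or any(c not in "01" for c in bits):
            _fail(i, "bits", f"not a 0/1 string: {bits!r}")
        ones = bits.count("1")
        if ones == 0 or ones == len(bits):
            _fail(
                i,
                "bits",
                f"pattern {bits} inadmissible: at least one and at most "
                f"{len(bits) - 1} cues must be present (all-absent and "
                "all-present patterns are excluded)",
            )
        if int(rec.n_cues) != ones:
            _fail(i, "n_cues", f"{rec.n_cues} inconsistent with pattern {bits}")
        try:
            rt = float(rec.rt)
        except (TypeError, ValueError):
            _fail(i, "rt", f"not a number: {rec.rt!r}")
        if not np.isfinite(rt) or rt <= 0:
            _fail(i, "rt", f"must be a positive number of seconds, got {rec.rt!r}")
        if rec.outcome not in (POSITIVE, NEGATIVE):
            _fail(i, "outcome", f"must be '{POSITIVE}' or '{NEGATIVE}'")
        if rec.choice not in (POSITIVE, NEGATIVE):
            _fail(i, "choice", f"must be '{POSITIVE}' or '{NEGATIVE}'")
        if pd.isna(rec.trial):
            _fail(i, "trial", "missing value")
    df["trial"] = df["trial"].astype(int)
    df["n_cues"] = df["n_cues"].astype(int)
    df["rt"] = df["rt"].astype(float)
    return df


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a dataset with deterministic column order and formatting.

    rt is serialized with three decimals (millisecond precision, ties
    rounded away from zero); repeated writes of the same dataset are
    byte-identical.
    """
    missing = [c for c in DATASET_COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    out = dataset[DATASET_COLUMNS].copy()
    out["rt"] = [f"{round_half_away(float(x), 3):.3f}" for x in out["rt"]]
    out.to_csv(path, index=False, lineterminator="\n")
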