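"""Reading and rescaling of single-cell fluorescence tables.

Input tables carry one row per cell with four columns: nucleus size
(area, arbitrary units), raw integrated fluorescence, replicative passage,
and experiment replicate.  Fluorescence is mapped to an integer count on
[0, max_count] by assigning max_count to the highest fluorescence observed
across ALL experiments and passages and scaling every other value linearly,
so the state space of the count model matches the data scale.

By default the raw integrated fluorescence is analyzed (the model concerns
the amount of nuclear protein, i.e. the integral signal); dividing by
nucleus size to get a density is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "MalformedTableError",
    "EmptySelectionError",
    "ScaledDataset",
    "read_records",
    "scale_to_counts",
    "select_passage",
    "write_records",
]

REQUIRED_COLUMNS = ("nucleus_size", "fluorescence", "passage", "experiment")


class MalformedTableError(ValueError):
    """The input table is missing columns or contains invalid rows."""


class EmptySelectionError(KeyError):
    """A passage/experiment selection matched no records."""


@dataclass
class ScaledDataset:
    """Integer counts on [0, max_count] with aligned passage/experiment labels."""

    counts: np.ndarray
    passages: np.ndarray
    experiments: np.ndarray
    scale_factor: float  # raw fluorescence units per count
    max_count: int = 1000
    nucleus_sizes: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "count": self.counts,
                "passage": self.passages,
                "experiment": self.experiments,
            }
        )
        if self.nucleus_sizes is not None:
            df["nucleus_size"] = self.nucleus_sizes
        return df


def read_records(
    source,
    dialect: str = "csv",
    on_malformed: str = "error",
) -> pd.DataFrame:
    """Read a single-cell table (one row per cell) into a validated DataFrame.

    Parameters
    ----------
    source : path or file-like
        CSV or TSV file with a header row and the four required columns.
    dialect : {"csv", "tsv"}
        Field separator of the file.
    on_malformed : {"error", "drop"}
        Whether rows with non-positive fluorescence/nucleus size,
        non-numeric fields or passage < 1 abort the read (listing 1-based
        data-row numbers) or are dropped with a warning.

    Returns
    -------
    pandas.DataFrame with columns nucleus_size (float), fluorescence
    (float), passage (int), experiment (str).
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    try:
        raw = pd.read_csv(source, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise MalformedTableError("input table is empty") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise MalformedTableError(f"missing required columns: {missing}")
    if len(raw) == 0:
        raise MalformedTableError("input table has a header but no data rows")

    df = pd.DataFrame(index=raw.index)
    df["nucleus_size"] = pd.to_numeric(raw["nucleus_size"], errors="coerce")
    df["fluorescence"] = pd.to_numeric(raw["fluorescence"], errors="coerce")
    df["passage"] = pd.to_numeric(raw["passage"], errors="coerce")
    df["experiment"] = raw["experiment"].astype(str)

    bad = (
        df["nucleus_size"].isna()
        | df["fluorescence"].isna()
        | df["passage"].isna()
        | (df["nucleus_size"] <= 0)
        | (df["fluorescence"] <= 0)
        | (df["passage"] < 1)
        | (df["passage"] % 1 != 0)
    )
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()  # 1-based data rows
        msg = f"{len(rows)} malformed row(s) at data row number(s) {rows[:20]}"
        if on_malformed == "error":
            raise MalformedTableError(msg)
        warnings.warn(msg + "; dropped", stacklevel=2)
        df = df.loc[~bad]
        if len(df) == 0:
            raise MalformedTableError("no valid rows remain after dropping")
    df["passage"] = df["passage"].astype(int)
    return df.reset_index(drop=True)


def write_records(df: pd.DataFrame, path, dialect: str = "csv") -> None:
    """Write a record table in the same CSV/TSV schema read_records expects."""
    sep = "," if dialect == "csv" else "\t"
    df.to_csv(path, sep=sep, index=False, columns=list(REQUIRED_COLUMNS))


def scale_to_counts(
    records: pd.DataFrame,
    max_count: int = 1000,
    use_density: bool = False,
) -> ScaledDataset:
    """Rescale fluorescence to integer counts on [0, max_count].

    The global maximum over all experiments and passages is assigned
    ``max_count``; every other value is scaled linearly and rounded to the
    nearest integer (half away from zero, since the state space is
    integer-valued).

    Parameters
    ----------
    records : DataFrame from :func:`read_records`.
    max_count : top of the count scale (default 1000).
    use_density : analyze fluorescence / nucleus_size instead of the raw
        integrated fluorescence.
    """
    if len(records) == 0:
        raise MalformedTableError("cannot scale an empty record set")
    signal = records["fluorescence"].to_numpy(dtype=float)
    if use_density:
        signal = signal / records["nucleus_size"].to_numpy(dtype=float)
    top = signal.max()
    if not top > 0:
        raise MalformedTableError("all-signal maximum must be positive")
    counts = np.floor(signal * (max_count / top) + 0.5).astype(int)
    return ScaledDataset(
        counts=counts,
        passages=records["passage"].to_numpy(dtype=int),
        experiments=records["experiment"].to_numpy(dtype=str),
        scale_factor=top / max_count,
        max_count=max_count,
        nucleus_sizes=records["nucleus_size"].to_numpy(dtype=float),
    )


def select_passage(
    dataset: ScaledDataset, passage: int, experiment: str | None = None
) -> np.ndarray:
    """Counts for one passage, optionally restricted to one experiment.

    ``experiment=None`` pools the union of all experiments ("combined").
    """
    mask = dataset.passages == passage
    if experiment is not None:
        mask &= dataset.experiments == str(experiment)
    if not mask.any():
        raise EmptySelectionError(
            f"no records for passage={passage}"
            + (f", experiment={experiment}" if experiment is not None else "")
        )
    return dataset.counts[mask]
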