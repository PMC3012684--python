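"""Reading, validating and joining spike-in tables.

Two tab-separated inputs describe a spike-in experiment:

* an intensity table with one row per technical-replicate measurement
  (``probe_id``, ``condition_id``, ``replicate_id``, ``intensity``), and
* a design table giving the nominal spiked-in concentration for each
  (``probe_id``, ``condition_id``) cell (``nominal_concentration``,
  in pM or molecule counts — the unit is metadata, not interpreted).

``average_replicates`` reduces the replicate measurements to their
arithmetic mean on the linear intensity scale and inner-joins them with
the design, producing the :class:`SpikeInDataset` every downstream
operation consumes.  Files are strict UTF-8 TSV with a header row and a
"." decimal separator; platform-native raw formats are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, ParseError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "INTENSITY_COLUMNS",
    "DESIGN_COLUMNS",
    "SpikeInDataset",
    "read_tables",
    "read_intensity_table",
    "read_design_table",
    "average_replicates",
]

INTENSITY_COLUMNS = ("probe_id", "condition_id", "replicate_id", "intensity")
DESIGN_COLUMNS = ("probe_id", "condition_id", "nominal_concentration")

_DATASET_COLUMNS = (
    "probe_id",
    "condition_id",
    "mean_intensity",
    "nominal_concentration",
    "n_replicates",
)


def _read_tsv(path, required: tuple, numeric: tuple) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].astype(str).str.strip().ne("")
        bad |= df[col].astype(str).str.strip().eq("")
        if bad.any():
            # header is line 1, so data row i lives on file line i + 2
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1} (file line {row + 2})"
            )
        df[col] = parsed
    return df


def read_intensity_table(path) -> pd.DataFrame:
    """Read and validate a raw intensity TSV.

    Returns a DataFrame with the four required columns typed, extra
    columns preserved untouched.  Duplicate (probe, condition, replicate)
    triples or non-finite intensities are schema violations.
    """
    df = _read_tsv(path, INTENSITY_COLUMNS, ("intensity",))
    key = ["probe_id", "condition_id", "replicate_id"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise SchemaError(
            f"{path}: duplicate (probe_id, condition_id, replicate_id) triple "
            f"{tuple(dup[k] for k in key)}"
        )
    if not np.all(np.isfinite(df["intensity"].to_numpy())):
        raise ParseError(f"{path}: non-finite intensity value")
    return df


def read_design_table(path) -> pd.DataFrame:
    """Read and validate a design TSV mapping cells to nominal concentrations."""
    df = _read_tsv(path, DESIGN_COLUMNS, ("nominal_concentration",))
    key = ["probe_id", "condition_id"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise SchemaError(
            f"{path}: duplicate (probe_id, condition_id) pair "
            f"{tuple(dup[k] for k in key)}"
        )
    conc = df["nominal_concentration"].to_numpy()
    if not np.all(np.isfinite(conc)) or np.any(conc < 0):
        raise ParseError(f"{path}: nominal_concentration must be finite and >= 0")
    return df


def read_tables(intensity_path, design_path):
    """Read the (intensity, design) TSV pair. See the module docstring."""
    return read_intensity_table(intensity_path), read_design_table(design_path)


@dataclass
class SpikeInDataset:
    """Replicate-averaged intensities joined with nominal concentrations.

    One row per (probe, condition) cell:
    ``probe_id, condition_id, mean_intensity, nominal_concentration,
    n_replicates``.  ``mean_intensity`` is always the arithmetic mean of
    that cell's replicate intensities on the linear scale.
    """

    table: pd.DataFrame
    concentration_units: str = "pM"

    def __post_init__(self) -> None:
        missing = [c for c in _DATASET_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"SpikeInDataset missing column(s) {missing}")
        if len(self.table) == 0:
            raise EmptyDatasetError("SpikeInDataset has no rows")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> list:
        """Distinct probe identifiers, in first-appearance order."""
        return list(dict.fromkeys(self.table["probe_id"]))

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def concentrations(self) -> np.ndarray:
        """Sorted distinct nominal concentrations."""
        return np.sort(self.table["nominal_concentration"].unique())

    def subset(self, probe_ids) -> "SpikeInDataset":
        """Rows for the given probes only (order preserved)."""
        wanted = set(probe_ids)
        sub = self.table[self.table["probe_id"].isin(wanted)]
        if len(sub) == 0:
            raise EmptyDatasetError(f"no rows for probes {sorted(wanted)!r}")
        return SpikeInDataset(sub.copy(), self.concentration_units)

    def drop_probes(self, probe_ids) -> "SpikeInDataset":
        unwanted = set(probe_ids)
        return self.subset([p for p in self.probe_ids if p not in unwanted])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, concentration_units: str = "pM") -> "SpikeInDataset":
        df = _read_tsv(
            path, _DATASET_COLUMNS, ("mean_intensity", "nominal_concentration")
        )
        df["n_replicates"] = pd.to_numeric(df["n_replicates"]).astype(int)
        return cls(df, concentration_units)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, concentration_units: str = "pM"
    ) -> "SpikeInDataset":
        return cls(df.copy(), concentration_units)


def average_replicates(
    raw: pd.DataFrame,
    design: pd.DataFrame,
    concentration_units: str = "pM",
) -> SpikeInDataset:
    """Collapse technical replicates and join with the design.

    The signal of each (probe, condition) cell is the arithmetic mean of
    its replicate intensities; a test site is treated as just another
    replicate.  Cells present in the intensity table but absent from the
    design are dropped with a logged warning (and vice versa the design
    may describe cells never measured — those contribute no rows).
    """
    for col in INTENSITY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"intensity table missing column {col!r}")
    for col in DESIGN_COLUMNS:
        if col not in design.columns:
            raise SchemaError(f"design table missing column {col!r}")

    grouped = (
        raw.groupby(["probe_id", "condition_id"], sort=False)["intensity"]
        .agg(mean_intensity="mean", n_replicates="size")
        .reset_index()
    )
    merged = grouped.merge(
        design[list(DESIGN_COLUMNS)], on=["probe_id", "condition_id"], how="inner"
    )
    n_dropped = len(grouped) - len(merged)
    if n_dropped:
        logger.warning(
            "average_replicates: dropped %d (probe, condition) cell(s) absent "
            "from the design table",
            n_dropped,
        )
    if len(merged) == 0:
        raise EmptyDatasetError(
            "intensity and design tables share no (probe_id, condition_id) cells"
        )
    merged = merged[list(_DATASET_COLUMNS)]
    return SpikeInDataset(merged, concentration_units)
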