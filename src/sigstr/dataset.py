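"""Phospho-antibody-array dataset container and on-disk formats.

The canonical on-disk form is a long TSV with columns
``molecule_id, channel, time_min, replicate, intensity, condition``.
A wide CSV adapter (one column per time point) is provided read-only,
because array scanners typically export wide tables while the analysis
prefers the long form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("phospho", "total", "negative_control")

#: molecule_id conventionally used for the antibody-free control spot
NEGCTRL_ID = "negative_control"

COLUMNS = ["molecule_id", "channel", "time_min", "replicate", "intensity"]


class DatasetError(ValueError):
    """Raised for structurally invalid array datasets."""


@dataclass
class PhosphoArrayDataset:
    """Raw fluorescence intensities by molecule, channel, time and replicate.

    Parameters
    ----------
    records
        Long-format table with columns ``molecule_id, channel, time_min,
        replicate, intensity``. Intensities are fluorescence arbitrary units
        and must be strictly positive.
    condition
        Free-text label of the experimental condition (e.g. ``"stressed"``).
    """

    records: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"dataset is missing columns: {missing}")
        bad = ~df["channel"].isin(CHANNELS)
        if bad.any():
            row = int(df.index[bad][0])
            raise DatasetError(
                f"unknown channel {df.loc[row, 'channel']!r} at row {row}; "
                f"expected one of {CHANNELS}"
            )
        nonpos = df["intensity"] <= 0
        if nonpos.any():
            row = int(df.index[nonpos][0])
            raise DatasetError(
                f"nonpositive intensity {df.loc[row, 'intensity']} at row {row}"
            )
        # every (molecule, channel, time) must carry the full replicate set
        counts = df.groupby(["molecule_id", "channel", "time_min"])["replicate"].nunique()
        if counts.nunique() > 1:
            gap = counts.idxmin()
            raise DatasetError(f"incomplete replicate set at {gap}")
        nc = df[df["channel"] == "negative_control"]
        if not set(self.times) <= set(nc["time_min"].unique()):
            raise DatasetError("negative_control channel missing at some time points")

    # -- views -------------------------------------------------------------
    @property
    def molecules(self) -> list[str]:
        """Molecule ids excluding the antibody-free control spot."""
        ids = self.records.loc[
            self.records["channel"] != "negative_control", "molecule_id"
        ].unique()
        return sorted(ids)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.records["time_min"].unique())

    @property
    def replicates(self) -> np.ndarray:
        return np.sort(self.records["replicate"].unique())

    def channel(self, molecule_id: str, channel: str) -> pd.DataFrame:
        """Wide (time × replicate) intensity table for one molecule/channel."""
        sub = self.records[
            (self.records["molecule_id"] == molecule_id)
            & (self.records["channel"] == channel)
        ]
        if sub.empty:
            raise DatasetError(f"no {channel!r} records for molecule {molecule_id!r}")
        return sub.pivot_table(
            index="time_min", columns="replicate", values="intensity"
        ).sort_index()

    def negative_control(self) -> pd.DataFrame:
        """Negative-control intensities as a (time × replicate) table.

        Multiple control spots at the same time/replicate are averaged.
        """
        sub = self.records[self.records["channel"] == "negative_control"]
        return sub.pivot_table(
            index="time_min", columns="replicate", values="intensity", aggfunc="mean"
        ).sort_index()

    # -- serialization -----------------------------------------------------
    def write_tsv(self, path) -> None:
        out = self.records.copy()
        out["condition"] = self.condition
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PhosphoArrayDataset":
        df = pd.read_csv(path, sep="\t")
        condition = ""
        if "condition" in df.columns:
            vals = df["condition"].dropna().unique()
            condition = str(vals[0]) if len(vals) else ""
            df = df.drop(columns=["condition"])
        try:
            return cls(df, condition=condition)
        except DatasetError as err:
            raise DatasetError(f"{path}: {err}") from err

    @classmethod
    def from_wide_csv(cls, path, condition: str = "") -> "PhosphoArrayDataset":
        """Read a wide CSV: molecule_id, channel, replicate, then one column
        per time point (column names are times in minutes)."""
        df = pd.read_csv(path)
        key_cols = ["molecule_id", "channel", "replicate"]
        missing = [c for c in key_cols if c not in df.columns]
        if missing:
            raise DatasetError(f"{path}: wide CSV missing columns {missing}")
        long = df.melt(id_vars=key_cols, var_name="time_min", value_name="intensity")
        long["time_min"] = long["time_min"].astype(float)
        return cls(long[COLUMNS], condition=condition)


def read_dataset(path, dialect: str = "long", condition: str = "") -> PhosphoArrayDataset:
    """Load a dataset from disk.

    ``dialect`` is ``"long"`` (canonical TSV) or ``"wide"`` (scanner-style CSV
    with one column per time point).
    """
    if dialect == "long":
        return PhosphoArrayDataset.read_tsv(path)
    if dialect == "wide":
        return PhosphoArrayDataset.from_wide_csv(path, condition=condition)
    raise ValueError(f"unknown dialect {dialect!r}")
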