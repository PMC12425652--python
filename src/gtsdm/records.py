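"""Occurrence and survey record containers.

Occurrence CSVs use the column order ``species,x,y,date,source`` (header
required; date and source may be empty).  Survey CSVs use
``site,trap,x,y,method`` followed by one 0/1 outcome column per species.
Coordinates are planar metres in the frame of the covariate stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OccurrenceSet", "read_survey_csv", "write_survey_csv"]

OCCURRENCE_COLUMNS = ["species", "x", "y", "date", "source"]
SURVEY_KEY_COLUMNS = ["site", "trap", "x", "y", "method"]


@dataclass
class OccurrenceSet:
    """Presence-only records for one species."""

    species_id: str
    records: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col, default in (("date", pd.NaT), ("source", "")):
            if col not in df.columns:
                df[col] = default
        df = df[["x", "y", "date", "source"]].reset_index(drop=True)
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValueError("occurrence coordinates must be finite")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy()

    @classmethod
    def from_points(cls, species_id: str, xy, source: str = "", notes=None) -> "OccurrenceSet":
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "date": pd.NaT, "source": source})
        return cls(species_id, df, notes=list(notes or []))

    @classmethod
    def from_csv(cls, path: str | Path, species_id: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        missing = [c for c in ("species", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence CSV missing columns {missing}")
        if species_id is not None:
            df = df[df["species"] == species_id]
        else:
            species = df["species"].unique()
            if len(species) != 1:
                raise ValueError("species_id required for multi-species CSV")
            species_id = str(species[0])
        if "date" in df.columns:
            df = df.assign(date=pd.to_datetime(df["date"], errors="coerce"))
        return cls(str(species_id), df)

    def to_csv(self, path: str | Path) -> None:
        out = self.records.copy()
        out.insert(0, "species", self.species_id)
        out[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV missing columns {missing}")
    return df


def write_survey_csv(df: pd.DataFrame, path: str | Path) -> None:
    species_cols = [c for c in df.columns if c not in SURVEY_KEY_COLUMNS]
    df[SURVEY_KEY_COLUMNS + species_cols].to_csv(path, index=False)
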