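"""Per-sample metadata: habitat, coordinates and environmental measurements."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SampleMetadata", "read_metadata"]

MANDATORY = ("habitat", "longitude", "latitude")


class SampleMetadata:
    """Table indexed by sample id with habitat, longitude/latitude (decimal
    degrees) and any number of numeric environmental columns."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        for col in MANDATORY:
            if col not in frame.columns:
                raise ValueError(f"metadata missing mandatory column {col!r}")
        lat = pd.to_numeric(frame["latitude"], errors="raise")
        lon = pd.to_numeric(frame["longitude"], errors="raise")
        if lat.isna().any() or lon.isna().any():
            bad = frame.index[lat.isna() | lon.isna()].tolist()
            raise ValueError(f"missing coordinates for samples: {bad}")
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude outside [-180, 180]")
        frame["latitude"] = lat.astype(float)
        frame["longitude"] = lon.astype(float)
        frame["habitat"] = frame["habitat"].astype(str)
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def habitat(self) -> pd.Series:
        return self.frame["habitat"]

    @property
    def coordinates(self) -> pd.DataFrame:
        return self.frame[["longitude", "latitude"]]

    def env_variables(self) -> list[str]:
        """Numeric columns other than coordinates, in file order."""
        out = []
        for col in self.frame.columns:
            if col in MANDATORY:
                continue
            if pd.api.types.is_numeric_dtype(self.frame[col]):
                out.append(col)
        return out

    def env_table(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        variables = list(variables) if variables is not None else self.env_variables()
        missing = [v for v in variables if v not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown environmental variables: {missing}")
        env = self.frame[variables].apply(pd.to_numeric, errors="raise")
        return env.astype(float)

    def select(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return SampleMetadata(self.frame.loc[list(sample_ids)])

    def write(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        out.to_csv(path, sep=sep)


def read_metadata(path) -> SampleMetadata:
    """Read CSV or TSV metadata (separator inferred from the extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    meta = SampleMetadata(df)
    return meta
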