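"""Biodistribution observation tables.

A dataset is a tidy table of per-time-point summary measurements:
``time_h, compartment, conc_cells_per_kg, sd, n`` — the form in which
flow-cytometry biodistribution experiments are reported (mean +/- sd over
``n`` animals per sampling time). The ``blood`` label maps to the model's
venous pool (terminal venous sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .dosing import DoseEvent
from .physiology import ORGANS

__all__ = ["OBSERVABLE_COMPARTMENTS", "BiodistributionDataset"]

#: Compartments a biodistribution experiment can report.
OBSERVABLE_COMPARTMENTS = ("blood",) + ORGANS

_COLUMNS = ["time_h", "compartment", "conc_cells_per_kg", "sd", "n"]


@dataclass
class BiodistributionDataset:
    """Observed or synthetic (time, compartment, concentration) records."""

    records: pd.DataFrame
    species: str = "mouse"
    dose_events: Sequence[DoseEvent] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        df = df[_COLUMNS].reset_index(drop=True)
        unknown = set(df["compartment"]) - set(OBSERVABLE_COMPARTMENTS)
        if unknown:
            raise ValueError(
                f"unknown compartments {sorted(unknown)}; expected {OBSERVABLE_COMPARTMENTS}"
            )
        if (df["time_h"] < 0).any():
            raise ValueError("observation times must be >= 0 h")
        if (df["conc_cells_per_kg"] < 0).any():
            raise ValueError("concentrations must be >= 0 cells/kg")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> list[float]:
        return sorted(self.records["time_h"].unique())

    @property
    def compartments(self) -> list[str]:
        return sorted(self.records["compartment"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        species: str = "mouse",
        dose_events: Sequence[DoseEvent] = (),
    ) -> "BiodistributionDataset":
        return cls(records=pd.read_csv(path), species=species, dose_events=dose_events)
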