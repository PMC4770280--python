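"""Synthetic biodistribution data with the structure of the mouse experiment.

The generator emulates a terminal-sampling flow-cytometry study: 5e5 cells
injected intravenously, groups of 5 animals sacrificed at 5 min, 15 min,
1 h, 3 h, 10 h and 20 h, with blood, lung, liver, spleen, kidney and heart
measured as cells per kg of tissue. Measurement noise is multiplicative
lognormal with a configurable coefficient of variation (default 0.25),
reflecting the right-skewed, scale-proportional error of rare-event counts;
replicate means and standard deviations are recorded per (time, compartment)
cell, exactly as such studies report their data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import OBSERVABLE_COMPARTMENTS, BiodistributionDataset
from .dosing import DoseEvent
from .kinetics import CellKineticParams
from .model import simulate
from .physiology import SpeciesPhysiology

__all__ = [
    "DEFAULT_SCHEDULE",
    "DEFAULT_COMPARTMENTS",
    "NoiseModel",
    "generate_dataset",
    "generate_disease_variant",
]

#: Default sampling schedule in hours: 5 min, 15 min, 1, 3, 10, 20 h.
DEFAULT_SCHEDULE = (5 / 60, 15 / 60, 1.0, 3.0, 10.0, 20.0)

#: Default measured compartments (blood maps to the venous pool).
DEFAULT_COMPARTMENTS = ("blood", "lung", "liver", "spleen", "kidney", "heart")


@dataclass(frozen=True)
class NoiseModel:
    """Lognormal multiplicative measurement noise.

    ``coefficient_of_variation`` is the sd/mean of a single replicate;
    replicates are drawn so their expectation equals the noiseless value.
    ``coefficient_of_variation = 0`` yields exact noiseless replicates.
    """

    coefficient_of_variation: float = 0.25
    n_animals: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coefficient_of_variation < 0:
            raise ValueError(f"CV must be >= 0, got {self.coefficient_of_variation!r}")
        if self.n_animals < 1:
            raise ValueError(f"n_animals must be >= 1, got {self.n_animals!r}")


def generate_dataset(
    physiology: SpeciesPhysiology,
    params: CellKineticParams,
    dose_events: Sequence[DoseEvent],
    schedule: Sequence[float] | None = None,
    noise: NoiseModel = NoiseModel(),
    compartments: Sequence[str] = DEFAULT_COMPARTMENTS,
) -> BiodistributionDataset:
    """Simulate true concentrations and draw noisy per-animal replicates.

    For each (time, compartment) cell the noiseless cells/kg value is
    simulated, ``n_animals`` lognormal replicates with the configured CV
    are drawn (mean-preserving), and their sample mean and sd recorded.
    Fully reproducible given ``noise.seed``.
    """
    schedule = tuple(schedule) if schedule is not None else DEFAULT_SCHEDULE
    events = tuple(dose_events)
    if not events:
        raise ValueError("at least one dose event is required")
    t0 = min(e.time for e in events)
    if min(schedule) < t0:
        raise ValueError("sampling schedule starts before the first dose")
    unknown = set(compartments) - set(OBSERVABLE_COMPARTMENTS)
    if unknown:
        raise ValueError(f"invalid compartments {sorted(unknown)}")

    grid = np.unique(np.concatenate([[t0], np.asarray(schedule, dtype=float)]))
    result = simulate(physiology, params, events, grid, solver="expm")
    t_index = {t: i for i, t in enumerate(grid)}

    rng = np.random.default_rng(noise.seed)
    cv = noise.coefficient_of_variation
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)

    rows = []
    for t in schedule:
        for comp in compartments:
            truth = result.concentration_per_kg_series(comp)[t_index[t]]
            if cv == 0 or truth == 0:
                mean, sd = float(truth), 0.0
            else:
                # mean-preserving lognormal: E[truth * exp(N(-s^2/2, s^2))] = truth
                replicates = truth * rng.lognormal(-sigma2 / 2, sigma, size=noise.n_animals)
                mean = float(np.mean(replicates))
                sd = float(np.std(replicates, ddof=1)) if noise.n_animals > 1 else 0.0
            rows.append(
                {
                    "time_h": t,
                    "compartment": comp,
                    "conc_cells_per_kg": mean,
                    "sd": sd,
                    "n": noise.n_animals,
                }
            )
    return BiodistributionDataset(
        records=pd.DataFrame(rows), species=physiology.species, dose_events=events
    )


def generate_disease_variant(
    base_params: CellKineticParams,
    organ: str,
    arrest_multiplier: float = 1.0,
    depletion_multiplier: float = 1.0,
    partition_multiplier: float = 1.0,
) -> CellKineticParams:
    """Kinetic parameters for a diseased organ: scaled arrest/depletion/partition.

    Disease alters how the target organ captures and retains circulating
    cells (e.g. an infarcted heart arrests more and depletes less; a
    cirrhotic liver partitions and arrests more); all other organs keep the
    baseline values.
    """
    return base_params.scale_organ(
        organ,
        arrest_multiplier=arrest_multiplier,
        depletion_multiplier=depletion_multiplier,
        partition_multiplier=partition_multiplier,
    )
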