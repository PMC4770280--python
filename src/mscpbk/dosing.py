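"""Administration routes and their translation into state perturbations.

Both supported routes are instantaneous boluses (a state jump): an
intravenous push is fast relative to the first sampling time, and no
infusion kinetics are modelled.

- ``intravenous``: cells enter the venous pool (tail-vein injection);
  the first capillary bed encountered is the lung.
- ``intra_hepatic_arterial``: cells are delivered directly into the
  hepatic vascular bed, bypassing the lung first pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physiology import SpeciesPhysiology

__all__ = ["ROUTES", "DoseEvent", "apply_dose"]

ROUTES = ("intravenous", "intra_hepatic_arterial")


@dataclass(frozen=True)
class DoseEvent:
    """A bolus administration of ``amount`` cells at ``time`` hours."""

    route: str
    amount: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unsupported route {self.route!r}; expected one of {ROUTES}")
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0 cells, got {self.amount!r}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0 h, got {self.time!r}")


def apply_dose(state: np.ndarray, event: DoseEvent, physiology: SpeciesPhysiology) -> np.ndarray:
    """Return a new state vector with the bolus applied.

    Intravenous doses raise the venous concentration by
    ``amount / venous_blood_volume``; intra-hepatic arterial doses raise the
    liver vascular concentration by ``amount / V_V_liver``. Total cell
    accounting increases by exactly ``amount``.
    """
    from .model import IDX_VASCULAR, IDX_VENOUS, N_STATES  # local import: avoid cycle

    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {state.shape}")
    new = state.copy()
    if event.route == "intravenous":
        new[IDX_VENOUS] += event.amount / physiology.venous_blood_volume
    elif event.route == "intra_hepatic_arterial":
        new[IDX_VASCULAR["liver"]] += event.amount / physiology.organs["liver"].vascular_volume
    else:  # pragma: no cover - guarded by DoseEvent validation
        raise ValueError(f"unsupported route {event.route!r}")
    return new
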