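"""Cell-specific kinetic parameters: partition, arrest, release, depletion.

Each organ carries four constants: a unitless partition coefficient ``P``
linking the concentration in the organ vascular space to the concentration
in the venous blood leaving it (outflow concentration = C_V / P), and
first-order rate constants (h^-1) for arrest of circulating cells into an
extravascular retained pool, release back into circulation, and
irreversible depletion from the retained pool. The circulating arterial
and venous blood pools carry a single depletion rate constant of their own.

A bundled set (``"reference"``) holds the MSC parameters estimated from
mouse biodistribution data; it ships as an editable YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .physiology import ORGANS

__all__ = [
    "OrganKinetics",
    "CellKineticParams",
    "PARAM_NAMES",
    "load_kinetic_params",
    "save_kinetic_params",
]

_ORGAN_FIELDS = ("partition_coefficient", "k_arrest", "k_release", "k_depletion")

#: Flat parameter names, ``"<organ>.<field>"`` plus ``"blood.k_depletion"``,
#: in canonical order (used by calibration masks and sensitivity sweeps).
PARAM_NAMES = tuple(f"{organ}.{field}" for organ in ORGANS for field in _ORGAN_FIELDS) + (
    "blood.k_depletion",
)


class KineticsError(ValueError):
    """Raised when a kinetic parameter set fails validation."""


@dataclass(frozen=True)
class OrganKinetics:
    """Partition coefficient and arrest/release/depletion rates of one organ."""

    partition_coefficient: float
    k_arrest: float
    k_release: float
    k_depletion: float

    def __post_init__(self) -> None:
        if not self.partition_coefficient > 0:
            raise KineticsError(f"partition_coefficient must be > 0, got {self.partition_coefficient!r}")
        for field in ("k_arrest", "k_release", "k_depletion"):
            if getattr(self, field) < 0:
                raise KineticsError(f"{field} must be >= 0, got {getattr(self, field)!r}")


@dataclass(frozen=True)
class CellKineticParams:
    """Full cell-specific parameter set over the six organ compartments."""

    organs: Mapping[str, OrganKinetics]
    blood_k_depletion: float
    name: str = "unnamed"

    def __post_init__(self) -> None:
        missing = set(ORGANS) - set(self.organs)
        extra = set(self.organs) - set(ORGANS)
        if missing or extra:
            raise KineticsError(f"organ set mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
        if self.blood_k_depletion < 0:
            raise KineticsError(f"blood_k_depletion must be >= 0, got {self.blood_k_depletion!r}")

    def get(self, param: str) -> float:
        """Return a parameter by flat name, e.g. ``"lung.k_arrest"``."""
        if param == "blood.k_depletion":
            return self.blood_k_depletion
        organ, _, field = param.partition(".")
        if organ not in ORGANS or field not in _ORGAN_FIELDS:
            raise KeyError(f"unknown parameter {param!r}")
        return getattr(self.organs[organ], field)

    def with_values(self, updates: Mapping[str, float]) -> "CellKineticParams":
        """Return a copy with the flat-named parameters replaced."""
        organs = dict(self.organs)
        blood = self.blood_k_depletion
        per_organ: dict[str, dict[str, float]] = {}
        for param, value in updates.items():
            if param == "blood.k_depletion":
                blood = float(value)
                continue
            organ, _, field = param.partition(".")
            if organ not in ORGANS or field not in _ORGAN_FIELDS:
                raise KeyError(f"unknown parameter {param!r}")
            per_organ.setdefault(organ, {})[field] = float(value)
        for organ, fields in per_organ.items():
            organs[organ] = replace(organs[organ], **fields)
        return CellKineticParams(organs=organs, blood_k_depletion=blood, name=self.name)

    def to_dict(self) -> dict[str, float]:
        return {p: self.get(p) for p in PARAM_NAMES}

    def scale_organ(
        self,
        organ: str,
        *,
        partition_multiplier: float = 1.0,
        arrest_multiplier: float = 1.0,
        release_multiplier: float = 1.0,
        depletion_multiplier: float = 1.0,
    ) -> "CellKineticParams":
        """Return a copy with one organ's parameters multiplied."""
        if organ not in ORGANS:
            raise KeyError(f"unknown organ {organ!r}; expected one of {ORGANS}")
        for label, m in (
            ("partition_multiplier", partition_multiplier),
            ("arrest_multiplier", arrest_multiplier),
            ("release_multiplier", release_multiplier),
            ("depletion_multiplier", depletion_multiplier),
        ):
            if not m > 0:
                raise KineticsError(f"{label} must be > 0, got {m!r}")
        ok = self.organs[organ]
        return self.with_values(
            {
                f"{organ}.partition_coefficient": ok.partition_coefficient * partition_multiplier,
                f"{organ}.k_arrest": ok.k_arrest * arrest_multiplier,
                f"{organ}.k_release": ok.k_release * release_multiplier,
                f"{organ}.k_depletion": ok.k_depletion * depletion_multiplier,
            }
        )


def load_kinetic_params(source: str | Path = "reference") -> CellKineticParams:
    """Load a kinetic parameter set from the bundled fixture or a YAML file.

    ``"reference"`` names the bundled MSC set estimated from mouse
    biodistribution data; any other string is interpreted as a file path.
    """
    if source == "reference":
        text = resources.files("mscpbk.data").joinpath("msc_reference_params.yaml").read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise KineticsError(f"unknown parameter source {str(source)!r}: not 'reference' and no such file")
        text = path.read_text()
    doc = yaml.safe_load(text)
    organs = {
        name: OrganKinetics(**{k: float(v) for k, v in entry.items()})
        for name, entry in doc["organs"].items()
    }
    return CellKineticParams(
        organs=organs,
        blood_k_depletion=float(doc["blood_k_depletion"]),
        name=str(doc.get("name", "unnamed")),
    )


def save_kinetic_params(params: CellKineticParams, path: str | Path) -> None:
    """Write a kinetic parameter set to YAML (round-trips with the loader)."""
    doc = {
        "name": params.name,
        "blood_k_depletion": params.blood_k_depletion,
        "organs": {
            name: {
                "partition_coefficient": ok.partition_coefficient,
                "k_arrest": ok.k_arrest,
                "k_release": ok.k_release,
                "k_depletion": ok.k_depletion,
            }
            for name, ok in params.organs.items()
        },
    }
    Path(path).write_text(
        "# units: partition_coefficient unitless; rate constants h^-1\n"
        + yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
    )
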