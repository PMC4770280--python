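"""Species physiology: organ volumes, vascular volumes and regional blood flows.

The whole body is divided into eight compartments: arterial blood, venous
blood, and six perfused organ compartments (lung, liver, spleen, kidney,
heart, rest of body). The lung sits in series between the venous and
arterial pools and receives the total cardiac output; the remaining organs
are perfused in parallel from the arterial pool. The liver additionally
receives the splenic venous outflow (splanchnic/portal route), so its
``blood_flow`` entry is the *hepatic-artery* inflow only.

Bundled parameter sets (mouse, rat, human) are shipped as editable YAML
files under :mod:`mscpbk.data`, transcribed from the standard physiological
reference compilations; every value carries a provenance comment in the
data file itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ORGANS",
    "BUNDLED_SPECIES",
    "OrganPhysiology",
    "SpeciesPhysiology",
    "load_species_physiology",
    "save_species_physiology",
    "scale_physiology",
]

#: Canonical organ compartment names, in model order.
ORGANS = ("lung", "liver", "spleen", "kidney", "heart", "rest_of_body")

#: Species with a bundled physiology file.
BUNDLED_SPECIES = ("mouse", "rat", "human")

#: Organs perfused directly from the arterial pool (lung is in series and
#: receives total cardiac output; spleen outflow drains into the liver).
ARTERIAL_ORGANS = ("liver", "spleen", "kidney", "heart", "rest_of_body")

#: Relative tolerance on the arterial flow balance (sum of arterial-fed
#: organ flows vs cardiac output).
FLOW_BALANCE_RTOL = 0.01


class PhysiologyError(ValueError):
    """Raised when a physiology table fails validation."""


@dataclass(frozen=True)
class OrganPhysiology:
    """One perfused organ compartment.

    Parameters
    ----------
    name
        Organ identifier, one of :data:`ORGANS`.
    total_volume
        Total organ volume in L (mass in kg at density 1 kg/L).
    vascular_volume
        Volume of blood resident in the organ's vessels, in L. The free
        (circulating) cell pool of the organ lives in this volume.
    blood_flow
        Perfusing blood flow in L/h. For the liver this is the
        hepatic-artery inflow; the splenic outflow is added by the model
        topology. For the lung it equals the cardiac output.
    """

    name: str
    total_volume: float
    vascular_volume: float
    blood_flow: float

    def __post_init__(self) -> None:
        if self.name not in ORGANS:
            raise PhysiologyError(f"unknown organ {self.name!r}; expected one of {ORGANS}")
        for field in ("total_volume", "vascular_volume", "blood_flow"):
            value = getattr(self, field)
            if not (isinstance(value, (int, float)) and value > 0):
                raise PhysiologyError(f"{self.name}.{field} must be strictly positive, got {value!r}")
        if self.vascular_volume >= self.total_volume:
            raise PhysiologyError(
                f"{self.name}: vascular_volume ({self.vascular_volume}) must be "
                f"smaller than total_volume ({self.total_volume})"
            )


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Whole-body physiological parameter set for one species.

    Invariants enforced on construction: all six organ compartments present;
    the arterial flow balance (hepatic artery + spleen + kidney + heart +
    rest of body = cardiac output within 1%, lung = cardiac output within
    1%); total compartment volume not exceeding body weight at 1 kg/L.
    """

    species: str
    body_weight: float
    arterial_blood_volume: float
    venous_blood_volume: float
    cardiac_output: float
    organs: Mapping[str, OrganPhysiology]

    def __post_init__(self) -> None:
        for field in ("body_weight", "arterial_blood_volume", "venous_blood_volume", "cardiac_output"):
            value = getattr(self, field)
            if not (isinstance(value, (int, float)) and value > 0):
                raise PhysiologyError(f"{field} must be strictly positive, got {value!r}")
        missing = set(ORGANS) - set(self.organs)
        extra = set(self.organs) - set(ORGANS)
        if missing or extra:
            raise PhysiologyError(f"organ set mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
        for name, organ in self.organs.items():
            if organ.name != name:
                raise PhysiologyError(f"organ key {name!r} does not match entry name {organ.name!r}")
        arterial_flow = sum(self.organs[o].blood_flow for o in ARTERIAL_ORGANS)
        if abs(arterial_flow - self.cardiac_output) > FLOW_BALANCE_RTOL * self.cardiac_output:
            raise PhysiologyError(
                f"arterial flow balance violated: organ flows sum to {arterial_flow:g} L/h "
                f"but cardiac output is {self.cardiac_output:g} L/h"
            )
        lung_flow = self.organs["lung"].blood_flow
        if abs(lung_flow - self.cardiac_output) > FLOW_BALANCE_RTOL * self.cardiac_output:
            raise PhysiologyError(
                f"lung flow ({lung_flow:g} L/h) must equal cardiac output ({self.cardiac_output:g} L/h)"
            )
        total_volume = (
            self.arterial_blood_volume
            + self.venous_blood_volume
            + sum(o.total_volume for o in self.organs.values())
        )
        if total_volume > self.body_weight * 1.000001:  # 1 kg/L density
            raise PhysiologyError(
                f"compartment volumes sum to {total_volume:g} L, exceeding body weight "
                f"{self.body_weight:g} kg at 1 kg/L"
            )

    @property
    def liver_total_flow(self) -> float:
        """Total hepatic perfusion: hepatic artery plus splenic inflow, L/h."""
        return self.organs["liver"].blood_flow + self.organs["spleen"].blood_flow

    @property
    def blood_accessible_volume(self) -> float:
        """Arterial + venous pools + all organ vascular volumes, L."""
        return (
            self.arterial_blood_volume
            + self.venous_blood_volume
            + sum(o.vascular_volume for o in self.organs.values())
        )

    def organ(self, name: str) -> OrganPhysiology:
        try:
            return self.organs[name]
        except KeyError:
            raise KeyError(f"unknown organ {name!r}; expected one of {ORGANS}") from None


def _from_mapping(doc: Mapping) -> SpeciesPhysiology:
    required = {"species", "body_weight", "arterial_blood_volume", "venous_blood_volume", "cardiac_output", "organs"}
    missing = required - set(doc)
    if missing:
        raise PhysiologyError(f"physiology document missing fields: {sorted(missing)}")
    organs = {}
    for name, entry in doc["organs"].items():
        entry_fields = {"total_volume", "vascular_volume", "blood_flow"}
        if not entry_fields <= set(entry):
            raise PhysiologyError(f"organ {name!r} missing fields: {sorted(entry_fields - set(entry))}")
        organs[name] = OrganPhysiology(name=name, **{k: float(entry[k]) for k in entry_fields})
    return SpeciesPhysiology(
        species=str(doc["species"]),
        body_weight=float(doc["body_weight"]),
        arterial_blood_volume=float(doc["arterial_blood_volume"]),
        venous_blood_volume=float(doc["venous_blood_volume"]),
        cardiac_output=float(doc["cardiac_output"]),
        organs=organs,
    )


def load_species_physiology(source: str | Path) -> SpeciesPhysiology:
    """Load a validated physiology set from a bundled species or a YAML file.

    Parameters
    ----------
    source
        One of the bundled labels (``"mouse"``, ``"rat"``, ``"human"``) or a
        path to a YAML document with the same keys as the bundled files
        (units: kg, L, L/h).
    """
    if isinstance(source, str) and source in BUNDLED_SPECIES:
        text = resources.files("mscpbk.data").joinpath(f"physiology_{source}.yaml").read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise PhysiologyError(
                f"unknown species {str(source)!r}: not one of {BUNDLED_SPECIES} and no such file"
            )
        text = path.read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise PhysiologyError(f"physiology source {source!r} is not a mapping document")
    return _from_mapping(doc)


def save_species_physiology(physiology: SpeciesPhysiology, path: str | Path) -> None:
    """Write a physiology set to YAML so that a re-load is bit-exact."""
    doc = {
        "species": physiology.species,
        "body_weight": physiology.body_weight,
        "arterial_blood_volume": physiology.arterial_blood_volume,
        "venous_blood_volume": physiology.venous_blood_volume,
        "cardiac_output": physiology.cardiac_output,
        "organs": {
            name: {
                "total_volume": organ.total_volume,
                "vascular_volume": organ.vascular_volume,
                "blood_flow": organ.blood_flow,
            }
            for name, organ in physiology.organs.items()
        },
    }
    Path(path).write_text(
        "# units: body_weight kg; volumes L; flows L/h\n"
        + yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
    )


def scale_physiology(
    base: SpeciesPhysiology, body_weight: float, flow_exponent: float = 0.75
) -> SpeciesPhysiology:
    """Allometrically rescale a physiology set to a new body weight.

    Volumes scale proportionally with body weight; flows scale with
    ``(bw_new / bw_old) ** flow_exponent`` (default exponent 0.75, the
    standard allometric exponent for perfusion and metabolic rates).
    """
    if not body_weight > 0:
        raise PhysiologyError(f"body_weight must be strictly positive, got {body_weight!r}")
    ratio = body_weight / base.body_weight
    flow_ratio = ratio**flow_exponent
    organs = {
        name: replace(
            organ,
            total_volume=organ.total_volume * ratio,
            vascular_volume=organ.vascular_volume * ratio,
            blood_flow=organ.blood_flow * flow_ratio,
        )
        for name, organ in base.organs.items()
    }
    return SpeciesPhysiology(
        species=base.species,
        body_weight=body_weight,
        arterial_blood_volume=base.arterial_blood_volume * ratio,
        venous_blood_volume=base.venous_blood_volume * ratio,
        cardiac_output=base.cardiac_output * flow_ratio,
        organs=organs,
    )
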