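"""Species physiology: organ volumes, blood flows, tissue composition.

Shipped as versioned YAML data files for rat and a 60 kg reference human.
Flows are mL/min/kg, volumes L/kg; the loader checks the flow topology
(lung flow equals cardiac output equals the sum of systemic arterial
draws) and exposes total hepatic blood flow as arterial plus portal.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from ..errors import ConstructionError, LookupError_

PORTAL_ORGANS = ("gut", "spleen", "stomach")


@dataclass(frozen=True)
class TissueComposition:
    f_ew: float = 0.0  # extracellular water, fraction of tissue volume (0 for cells)
    f_iw: float = 0.0  # intracellular water
    f_nl: float = 0.0  # neutral lipid
    f_np: float = 0.0  # neutral phospholipid
    ap_mg_g: float = 0.0  # acidic phospholipid, mg per g tissue


@dataclass(frozen=True)
class Organ:
    name: str
    volume_l_kg: float
    flow_ml_min_kg: float  # arterial draw (for liver: hepatic artery only)
    composition: TissueComposition


@dataclass(frozen=True)
class SpeciesPhysiology:
    species: str
    body_weight_kg: float
    hematocrit: float
    cardiac_output_ml_min_kg: float
    gfr_ml_min_kg: float
    ph_plasma: float
    ph_intracellular: float
    ph_erythrocyte: float
    arterial_volume_l_kg: float
    venous_volume_l_kg: float
    erythrocyte_composition: TissueComposition
    organs: dict[str, Organ]

    @property
    def hepatic_flow_ml_min_kg(self) -> float:
        """Total liver inflow: hepatic artery plus portal organ outflows."""
        return self.organs["liver"].flow_ml_min_kg + sum(
            self.organs[o].flow_ml_min_kg for o in PORTAL_ORGANS
        )

    def organ(self, name: str) -> Organ:
        if name not in self.organs:
            raise LookupError_(
                f"no composition/physiology for organ {name!r}; known: "
                + ", ".join(sorted(self.organs))
            )
        return self.organs[name]


def check_topology(phys: SpeciesPhysiology) -> None:
    """Validate the flow topology and volume sanity of a physiology table."""
    co = phys.cardiac_output_ml_min_kg
    if abs(phys.organs["lung"].flow_ml_min_kg - co) > 1e-6 * co:
        raise ConstructionError(
            f"lung flow {phys.organs['lung'].flow_ml_min_kg} != cardiac output {co}"
        )
    systemic = sum(
        o.flow_ml_min_kg for n, o in phys.organs.items() if n != "lung"
    )
    if abs(systemic - co) > 1e-3 * co:
        raise ConstructionError(
            f"sum of systemic arterial draws ({systemic:.3f}) != cardiac output ({co})"
        )
    total_volume = (
        sum(o.volume_l_kg for o in phys.organs.values())
        + phys.arterial_volume_l_kg
        + phys.venous_volume_l_kg
    )
    if not 0.5 <= total_volume <= 1.1:
        raise ConstructionError(
            f"total specific volume {total_volume:.3f} L/kg fails sanity bounds"
        )


def load_physiology(species: str) -> SpeciesPhysiology:
    """Load and validate the physiology table for 'rat' or 'human'."""
    try:
        text = (
            resources.files("preclinpk.pbpk") / "data" / f"{species}.yaml"
        ).read_text()
    except FileNotFoundError:
        raise LookupError_(
            f"no physiology data for species {species!r}; available: rat, human"
        ) from None
    raw = yaml.safe_load(text)
    organs = {
        name: Organ(
            name=name,
            volume_l_kg=float(spec["volume_l_kg"]),
            flow_ml_min_kg=float(spec["flow_ml_min_kg"]),
            composition=TissueComposition(**spec["composition"]),
        )
        for name, spec in raw["organs"].items()
    }
    phys = SpeciesPhysiology(
        species=raw["species"],
        body_weight_kg=float(raw["body_weight_kg"]),
        hematocrit=float(raw["hematocrit"]),
        cardiac_output_ml_min_kg=float(raw["cardiac_output_ml_min_kg"]),
        gfr_ml_min_kg=float(raw["gfr_ml_min_kg"]),
        ph_plasma=float(raw["ph"]["plasma"]),
        ph_intracellular=float(raw["ph"]["intracellular"]),
        ph_erythrocyte=float(raw["ph"]["erythrocyte"]),
        arterial_volume_l_kg=float(raw["blood"]["arterial_volume_l_kg"]),
        venous_volume_l_kg=float(raw["blood"]["venous_volume_l_kg"]),
        erythrocyte_composition=TissueComposition(**raw["erythrocyte_composition"]),
        organs=organs,
    )
    check_topology(phys)
    return phys
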