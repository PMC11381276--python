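"""Domain types and unit conventions.

Units are fixed package-wide: time in hours for in vivo data and minutes for
in vitro incubations, concentration in ng/mL, dose in mg per kg body weight.
Converters between these and SI-style units are explicit operations; nothing
converts implicitly.
"""
from __future__ import annotations

import enum
import math
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .errors import LookupError_


class Route(str, enum.Enum):
    iv_bolus = "iv_bolus"
    oral = "oral"


class Species(str, enum.Enum):
    mouse = "mouse"
    rat = "rat"
    dog = "dog"
    monkey = "monkey"
    human = "human"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unspecified = "unspecified"


class DoseEvent(BaseModel):
    """A single administration: route, weight-normalised dose, time of dosing."""

    route: Route
    dose_per_bw: float = Field(gt=0, description="dose in mg/kg body weight")
    time: float = Field(default=0.0, ge=0, description="dosing time, h")
    body_weight: Optional[float] = Field(
        default=None, gt=0, description="kg; needed for absolute-amount conversions"
    )


class Sample(BaseModel):
    """One concentration observation."""

    time: float = Field(ge=0, description="h post dose")
    conc: float = Field(ge=0, description="ng/mL")
    blq: bool = False


class ConcTimeProfile(BaseModel):
    """A subject x matrix concentration-time series with dosing metadata."""

    subject_id: str
    species: Species
    sex: Sex = Sex.unspecified
    matrix: str = "plasma"
    dose: DoseEvent
    samples: list[Sample]
    lloq: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _times_strictly_increasing(self) -> "ConcTimeProfile":
        times = [s.time for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            from .errors import ValidationError

            raise ValidationError(
                f"profile {self.subject_id}/{self.matrix}: sample times must be "
                f"strictly increasing, got {times}"
            )
        return self

    @property
    def times(self) -> list[float]:
        return [s.time for s in self.samples]

    @property
    def concs(self) -> list[float]:
        return [s.conc for s in self.samples]


class SpeciesConstants(BaseModel):
    """Registry row of microsomal scaling constants and hepatic blood flow.

    sf (mg microsomal protein per kg body weight) is always derived as
    mppgl x liver_bw_ratio, never stored independently.
    """

    species: Species
    mppgl: float = Field(gt=0, description="mg microsomal protein per g liver")
    liver_bw_ratio: float = Field(gt=0, description="g liver per kg body weight")
    q_h: float = Field(gt=0, description="hepatic blood flow, mL/min/kg")

    @property
    def sf(self) -> float:
        """Scaling factor, mg microsomal protein per kg body weight."""
        return self.mppgl * self.liver_bw_ratio


# Microsomal protein per gram liver, liver weight per kg body weight, and
# hepatic blood flow for the five supported species (standard allometric
# compilation values; SF(human) = 48.8 x 25.7 = 1254.16 mg/kg).
_SPECIES_REGISTRY: dict[Species, SpeciesConstants] = {
    Species.mouse: SpeciesConstants(species=Species.mouse, mppgl=45.0, liver_bw_ratio=87.5, q_h=90.0),
    Species.rat: SpeciesConstants(species=Species.rat, mppgl=44.8, liver_bw_ratio=40.0, q_h=55.2),
    Species.dog: SpeciesConstants(species=Species.dog, mppgl=77.9, liver_bw_ratio=32.0, q_h=30.9),
    Species.monkey: SpeciesConstants(species=Species.monkey, mppgl=45.0, liver_bw_ratio=32.5, q_h=44.0),
    Species.human: SpeciesConstants(species=Species.human, mppgl=48.8, liver_bw_ratio=25.7, q_h=20.7),
}


def species_constants(species: Species | str) -> SpeciesConstants:
    """Return the scaling-constant registry row for one species."""
    try:
        key = Species(species)
    except ValueError:
        raise LookupError_(
            f"unknown species {species!r}; supported: "
            + ", ".join(s.value for s in Species)
        ) from None
    return _SPECIES_REGISTRY[key]


def all_species_constants() -> list[SpeciesConstants]:
    return list(_SPECIES_REGISTRY.values())


class CompoundCard(BaseModel):
    """Drug-specific physicochemical and in vitro parameters.

    fup is held per species because plasma protein binding is species
    dependent; fub_microsome is the unbound fraction in the microsomal
    incubation (taken as 1 when binding in the incubation is negligible).
    """

    name: str = "compound"
    mw: float = Field(gt=0, description="g/mol")
    logp: float
    pka: Optional[float] = Field(default=None, description="basic centre; None = neutral")
    solubility: Optional[float] = Field(default=None, gt=0, description="mg/L at pH 7.4")
    fup: dict[Species, float] = Field(default_factory=dict)
    papp: Optional[float] = Field(default=None, gt=0, description="cm/s")
    clint_invitro: dict[Species, float] = Field(
        default_factory=dict, description="mL/min/mg microsomal protein"
    )
    t_half_microsome: dict[Species, float] = Field(default_factory=dict, description="min")
    fub_microsome: float = Field(default=1.0, gt=0, le=1)

    @model_validator(mode="after")
    def _fup_in_unit_interval(self) -> "CompoundCard":
        for sp, v in self.fup.items():
            if not 0 < v <= 1:
                from .errors import ValidationError

                raise ValidationError(f"fup[{sp}] = {v} outside (0, 1]")
        return self

    def fup_for(self, species: Species | str) -> float:
        key = Species(species)
        if key not in self.fup:
            raise LookupError_(f"no fup recorded for species {key.value}")
        return self.fup[key]


def deg_azm_card() -> CompoundCard:
    """Property card for Deg-AZM (deglycosylated azithromycin).

    Measured values: MW 433.59 g/mol, logP 1.7, basic pKa 9.0, solubility
    3450 mg/L at pH 7.4, Caco-2 Papp 3e-7 cm/s, in vitro microsomal CLint
    0.016 mL/min/mg (rat). fup per species is 1 minus the mean equilibrium
    dialysis binding over the 1-20 ug/mL range.
    """
    return CompoundCard(
        name="Deg-AZM",
        mw=433.59,
        logp=1.7,
        pka=9.0,
        solubility=3450.0,
        fup={
            Species.mouse: 0.507,
            Species.rat: 0.61,
            Species.dog: 0.126,
            Species.human: 0.27,
        },
        papp=3e-7,
        clint_invitro={Species.rat: 0.016},
        t_half_microsome={Species.rat: 43.0, Species.human: 46.5},
        fub_microsome=1.0,
    )


# --- explicit unit converters ------------------------------------------------

NG_PER_ML_TO_MG_PER_L = 1e-3  # 1 ng/mL = 1 ug/L = 1e-3 mg/L


def auc_ngh_ml_to_mgh_l(auc: float) -> float:
    """Convert h*ng/mL to h*mg/L."""
    return auc * NG_PER_ML_TO_MG_PER_L


def clearance_l_h_kg(dose_mg_kg: float, auc_ngh_ml: float) -> float:
    """CL (L/h/kg) from a mg/kg dose and an AUC in h*ng/mL."""
    return dose_mg_kg / auc_ngh_ml_to_mgh_l(auc_ngh_ml)


def ml_min_kg_to_l_h_kg(x: float) -> float:
    return x * 60.0 / 1000.0


def l_h_kg_to_ml_min_kg(x: float) -> float:
    return x * 1000.0 / 60.0


def round_sig(x: float, sig: int = 3) -> float:
    """Round to `sig` significant figures (half-even, for table display)."""
    if x == 0 or not math.isfinite(x):
        return x
    from decimal import ROUND_HALF_EVEN, Decimal

    d = Decimal(repr(x))
    shift = sig - 1 - math.floor(math.log10(abs(x)))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_EVEN))
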