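"""Mechanistic tissue:plasma partition coefficients (Rodgers-Rowland style).

For a monoprotic base with a basic centre of pKa >= 7 the unbound
tissue:plasma water ratio is built from four terms: extracellular water,
pH-partitioned intracellular water, electrostatic association of the
ionised species with acidic phospholipids, and partitioning of the neutral
species into neutral lipid and neutral phospholipid:

    Kpu = f_EW
        + f_IW * (1 + 10^(pKa - pH_iw)) / (1 + 10^(pKa - pH_p))
        + Ka_AP * [AP] * 10^(pKa - pH_iw) / (1 + 10^(pKa - pH_p))
        + (P * f_NL + (0.3 P + 0.7) * f_NP) / (1 + 10^(pKa - pH_p))

with P = 10^logP (a vegetable-oil corrected logP for adipose neutral
lipid).  The acidic-phospholipid affinity Ka_AP is back-calculated from
blood-cell partitioning implied by the blood:plasma ratio and haematocrit.
Plasma is treated as aqueous, with plasma protein binding carried entirely
by fup, so Kp (total tissue : total plasma) = Kpu * fup.

For neutral compounds the ionisation and acidic-phospholipid terms vanish:
    Kpu = f_EW + f_IW + P * f_NL + (0.3 P + 0.7) * f_NP
"""
from __future__ import annotations

import warnings

from ..datamodel import CompoundCard
from ..errors import DomainError
from .physiology import SpeciesPhysiology, TissueComposition

BASE_PKA_THRESHOLD = 7.0


def _adipose_p(logp: float) -> float:
    """Vegetable-oil partition estimate used for adipose neutral lipid."""
    return 10.0 ** (1.115 * logp - 1.35)


def blood_cell_kpu(bp_ratio: float, hematocrit: float, fup: float) -> float:
    """Unbound blood-cell-to-plasma ratio implied by B:P and haematocrit."""
    if fup <= 0:
        raise DomainError(f"fup must be > 0, got {fup}")
    return (bp_ratio - (1.0 - hematocrit)) / (hematocrit * fup)


def ka_ap_from_blood(
    compound: CompoundCard,
    physiology: SpeciesPhysiology,
    fup: float,
    bp_ratio: float = 1.0,
) -> float:
    """Acidic-phospholipid affinity constant from blood-cell partitioning.

    Solves the base Kpu expression for the erythrocyte (pH 7.22, known
    composition) for Ka_AP.  A non-positive solution (no association needed
    to explain the observed blood distribution) is clamped to zero with a
    warning.
    """
    if compound.pka is None or compound.pka < BASE_PKA_THRESHOLD:
        return 0.0
    bc = physiology.erythrocyte_composition
    p = 10.0**compound.logp
    x_bc = 10.0 ** (compound.pka - physiology.ph_erythrocyte)
    x_p = 10.0 ** (compound.pka - physiology.ph_plasma)
    kpu_bc = blood_cell_kpu(bp_ratio, physiology.hematocrit, fup)
    iw_term = bc.f_iw * (1.0 + x_bc) / (1.0 + x_p)
    lipid_term = (p * bc.f_nl + (0.3 * p + 0.7) * bc.f_np) / (1.0 + x_p)
    ka = (kpu_bc - iw_term - lipid_term) * (1.0 + x_p) / (bc.ap_mg_g * x_bc)
    if ka < 0:
        warnings.warn(
            "blood-cell partitioning implies no acidic-phospholipid "
            "association; Ka_AP clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return ka


def _kpu(
    comp: TissueComposition,
    compound: CompoundCard,
    physiology: SpeciesPhysiology,
    ka_ap: float,
    adipose: bool,
) -> float:
    p_nl = _adipose_p(compound.logp) if adipose else 10.0**compound.logp
    p = 10.0**compound.logp
    if compound.pka is None or compound.pka < BASE_PKA_THRESHOLD:
        return (
            comp.f_ew
            + comp.f_iw
            + p_nl * comp.f_nl
            + (0.3 * p + 0.7) * comp.f_np
        )
    x_iw = 10.0 ** (compound.pka - physiology.ph_intracellular)
    x_p = 10.0 ** (compound.pka - physiology.ph_plasma)
    return (
        comp.f_ew
        + comp.f_iw * (1.0 + x_iw) / (1.0 + x_p)
        + ka_ap * comp.ap_mg_g * x_iw / (1.0 + x_p)
        + (p_nl * comp.f_nl + (0.3 * p + 0.7) * comp.f_np) / (1.0 + x_p)
    )


def rodgers_rowland_kp(
    compound: CompoundCard,
    physiology: SpeciesPhysiology,
    organ: str,
    fup: float,
    bp_ratio: float = 1.0,
) -> float:
    """Total tissue:plasma partition coefficient for one organ."""
    if fup <= 0:
        raise DomainError(f"fup must be > 0, got {fup}")
    comp = physiology.organ(organ).composition
    ka_ap = ka_ap_from_blood(compound, physiology, fup, bp_ratio)
    return _kpu(comp, compound, physiology, ka_ap, adipose=(organ == "adipose")) * fup


def partition_set(
    compound: CompoundCard,
    physiology: SpeciesPhysiology,
    fup: float,
    bp_ratio: float = 1.0,
) -> dict[str, float]:
    """Kp for every organ in the physiology; deterministic in its inputs."""
    ka_ap = ka_ap_from_blood(compound, physiology, fup, bp_ratio)
    return {
        name: _kpu(
            organ.composition, compound, physiology, ka_ap,
            adipose=(name == "adipose"),
        )
        * fup
        for name, organ in physiology.organs.items()
    }
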