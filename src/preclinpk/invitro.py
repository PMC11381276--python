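"""Plasma protein binding, microsomal stability with IVIVE, metabolite profiles.

The in vitro-to-in vivo extrapolation chain follows the classic well-stirred
liver model: a mono-exponential depletion rate ke (1/min) measured at a
microsomal protein concentration C_protein (mg/mL) scales to whole-body
intrinsic clearance with SF = MPPGL x liver weight per kg body weight,

    CLint = ke / C_protein x SF          (mL/min/kg)
    CLh   = Q * fub * CLint / (Q + fub * CLint)
    ER    = CLh / Q

with Q the hepatic blood flow and fub the unbound fraction in the
incubation.  T1/2 is reported with the conventional rounded constant,
T1/2 = 0.693/ke.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .datamodel import Species, SpeciesConstants, species_constants
from .errors import DomainError, InsufficientDataError

T_HALF_CONSTANT = 0.693  # conventional rounded ln(2) used in the reported chain


class DialysisMeasurement(BaseModel):
    """One equilibrium-dialysis replicate: plasma-side and buffer-side conc."""

    species: Species
    nominal_conc: float = Field(gt=0, description="ug/mL spiking level")
    c_total: float = Field(ge=0, description="plasma-side concentration")
    c_free: float = Field(ge=0, description="buffer-side concentration")
    replicate: int = 0


class MicrosomalAssay(BaseModel):
    """Substrate-depletion assay: % remaining vs incubation time (min)."""

    species: Species
    protein_conc: float = Field(default=1.0, gt=0, description="mg/mL")
    substrate_conc: float = Field(default=1.0, gt=0, description="uM")
    timepoints: list[float]
    remaining: list[list[float]]  # one inner list per replicate, % of t=0

    @property
    def mean_remaining(self) -> np.ndarray:
        return np.asarray(self.remaining, dtype=float).mean(axis=0)


@dataclass(frozen=True)
class MicrosomalStabilityResult:
    species: Species
    ke: float  # 1/min
    t_half: float  # min; inf when ke == 0
    clint: float  # mL/min/kg
    clh: float  # mL/min/kg
    er: float
    fub: float
    constants: SpeciesConstants


class MetaboliteRecord(BaseModel):
    metabolite_id: str
    pathway_label: str = ""
    mz: Optional[float] = None
    rt: Optional[float] = None
    peak_area: Optional[float] = Field(default=None, ge=0)  # None = not detected


def bound_percent(c_total: float, c_free: float) -> float:
    """Bound %% = (C_total - C_free) / C_total x 100.

    A buffer-side excess (c_free > c_total) returns a negative value with a
    warning rather than silently clipping to zero.
    """
    if c_total <= 0:
        raise DomainError(f"c_total must be > 0, got {c_total}")
    if c_free < 0:
        raise DomainError(f"c_free must be >= 0, got {c_free}")
    pct = 100.0 * (c_total - c_free) / c_total
    if pct < 0:
        warnings.warn(
            f"c_free ({c_free}) exceeds c_total ({c_total}); bound% is negative",
            stacklevel=2,
        )
    return pct


@dataclass(frozen=True)
class BindingSummary:
    species: Species
    level_means: dict[float, float]  # nominal conc -> mean bound %
    level_sds: dict[float, float]
    average_bound: float  # unweighted mean of level means, %
    fup: float  # 1 - average/100


def binding_summary(measurements: Sequence[DialysisMeasurement]) -> list[BindingSummary]:
    """Per-species level means, SDs and the across-level average binding.

    The across-level average is the unweighted mean of the level means, and
    fup = 1 - average/100.
    """
    if not measurements:
        raise DomainError("no dialysis measurements supplied")
    out = []
    by_species: dict[Species, list[DialysisMeasurement]] = {}
    for m in measurements:
        by_species.setdefault(m.species, []).append(m)
    for sp, ms in by_species.items():
        levels: dict[float, list[float]] = {}
        for m in ms:
            levels.setdefault(m.nominal_conc, []).append(
                bound_percent(m.c_total, m.c_free)
            )
        means = {lv: float(np.mean(v)) for lv, v in sorted(levels.items())}
        sds = {
            lv: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            for lv, v in sorted(levels.items())
        }
        avg = float(np.mean(list(means.values())))
        out.append(
            BindingSummary(
                species=sp,
                level_means=means,
                level_sds=sds,
                average_bound=avg,
                fup=1.0 - avg / 100.0,
            )
        )
    return out


def fit_ke(assay: MicrosomalAssay, include_t0: bool = True) -> tuple[float, float]:
    """ke (1/min) from OLS of ln(%% remaining) on time; returns (ke, r2).

    Replicates are averaged per timepoint before regression.  Non-positive
    remaining values are excluded with a warning.  A non-negative slope is
    reported as ke = 0 (no measurable depletion).
    """
    t = np.asarray(assay.timepoints, dtype=float)
    y = assay.mean_remaining
    if not include_t0:
        mask0 = t > 0
        t, y = t[mask0], y[mask0]
    ok = y > 0
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} non-positive remaining value(s) excluded from ke fit",
            stacklevel=2,
        )
    t, y = t[ok], y[ok]
    if len(t) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable timepoints for ke regression, got {len(t)}"
        )
    slope, _, r, _, _ = stats.linregress(t, np.log(y))
    ke = max(0.0, -float(slope))
    return ke, float(r**2)


def ivive_chain(
    ke: float,
    species: Species | str,
    fub: float = 1.0,
    protein_conc: float = 1.0,
) -> MicrosomalStabilityResult:
    """Scale a microsomal depletion rate to hepatic clearance and ER.

    ke = 0 (metabolically stable) yields CLint = CLh = ER = 0 with an
    infinite half-life.
    """
    if ke < 0:
        raise DomainError(f"ke must be >= 0, got {ke}")
    if not 0 < fub <= 1:
        raise DomainError(f"fub must be in (0, 1], got {fub}")
    const = species_constants(species)
    if ke == 0:
        return MicrosomalStabilityResult(
            species=const.species, ke=0.0, t_half=math.inf,
            clint=0.0, clh=0.0, er=0.0, fub=fub, constants=const,
        )
    t_half = T_HALF_CONSTANT / ke
    clint = ke / protein_conc * const.sf
    clh = const.q_h * fub * clint / (const.q_h + fub * clint)
    er = clh / const.q_h
    return MicrosomalStabilityResult(
        species=const.species, ke=ke, t_half=t_half,
        clint=clint, clh=clh, er=er, fub=fub, constants=const,
    )


def metabolite_profile(records: Sequence[MetaboliteRecord]) -> pd.DataFrame:
    """Semi-quantitative peak-area normalisation to proportions summing to 100%.

    Records without a peak area (not detected) are reported with an empty
    proportion; proportions are computed over detected records only.
    """
    detected = [r for r in records if r.peak_area is not None]
    if not detected:
        raise DomainError("no detected metabolite peak areas to normalise")
    total = sum(r.peak_area for r in detected)
    if total <= 0:
        raise DomainError("total peak area is zero")
    rows = []
    for r in records:
        rows.append(
            {
                "metabolite_id": r.metabolite_id,
                "pathway": r.pathway_label,
                "mz": r.mz,
                "rt_min": r.rt,
                "peak_area": r.peak_area,
                "proportion_pct": 100.0 * r.peak_area / total
                if r.peak_area is not None
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def qc_controls(
    positive_remaining_pct: float,
    negative_remaining_pct: float,
    positive_max: float = 1.0,
    negative_range: tuple[float, float] = (90.0, 110.0),
) -> dict[str, bool]:
    """Pass/fail QC for the assay controls.

    The positive control (a rapidly metabolised probe) must be nearly fully
    depleted; the negative control (inactivated microsomes) must show no
    depletion beyond assay noise.
    """
    lo, hi = negative_range
    return {
        "positive_ok": positive_remaining_pct <= positive_max,
        "negative_ok": lo <= negative_remaining_pct <= hi,
    }
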