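"""Excretion mass balance and tissue distribution ratios.

Cumulative excretion converts interval concentration x volume (or weight)
records to percent of the administered dose per matrix and in total.
Tissue exposure expresses each tissue's AUC relative to the plasma AUC
(observed partition ratio Kp_obs) over the sparse tissue-sampling design.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .datamodel import ConcTimeProfile, DoseEvent
from .errors import DomainError, ValidationError
from .nca import auc_trapezoid


class ExcretionMatrix(str, enum.Enum):
    urine = "urine"
    bile = "bile"
    feces = "feces"


class ExcretionInterval(BaseModel):
    """One collection interval for one matrix.

    conc refers to the assayed sample (homogenate for feces); amount applies
    the homogenate dilution factor.  Pooled cages carry n_animals and the
    summed dose is used downstream.
    """

    matrix: ExcretionMatrix
    t_start: float = Field(ge=0)
    t_end: float
    volume_or_weight: Optional[float] = Field(default=None, ge=0, description="mL or g")
    conc: float = Field(ge=0, description="ng/mL or ng/g homogenate")
    dilution_factor: float = Field(default=1.0, gt=0, description="homogenate mL per g")
    n_animals: int = Field(default=1, ge=1)

    @property
    def amount_ng(self) -> Optional[float]:
        if self.volume_or_weight is None:
            return None
        return self.conc * self.volume_or_weight * self.dilution_factor


@dataclass(frozen=True)
class ExcretionSummary:
    """Cumulative % of dose per matrix over time plus the total recovery."""

    cumulative: pd.DataFrame  # columns: matrix, t_end, cum_pct_dose
    matrix_totals: dict[str, float]  # % of dose at final time
    total_recovery: float  # % of dose


def cumulative_excretion(
    intervals: Sequence[ExcretionInterval],
    dose_event: DoseEvent,
    body_weight: float,
) -> ExcretionSummary:
    """Cumulative excretion curves as percent of the administered dose.

    The dose in ng is dose_per_bw x body_weight x n_animals (pooled cages).
    Overlapping intervals within a matrix raise; an interval without a
    measured volume/weight is skipped with a warning.  A total recovery
    above 100% is physically inconsistent and warns.
    """
    if body_weight <= 0:
        raise DomainError(f"body_weight must be > 0, got {body_weight}")
    by_matrix: dict[str, list[ExcretionInterval]] = {}
    for iv in intervals:
        if iv.t_end <= iv.t_start:
            raise ValidationError(
                f"interval [{iv.t_start}, {iv.t_end}] has non-positive length"
            )
        by_matrix.setdefault(iv.matrix.value, []).append(iv)

    rows = []
    totals: dict[str, float] = {}
    for matrix, ivs in sorted(by_matrix.items()):
        ivs = sorted(ivs, key=lambda x: x.t_start)
        for a, b in zip(ivs, ivs[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValidationError(
                    f"{matrix}: overlapping intervals "
                    f"[{a.t_start},{a.t_end}] and [{b.t_start},{b.t_end}]"
                )
        n_animals = ivs[0].n_animals
        dose_ng = dose_event.dose_per_bw * body_weight * n_animals * 1e6  # mg -> ng
        cum = 0.0
        for iv in ivs:
            amt = iv.amount_ng
            if amt is None:
                warnings.warn(
                    f"{matrix} interval [{iv.t_start},{iv.t_end}]: missing "
                    "volume/weight; skipped",
                    stacklevel=2,
                )
                continue
            cum += 100.0 * amt / dose_ng
            rows.append({"matrix": matrix, "t_end": iv.t_end, "cum_pct_dose": cum})
        totals[matrix] = cum
    total = float(sum(totals.values()))
    if total > 100.0:
        warnings.warn(
            f"total recovery {total:.1f}% exceeds the administered dose",
            stacklevel=2,
        )
    return ExcretionSummary(
        cumulative=pd.DataFrame(rows, columns=["matrix", "t_end", "cum_pct_dose"]),
        matrix_totals=totals,
        total_recovery=total,
    )


@dataclass(frozen=True)
class TissueExposure:
    tissue: str
    auc: float  # h*ng/mL over the tissue sampling window
    kp_obs: float  # tissue AUC / plasma AUC
    t_peak: float  # sampled time of the maximal mean concentration


def tissue_exposure(
    tissue_profiles: Sequence[ConcTimeProfile],
    plasma_profile: ConcTimeProfile,
    method: str = "linear_up_log_down",
) -> list[TissueExposure]:
    """Observed tissue-to-plasma exposure ratios, ranked descending.

    Each AUC is integrated over its own sample times with no extrapolation
    (the sparse tissue design has too few points for a terminal fit).
    """
    plasma_auc = auc_trapezoid(
        plasma_profile.times, plasma_profile.concs, method=method
    )
    if plasma_auc <= 0:
        raise DomainError("plasma AUC must be > 0")
    out = []
    for p in tissue_profiles:
        auc = auc_trapezoid(p.times, p.concs, method=method)
        c = np.asarray(p.concs)
        t_peak = float(p.times[int(np.argmax(c))])
        out.append(
            TissueExposure(tissue=p.matrix, auc=auc, kp_obs=auc / plasma_auc, t_peak=t_peak)
        )
    return sorted(out, key=lambda e: e.kp_obs, reverse=True)


def exposure_table(exposures: Sequence[TissueExposure]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in exposures])
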