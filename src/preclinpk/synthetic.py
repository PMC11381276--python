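"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration, including the
seed: the same config yields bit-identical output.  Residual error is
multiplicative lognormal throughout (concentrations are positive and
assay CVs are relative).  Noise-free mode (sigma = 0) reproduces the
underlying closed forms to machine precision, which anchors the
round-trip tests.

Default sampling schedules mirror the study design this pipeline was
built around: dense plasma sampling to 12 h, microsomal depletion to
120 min, dialysis at 1/4/20 ug/mL, and interval excretion to 96 h.
"""
from __future__ import annotations

import enum
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .datamodel import ConcTimeProfile, DoseEvent, Route, Sample, Sex, Species
from .disposition import ExcretionInterval, ExcretionMatrix
from .errors import ConfigError
from .invitro import DialysisMeasurement, MicrosomalAssay

IV_SCHEDULE_H = [0.0333, 0.0833, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
ORAL_SCHEDULE_H = [0.0833, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
MICROSOME_SCHEDULE_MIN = [0.0, 6.0, 15.0, 30.0, 60.0, 120.0]
MICROSOME_SCHEDULE_FAST_MIN = [0.0, 3.0, 6.0, 9.0, 15.0, 30.0]
DIALYSIS_LEVELS_UG_ML = [1.0, 4.0, 20.0]
URINE_INTERVALS_H = [
    (0, 2), (2, 4), (4, 6), (6, 8), (8, 12), (12, 24), (24, 30),
    (30, 48), (48, 72), (72, 96),
]


class CompartmentModel(str, enum.Enum):
    one_compartment = "one_compartment"
    two_compartment = "two_compartment"


class GeneratorConfig(BaseModel):
    """Configuration for the compartmental profile generator.

    Typical parameter values (cl, v in L/h/kg and L/kg) are the population
    medians; per-subject parameters are drawn lognormally with the given
    between-subject CVs.  Residual error is lognormal with sdlog `sigma`.
    """

    seed: int = 0
    model: CompartmentModel = CompartmentModel.one_compartment
    route: Route = Route.iv_bolus
    dose_per_bw: float = Field(default=10.0, gt=0)
    cl: float = Field(default=3.0, gt=0, description="L/h/kg")
    v: float = Field(default=4.5, gt=0, description="central volume, L/kg")
    v2: float = Field(default=2.0, gt=0, description="peripheral volume, L/kg")
    q_dist: float = Field(default=1.0, gt=0, description="inter-compartment CL, L/h/kg")
    ka: float = Field(default=5.0, gt=0, description="1/h, oral only")
    f_oral: float = Field(default=0.4, gt=0, le=1)
    sigma: float = Field(default=0.0, ge=0, description="lognormal residual sdlog")
    bsv_cv: float = Field(default=0.0, ge=0, description="between-subject CV")
    schedule: Optional[list[float]] = None
    n_subjects: int = Field(default=1, ge=1)
    species: Species = Species.rat
    lloq: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _schedule_increasing(self) -> "GeneratorConfig":
        if self.schedule is not None:
            s = self.schedule
            if any(b <= a for a, b in zip(s, s[1:])):
                raise ConfigError(f"schedule must be strictly increasing: {s}")
        return self


def _conc_closed_form(cfg: GeneratorConfig, t: np.ndarray, cl: float, v: float) -> np.ndarray:
    """Closed-form concentration (ng/mL) at times t for one subject."""
    dose_ug_l = cfg.dose_per_bw * 1000.0  # mg/kg over L/kg -> mg/L*; scaled below
    if cfg.model is CompartmentModel.one_compartment:
        k = cl / v
        if cfg.route is Route.iv_bolus:
            return dose_ug_l / v * np.exp(-k * t)
        ka = cfg.ka
        if abs(ka - k) < 1e-12:
            ka = k * (1 + 1e-9)
        return (
            cfg.f_oral * dose_ug_l * ka / (v * (ka - k))
            * (np.exp(-k * t) - np.exp(-ka * t))
        )
    # two-compartment disposition (macro-constants from micro-rates)
    k10 = cl / v
    k12 = cfg.q_dist / v
    k21 = cfg.q_dist / cfg.v2
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4 * k10 * k21)
    alpha, beta = (s + disc) / 2, (s - disc) / 2
    if cfg.route is Route.iv_bolus:
        a = dose_ug_l / v * (alpha - k21) / (alpha - beta)
        b = dose_ug_l / v * (k21 - beta) / (alpha - beta)
        return a * np.exp(-alpha * t) + b * np.exp(-beta * t)
    ka = cfg.ka
    pref = cfg.f_oral * dose_ug_l * ka / v
    out = np.zeros_like(t)
    for lam, other in ((alpha, beta), (beta, alpha)):
        out += (
            pref * (k21 - lam)
            / ((ka - lam) * (other - lam))
            * np.exp(-lam * t)
        )
    out += pref * (k21 - ka) / ((alpha - ka) * (beta - ka)) * np.exp(-ka * t)
    return out


def generate_profiles(config: GeneratorConfig) -> list[ConcTimeProfile]:
    """Simulate concentration-time profiles under the configured kinetics."""
    rng = np.random.default_rng(config.seed)
    schedule = config.schedule
    if schedule is None:
        schedule = IV_SCHEDULE_H if config.route is Route.iv_bolus else ORAL_SCHEDULE_H
    t = np.asarray(schedule, dtype=float)
    profiles = []
    for i in range(config.n_subjects):
        cl, v = config.cl, config.v
        if config.bsv_cv > 0:
            sdlog = math.sqrt(math.log(1 + config.bsv_cv**2))
            cl = cl * rng.lognormal(-sdlog**2 / 2, sdlog)
            v = v * rng.lognormal(-sdlog**2 / 2, sdlog)
        conc = _conc_closed_form(config, t, cl, v)
        if config.sigma > 0:
            conc = conc * rng.lognormal(0.0, config.sigma, size=len(t))
        # pre-dose time-0 row retained, below quantification by construction
        samples = [Sample(time=0.0, conc=0.0, blq=True)]
        for tj, cj in zip(t, conc):
            blq = config.lloq is not None and cj < config.lloq
            samples.append(Sample(time=float(tj), conc=float(max(cj, 0.0)), blq=blq))
        profiles.append(
            ConcTimeProfile(
                subject_id=f"sim{i + 1:03d}",
                species=config.species,
                sex=Sex.unspecified,
                matrix="plasma",
                dose=DoseEvent(route=config.route, dose_per_bw=config.dose_per_bw),
                samples=samples,
                lloq=config.lloq,
            )
        )
    return profiles


def generate_microsomal_assay(
    ke_true: float,
    sigma: float = 0.0,
    schedule: Sequence[float] = tuple(MICROSOME_SCHEDULE_MIN),
    seed: int = 0,
    species: Species = Species.rat,
    n_replicates: int = 1,
) -> MicrosomalAssay:
    """Mono-exponential substrate depletion with lognormal assay error."""
    if ke_true < 0:
        raise ConfigError(f"ke_true must be >= 0, got {ke_true}")
    rng = np.random.default_rng(seed)
    t = np.asarray(schedule, dtype=float)
    reps = []
    for _ in range(n_replicates):
        rem = 100.0 * np.exp(-ke_true * t)
        if sigma > 0:
            rem = rem * rng.lognormal(0.0, sigma, size=len(t))
        reps.append([float(x) for x in rem])
    return MicrosomalAssay(
        species=species, timepoints=[float(x) for x in t], remaining=reps
    )


def generate_dialysis(
    bound_true_pct: float,
    sigma: float = 0.0,
    levels: Sequence[float] = tuple(DIALYSIS_LEVELS_UG_ML),
    seed: int = 0,
    species: Species = Species.rat,
    n_replicates: int = 3,
) -> list[DialysisMeasurement]:
    """Equilibrium-dialysis measurements at the given spiking levels."""
    if not 0 <= bound_true_pct <= 100:
        raise ConfigError(f"bound_true_pct must be in [0, 100], got {bound_true_pct}")
    rng = np.random.default_rng(seed)
    out = []
    for level in levels:
        for rep in range(n_replicates):
            c_total = level * (rng.lognormal(0.0, sigma) if sigma > 0 else 1.0)
            c_free = c_total * (1.0 - bound_true_pct / 100.0)
            if sigma > 0:
                c_free = c_free * rng.lognormal(0.0, sigma)
            out.append(
                DialysisMeasurement(
                    species=species, nominal_conc=level,
                    c_total=c_total, c_free=c_free, replicate=rep,
                )
            )
    return out


def generate_excretion(
    fe_by_matrix: dict[str, float],
    k_elim_per_h: float = 0.5,
    dose_mg_kg: float = 25.0,
    body_weight_kg: float = 0.25,
    schedule: Sequence[tuple[float, float]] = tuple(URINE_INTERVALS_H),
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[ExcretionInterval], DoseEvent]:
    """Interval excretion records from first-order elimination fractions.

    The amount in interval (t0, t1) for a matrix with eventual fraction fe
    is fe * dose * (exp(-k t0) - exp(-k t1)), perturbed multiplicatively.
    Interval volumes are fixed at 1 mL/g so concentration carries the
    amount.  Returns the intervals and the dose event they refer to.
    """
    if sum(fe_by_matrix.values()) > 1.0 + 1e-12:
        raise ConfigError("sum of fe values exceeds 1")
    rng = np.random.default_rng(seed)
    dose_ng = dose_mg_kg * body_weight_kg * 1e6
    intervals = []
    for matrix, fe in fe_by_matrix.items():
        for t0, t1 in schedule:
            amt = fe * dose_ng * (
                math.exp(-k_elim_per_h * t0) - math.exp(-k_elim_per_h * t1)
            )
            if sigma > 0:
                amt *= rng.lognormal(0.0, sigma)
            intervals.append(
                ExcretionInterval(
                    matrix=ExcretionMatrix(matrix),
                    t_start=float(t0), t_end=float(t1),
                    volume_or_weight=1.0, conc=amt,
                )
            )
    dose = DoseEvent(route=Route.oral, dose_per_bw=dose_mg_kg, body_weight=body_weight_kg)
    return intervals, dose
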