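"""Non-compartmental analysis of concentration-time profiles.

Implements the standard NCA parameter set (Cmax, Tmax, AUC by trapezoid,
terminal slope, half-life, MRT, CL, Vz) plus the derived between-dose
statistics: absolute bioavailability from mean AUCs, dose-proportionality
ratios, and repeat-dose accumulation ratios.

Conventions
-----------
* Integration default is linear-up/log-down: the log trapezoid is used on a
  segment only when both concentrations are positive and declining;
  otherwise the linear rule applies.  A pure linear rule is available.
* The terminal slope is an ordinary least-squares fit of ln(C) on t.  In
  best-fit mode every terminal window of >= 3 points is evaluated and the
  window with maximal adjusted R^2 wins, ties broken toward more points.
  Tmax is excluded as a candidate point for extravascular profiles and
  included for iv bolus.
* BLQ handling: pre-Tmax BLQ samples count as zero; post-Tmax BLQ samples
  are dropped from the terminal fit and from AUC beyond the last
  quantifiable point.
* Oral CL and Vz are apparent (per bioavailability) and flagged as such.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ConcTimeProfile, Route, clearance_l_h_kg
from .errors import DomainError, InsufficientDataError, NoTerminalPhaseError

AUCMethod = Literal["linear", "linear_up_log_down"]


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float  # 1/h
    n_points: int
    adj_r2: float
    intercept: float  # ln(ng/mL) at t=0 of the terminal line


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    route: Route
    dose_per_bw: float
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    lambda_z: float
    t_half: float
    mrt_last: float
    mrt_inf: float
    vz: float  # L/kg; apparent (Vz/F) for oral
    cl: float  # L/h/kg; apparent (CL/F) for oral
    n_lambda_points: int
    adj_r2: float
    extrapolated_fraction: float
    apparent: bool  # True when CL and Vz are per-F (oral route)


def _usable_points(profile: ConcTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ convention and return (times, concs) arrays."""
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concs, dtype=float)
    blq = np.asarray([s.blq for s in profile.samples], dtype=bool)
    if profile.lloq is not None:
        blq = blq | (c < profile.lloq)
    if not blq.any():
        return t, c
    i_tmax = int(np.argmax(c))
    keep = np.ones_like(blq)
    c = c.copy()
    for i in range(len(t)):
        if blq[i]:
            if i <= i_tmax:
                c[i] = 0.0  # pre-peak BLQ counts as zero
            else:
                keep[i] = False  # post-peak BLQ dropped
    return t[keep], c[keep]


def _backextrapolate_c0(t: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Estimate C(0) for an iv bolus by log-linear back-extrapolation of the
    first two quantifiable points (falling back to the first observed value
    when the initial segment is not declining), and anchor the profile at
    t = 0 so the pre-first-sample area is included in AUC and AUMC."""
    pos = np.nonzero(c > 0)[0]
    if len(pos) < 2 or t[pos[0]] <= 0:
        return t, c
    i1, i2 = pos[0], pos[1]
    if c[i1] > c[i2] > 0:
        slope = (math.log(c[i2]) - math.log(c[i1])) / (t[i2] - t[i1])
        c0 = math.exp(math.log(c[i1]) - slope * t[i1])
    else:
        c0 = c[i1]
    if t[0] == 0:  # replace the pre-dose zero row
        c = c.copy()
        c[0] = c0
        return t, c
    return np.concatenate(([0.0], t)), np.concatenate(([c0], c))


def auc_trapezoid(
    times: Sequence[float],
    concs: Sequence[float],
    method: AUCMethod = "linear_up_log_down",
    upper_time: Optional[float] = None,
    moment: int = 0,
) -> float:
    """Piecewise trapezoidal AUC (moment=0) or AUMC (moment=1) in h*ng/mL.

    The log-down rule applies to a segment only when both concentrations are
    strictly positive and declining; AUMC always uses the linear rule on
    t*C (the standard moment-curve convention).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if upper_time is not None:
        m = t <= upper_time + 1e-12
        t, c = t[m], c[m]
    if len(t) < 2:
        raise InsufficientDataError(
            f"need >= 2 samples for trapezoidal integration, got {len(t)}"
        )
    total = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if moment == 1:
            total += dt * (t[i] * c1 + t[i + 1] * c2) / 2.0
        elif (
            method == "linear_up_log_down"
            and c1 > 0
            and c2 > 0
            and c2 < c1
        ):
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * (c1 + c2) / 2.0
    return float(total)


def _ols_loglinear(t: np.ndarray, lnc: np.ndarray) -> tuple[float, float, float]:
    """Return (slope, intercept, adj_r2) of OLS lnc ~ t."""
    n = len(t)
    slope, intercept, r, _, _ = stats.linregress(t, lnc)
    if n > 2:
        adj_r2 = 1.0 - (1.0 - r**2) * (n - 1) / (n - 2)
    else:
        adj_r2 = r**2
    return float(slope), float(intercept), float(adj_r2)


def fit_lambda_z(
    times: Sequence[float],
    concs: Sequence[float],
    selection: Literal["best_fit", "manual"] = "best_fit",
    indices: Optional[Sequence[int]] = None,
    exclude_tmax: bool = True,
) -> LambdaZFit:
    """Fit the terminal elimination rate constant on quantifiable points.

    best_fit enumerates every terminal window of >= 3 points (optionally
    excluding Tmax for extravascular data) and keeps the window with the
    largest adjusted R^2; ties go to the window with more points.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    pos = c > 0
    t, c = t[pos], c[pos]
    if selection == "manual":
        if indices is None:
            raise DomainError("manual selection requires indices")
        t, c = t[list(indices)], c[list(indices)]
        if len(t) < 3:
            raise InsufficientDataError("manual lambda_z window needs >= 3 points")
        slope, intercept, adj_r2 = _ols_loglinear(t, np.log(c))
        if slope >= 0:
            raise NoTerminalPhaseError("manual window slope is non-negative")
        return LambdaZFit(-slope, len(t), adj_r2, intercept)

    i_tmax = int(np.argmax(c))
    first = i_tmax + 1 if exclude_tmax else i_tmax
    tail_t, tail_c = t[first:], c[first:]
    if len(tail_t) < 3:
        raise InsufficientDataError(
            f"need >= 3 post-peak quantifiable points for lambda_z, got {len(tail_t)}"
        )
    best: Optional[tuple[float, int, float, float]] = None  # adj_r2, n, slope, icpt
    for start in range(len(tail_t) - 2):
        wt, wc = tail_t[start:], tail_c[start:]
        slope, intercept, adj_r2 = _ols_loglinear(wt, np.log(wc))
        if slope >= 0:
            continue
        key = (adj_r2, len(wt))
        if best is None or key > (best[0], best[1]):
            best = (adj_r2, len(wt), slope, intercept)
    if best is None:
        raise NoTerminalPhaseError("all candidate terminal slopes are non-negative")
    adj_r2, n, slope, intercept = best
    return LambdaZFit(-slope, n, adj_r2, intercept)


def run_nca(
    profile: ConcTimeProfile,
    method: AUCMethod = "linear_up_log_down",
    lambda_z_selection: Literal["best_fit", "manual"] = "best_fit",
    lambda_z_indices: Optional[Sequence[int]] = None,
) -> NCAResult:
    """Full non-compartmental parameter set for one profile."""
    if profile.dose is None:  # pragma: no cover - pydantic enforces presence
        raise DomainError("profile has no dose event")
    t, c = _usable_points(profile)
    quant = c > 0
    if quant.sum() < 2:
        raise InsufficientDataError(
            "profile has fewer than two quantifiable post-dose points"
        )
    i_cmax = int(np.argmax(c))  # first occurrence wins on ties
    cmax, tmax = float(c[i_cmax]), float(t[i_cmax])

    iv = profile.dose.route is Route.iv_bolus
    if iv:
        t, c = _backextrapolate_c0(t, c)
        quant = c > 0

    # AUC/AUMC to the last quantifiable point
    i_last = int(np.nonzero(quant)[0][-1])
    tl, cl_ = t[: i_last + 1], c[: i_last + 1]
    auc_last = auc_trapezoid(tl, cl_, method=method)
    aumc_last = auc_trapezoid(tl, cl_, method=method, moment=1)

    fit = fit_lambda_z(
        t, c, selection=lambda_z_selection, indices=lambda_z_indices,
        exclude_tmax=not iv,
    )
    lz = fit.lambda_z
    c_last, t_last = float(cl_[-1]), float(tl[-1])
    auc_inf = auc_last + c_last / lz
    aumc_inf = aumc_last + c_last * t_last / lz + c_last / lz**2

    cl_val = clearance_l_h_kg(profile.dose.dose_per_bw, auc_inf)
    vz = cl_val / lz
    return NCAResult(
        subject_id=profile.subject_id,
        route=profile.dose.route,
        dose_per_bw=profile.dose.dose_per_bw,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        lambda_z=lz,
        t_half=math.log(2) / lz,
        mrt_last=aumc_last / auc_last,
        mrt_inf=aumc_inf / auc_inf,
        vz=vz,
        cl=cl_val,
        n_lambda_points=fit.n_points,
        adj_r2=fit.adj_r2,
        extrapolated_fraction=(auc_inf - auc_last) / auc_inf,
        apparent=not iv,
    )


def bioavailability(
    mean_auc_po: float, dose_po: float, mean_auc_iv: float, dose_iv: float
) -> float:
    """Absolute bioavailability F%% from dose-normalised mean AUCs."""
    for name, v in (
        ("mean_auc_po", mean_auc_po),
        ("dose_po", dose_po),
        ("mean_auc_iv", mean_auc_iv),
        ("dose_iv", dose_iv),
    ):
        if v <= 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return 100.0 * (mean_auc_po / dose_po) / (mean_auc_iv / dose_iv)


def dose_proportionality(values: Sequence[float]) -> list[float]:
    """Exposure ratios normalised to the lowest dose (values sorted by dose)."""
    if len(values) < 2:
        raise DomainError("need values for >= 2 dose levels")
    if any(v <= 0 for v in values):
        raise DomainError("all values must be > 0")
    ref = values[0]
    return [v / ref for v in values]


def accumulation_ratio(value_last_dose: float, value_first_dose: float) -> float:
    """Repeat-dose exposure divided by first-dose exposure."""
    if value_first_dose <= 0 or value_last_dose <= 0:
        raise DomainError("both exposures must be > 0")
    return value_last_dose / value_first_dose


_SUMMARY_PARAMS = [
    "cmax", "tmax", "auc_last", "auc_inf", "t_half",
    "mrt_last", "mrt_inf", "vz", "cl",
]


def summarize_group(results: Sequence[NCAResult]) -> pd.DataFrame:
    """Mean +/- SD per parameter across subjects (SD omitted when n = 1)."""
    if not results:
        raise DomainError("empty result group")
    df = pd.DataFrame([r.__dict__ for r in results])
    rows = []
    for p in _SUMMARY_PARAMS:
        vals = df[p].astype(float)
        rows.append(
            {
                "parameter": p,
                "n": len(vals),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def welch_t_report(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Plain two-sample Welch test between groups; a report field, not a gate."""
    res = stats.ttest_ind(list(a), list(b), equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def results_table(results: Sequence[NCAResult]) -> pd.DataFrame:
    """One row per profile, deterministic column order."""
    df = pd.DataFrame([r.__dict__ for r in results])
    df["route"] = [r.route.value for r in results]
    return df
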