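"""CSV readers and writers for concentration-time profiles and registries.

The profile schema is one row per observation:
subject, species, sex, matrix, route, dose_mg_per_kg, time_h, conc_ng_ml
with optional columns blq (0/1), lloq (ng/mL) and body_weight_kg.
Writers emit a deterministic column order so write -> read round-trips.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .datamodel import (
    ConcTimeProfile,
    DoseEvent,
    Route,
    Sample,
    Sex,
    Species,
    all_species_constants,
)
from .errors import SchemaError, ValidationError

REQUIRED_COLUMNS = [
    "subject",
    "species",
    "sex",
    "matrix",
    "route",
    "dose_mg_per_kg",
    "time_h",
    "conc_ng_ml",
]
OPTIONAL_COLUMNS = ["blq", "lloq", "body_weight_kg"]


def read_profiles(path: str | Path) -> list[ConcTimeProfile]:
    """Read a profile CSV into one ConcTimeProfile per (subject, matrix).

    Samples are sorted by time; the pre-dose time-0 row is retained.
    Raises SchemaError naming any missing required column, and
    ValidationError on duplicate times within one subject/matrix.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    profiles: list[ConcTimeProfile] = []
    for (subject, matrix), grp in df.groupby(["subject", "matrix"], sort=True):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy()
        if len(times) != len(set(times)):
            raise ValidationError(
                f"duplicate sample times for subject {subject!r}, matrix {matrix!r}"
            )
        first = grp.iloc[0]
        samples = [
            Sample(
                time=float(r.time_h),
                conc=float(r.conc_ng_ml),
                blq=bool(int(r.blq)) if "blq" in grp.columns and pd.notna(r.blq) else False,
            )
            for r in grp.itertuples()
        ]
        lloq = None
        if "lloq" in grp.columns and pd.notna(first["lloq"]):
            lloq = float(first["lloq"])
        bw = None
        if "body_weight_kg" in grp.columns and pd.notna(first["body_weight_kg"]):
            bw = float(first["body_weight_kg"])
        profiles.append(
            ConcTimeProfile(
                subject_id=str(subject),
                species=Species(first["species"]),
                sex=Sex(first["sex"]),
                matrix=str(matrix),
                dose=DoseEvent(
                    route=Route(first["route"]),
                    dose_per_bw=float(first["dose_mg_per_kg"]),
                    body_weight=bw,
                ),
                samples=samples,
                lloq=lloq,
            )
        )
    return profiles


def write_profiles(profiles: Iterable[ConcTimeProfile], path: str | Path) -> None:
    """Write profiles to CSV in the schema read_profiles consumes."""
    rows = []
    for p in profiles:
        for s in p.samples:
            rows.append(
                {
                    "subject": p.subject_id,
                    "species": p.species.value,
                    "sex": p.sex.value,
                    "matrix": p.matrix,
                    "route": p.dose.route.value,
                    "dose_mg_per_kg": p.dose.dose_per_bw,
                    "time_h": s.time,
                    "conc_ng_ml": s.conc,
                    "blq": int(s.blq),
                    "lloq": p.lloq if p.lloq is not None else "",
                    "body_weight_kg": p.dose.body_weight
                    if p.dose.body_weight is not None
                    else "",
                }
            )
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS).to_csv(
        path, index=False
    )


def species_constants_table() -> pd.DataFrame:
    """The five-species scaling-constant registry as a plain table."""
    rows = [
        {
            "species": c.species.value,
            "mppgl_mg_per_g": c.mppgl,
            "liver_bw_ratio_g_per_kg": c.liver_bw_ratio,
            "sf_mg_per_kg": c.sf,
            "q_h_ml_min_kg": c.q_h,
        }
        for c in all_species_constants()
    ]
    return pd.DataFrame(rows)
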