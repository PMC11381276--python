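"""Published summary values from the preclinical characterization of Deg-AZM.

These are the printed group means of the in vivo PK tables, the equilibrium
dialysis binding levels, the microsomal stability parameters, and the
excretion fractions.  They serve two roles: reference inputs for
computations the pipeline re-derives (bioavailability, dose ratios, the
IVIVE chain, excretion totals) and observed anchors for PBPK validation.
All values are group means; units follow the package conventions
(ng/mL, h*ng/mL, mg/kg, min).
"""
from __future__ import annotations

from .datamodel import Species

# --- rat plasma PK (mean per sex, n = 3 per sex) ----------------------------
# Single iv bolus 10 mg/kg; single oral 10/25/50 mg/kg; repeat oral 25 mg/kg.
RAT_PK = {
    "iv": {
        "dose": 10.0,
        "male": {"cmax": 5287.0, "auc_0_12": 3217.0, "auc_inf": 3227.0,
                 "t_half": 1.05, "cl_l_h_kg": 3.22, "vd_l_kg": 4.85},
        "female": {"cmax": 6733.0, "auc_0_12": 4060.0, "auc_inf": 4080.0,
                   "t_half": 1.72, "cl_l_h_kg": 2.81, "vd_l_kg": 6.82},
    },
    "oral": {
        10.0: {"male": {"cmax": 402.0, "auc_0_12": 765.0, "tmax": 0.917},
               "female": {"cmax": 1062.0, "auc_0_12": 1927.0, "tmax": 0.194}},
        25.0: {"male": {"cmax": 2000.0, "auc_0_12": 3367.0, "tmax": 0.333},
               "female": {"cmax": 3287.0, "auc_0_12": 6580.0, "tmax": 0.333}},
        50.0: {"male": {"cmax": 6730.0, "auc_0_12": 11633.0, "tmax": 0.278},
               "female": {"cmax": 7117.0, "auc_0_12": 10857.0, "tmax": 0.278}},
    },
    "repeat_oral_25_day7": {
        "male": {"cmax": 1169.0, "auc_0_12": 3310.0},
        "female": {"cmax": 2270.0, "auc_0_12": 3293.0},
    },
    # printed bioavailability cells; the male 25 mg/kg cell (82.8%) is not
    # reproducible from the printed mean AUCs and is excluded from checks
    "f_pct": {10.0: {"male": 23.8, "female": 47.46}},
}

# --- dog plasma PK (mean per sex, n = 3 per sex) ----------------------------
DOG_PK = {
    "iv": {
        "dose": 3.0,
        "male": {"auc_0_24": 11070.0, "auc_inf": 11093.0},
        "female": {"auc_0_24": 8023.0, "auc_inf": 8077.0},
    },
    "oral": {
        3.0: {"male": {"cmax": 1617.0, "auc_0_24": 3627.0},
              "female": {"cmax": 1760.0, "auc_0_24": 4603.0}},
        10.0: {"male": {"cmax": 5830.0, "auc_0_24": 14300.0},
               "female": {"cmax": 4603.0, "auc_0_24": 16700.0}},
        30.0: {"male": {"cmax": 10973.0, "auc_0_24": 40200.0},
               "female": {"cmax": 11117.0, "auc_0_24": 34700.0}},
    },
    "f_pct": {3.0: {"male": 32.8, "female": 57.4},
              10.0: {"male": 38.8, "female": 62.4},
              30.0: {"male": 36.3, "female": 43.3}},
}

# --- equilibrium dialysis: mean bound % per spiking level (ug/mL) -----------
BINDING_LEVEL_MEANS = {
    Species.mouse: {1.0: 51.1, 4.0: 46.3, 20.0: 50.6},
    Species.rat: {1.0: 37.1, 4.0: 39.6, 20.0: 41.0},
    Species.dog: {1.0: 93.7, 4.0: 91.5, 20.0: 76.9},
    Species.human: {1.0: 86.5, 4.0: 75.4, 20.0: 57.9},
}
BINDING_AVERAGES = {
    Species.mouse: 49.3, Species.rat: 39.2, Species.dog: 87.4, Species.human: 73.3,
}

# --- microsomal stability: measured depletion rate and derived chain --------
MICROSOME_KE = {  # 1/min, substrate depletion at 1 mg/mL microsomal protein
    Species.mouse: 0.00360,
    Species.rat: 0.0161,
    Species.dog: 0.00180,
    Species.monkey: 0.0887,
    Species.human: 0.0149,
}
MICROSOME_DERIVED = {  # printed (t_half min, clint, clh mL/min/kg, er)
    Species.mouse: {"t_half": 193.0, "clint": 14.2, "clh": 12.2, "er": 0.136},
    Species.rat: {"t_half": 43.0, "clint": 28.9, "clh": 18.9, "er": 0.343},
    Species.dog: {"t_half": 385.0, "clint": 4.49, "clh": 3.92, "er": 0.127},
    Species.monkey: {"t_half": 7.81, "clint": 130.0, "clh": 32.9, "er": 0.747},
    Species.human: {"t_half": 46.5, "clint": 18.7, "clh": 9.82, "er": 0.474},
}

# --- cumulative excretion at 96 h after oral 25 mg/kg, % of dose ------------
EXCRETION_PCT = {
    "male": {"urine": 17.3, "bile": 0.752, "feces": 1.97},
    "female": {"urine": 12.5, "bile": 0.623, "feces": 1.64},
}
EXCRETION_TOTALS = {"male": 20.022, "female": 14.763}

# --- observed tissue-to-plasma exposure multiples (display only; the raw
# tissue concentrations behind them are not published) -----------------------
TISSUE_EXPOSURE_ANNOTATIONS = {
    "stomach": 12.8, "fat_fraction_of_plasma": 0.357, "brain_fraction_of_plasma": 0.0836,
}

# --- human dose-escalation scenario (single ascending doses, mg) ------------
HUMAN_SAD_DOSES_MG = [5.0, 15.0, 30.0, 50.0, 80.0, 120.0, 150.0]


def pooled(mean_male: float, mean_female: float) -> float:
    """Unweighted pool of the two sex means (equal n per sex)."""
    return 0.5 * (mean_male + mean_female)


def rat_oral_observed_pooled() -> dict[float, dict[str, float]]:
    """Pooled-sex observed oral Cmax and AUC(0-12 h) per dose, for validation."""
    out = {}
    for dose, by_sex in RAT_PK["oral"].items():
        out[dose] = {
            "cmax": pooled(by_sex["male"]["cmax"], by_sex["female"]["cmax"]),
            "auc": pooled(by_sex["male"]["auc_0_12"], by_sex["female"]["auc_0_12"]),
            "tmax": pooled(by_sex["male"]["tmax"], by_sex["female"]["tmax"]),
        }
    return out
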