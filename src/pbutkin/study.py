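"""Reference parameter set for six uremic solutes in chronic hemodialysis.

The package ships the published summary statistics of a calibration cohort of
ten stable patients on thrice-weekly 4-h high-flux hemodialysis (blood flow
300 mL/min, dialysate flow 700 mL/min, mean ultrafiltration 0.41 L/h):
protein binding, predialysis concentration, generation rate and dialyzer
clearance per solute, plus the kinetically derived plasmatic volume, total
distribution volume and intercompartment clearance.  Normally distributed
quantities are summarised as ``("normal", mean, sd)``; skewed ones as
``("lognormal", median, q25, q75)``.

``central`` returns the printed central value (mean or median as published);
``reference_kinetics`` assembles the canonical per-solute parameter bundles
that drive the strategy simulations; all concentrations are canonical mg/L.
"""

from __future__ import annotations

from .clearance import Anthropometrics
from .kinetics import SoluteKinetics
from .samples import SessionPrescription

__all__ = [
    "SOLUTES",
    "PARAMETER_DISTRIBUTIONS",
    "COHORT_DISTRIBUTIONS",
    "REFERENCE_PRESCRIPTION",
    "REFERENCE_ANTHROPOMETRICS",
    "WEEKLY_UF_L",
    "central",
    "central_table",
    "reference_kinetics",
    "reference_c_pre",
]

#: Solutes in decreasing dialyzer-clearance order (urea, p-cresylglucuronide,
#: hippuric acid, indole acetic acid, indoxyl sulfate, p-cresylsulfate).
SOLUTES = ("urea", "PCG", "HA", "IAA", "IS", "PCS")

# Per-solute summary statistics.  Units: PB %, C_pre mg/L, G mg/min,
# K and K21 mL/min, V1 and Vtot L.
PARAMETER_DISTRIBUTIONS: dict[str, dict[str, tuple]] = {
    "urea": {
        "PB": ("normal", 0.0, 0.0),
        "C_pre": ("lognormal", 950.0, 900.0, 1280.0),
        "G": ("normal", 9.7, 2.6),
        "K": ("normal", 224.0, 20.0),
        "V1": ("normal", 10.2, 5.6),
        "Vtot": ("normal", 32.9, 8.1),
        "K21": ("normal", 457.0, 175.0),
    },
    "PCG": {
        "PB": ("lognormal", 13.0, 12.0, 15.0),
        "C_pre": ("lognormal", 3.5, 2.6, 7.9),
        "G": ("lognormal", 0.019, 0.016, 0.049),
        "K": ("normal", 152.0, 28.0),
        "V1": ("normal", 8.2, 2.4),
        "Vtot": ("lognormal", 18.9, 15.7, 25.2),
        "K21": ("normal", 103.0, 47.0),
    },
    "HA": {
        "PB": ("normal", 47.0, 12.0),
        "C_pre": ("lognormal", 24.1, 18.2, 47.7),
        "G": ("lognormal", 0.136, 0.123, 0.321),
        "K": ("normal", 132.0, 12.0),
        "V1": ("normal", 8.4, 3.8),
        "Vtot": ("normal", 20.9, 4.7),
        "K21": ("normal", 169.0, 81.0),
    },
    "IAA": {
        "PB": ("normal", 73.0, 9.0),
        "C_pre": ("normal", 2.1, 1.2),
        "G": ("normal", 0.005, 0.003),
        "K": ("normal", 52.0, 8.0),
        "V1": ("normal", 4.9, 1.5),
        "Vtot": ("normal", 24.7, 10.6),
        "K21": ("normal", 123.0, 46.0),
    },
    "IS": {
        "PB": ("lognormal", 93.0, 91.0, 95.0),
        "C_pre": ("normal", 15.1, 8.8),
        "G": ("normal", 0.024, 0.015),
        "K": ("normal", 27.0, 5.0),
        "V1": ("lognormal", 3.7, 3.7, 4.2),
        "Vtot": ("normal", 16.5, 6.5),
        "K21": ("normal", 85.0, 72.0),
    },
    "PCS": {
        "PB": ("lognormal", 95.0, 94.0, 96.0),
        "C_pre": ("normal", 30.6, 15.3),
        "G": ("normal", 0.044, 0.026),
        "K": ("normal", 21.0, 4.0),
        "V1": ("normal", 3.8, 0.9),
        "Vtot": ("lognormal", 10.4, 9.8, 15.1),
        "K21": ("normal", 87.0, 44.0),
    },
}

#: Cohort anthropometrics: body weight kg, hematocrit fraction, total protein g/L.
COHORT_DISTRIBUTIONS: dict[str, tuple] = {
    "body_weight": ("lognormal", 75.0, 69.9, 82.6),
    "hematocrit": ("normal", 0.372, 0.042),
    "TP_pre": ("normal", 61.4, 6.4),
}

REFERENCE_PRESCRIPTION = SessionPrescription(Q_B=300.0, Q_D=700.0, Q_UF=0.41, duration=240.0)
REFERENCE_ANTHROPOMETRICS = Anthropometrics(body_weight=75.0, hematocrit=0.372, TP_pre=61.4)

#: Weekly net fluid removal, L (0.41 L/h x 4 h x 3 sessions).
WEEKLY_UF_L = 0.41 * 4.0 * 3.0


def central(solute: str, param: str) -> float:
    """Published central value (mean or median, as summarised) of a parameter."""
    return float(PARAMETER_DISTRIBUTIONS[solute][param][1])


def central_table():
    """Central values as a solute-by-parameter DataFrame (canonical units)."""
    import pandas as pd

    params = ("PB", "C_pre", "G", "K", "V1", "Vtot", "K21")
    return pd.DataFrame(
        {p: [central(s, p) for s in SOLUTES] for p in params}, index=list(SOLUTES)
    )


def reference_kinetics(solute: str) -> SoluteKinetics:
    """Canonical parameter bundle for one solute, from the central values."""
    return SoluteKinetics(
        solute_id=solute,
        K=central(solute, "K"),
        K21=central(solute, "K21"),
        V1_0=central(solute, "V1"),
        Vtot_0=central(solute, "Vtot"),
        G=central(solute, "G"),
        PB=central(solute, "PB"),
    )


def reference_c_pre(solute: str) -> float:
    """Central predialysis plasma concentration, mg/L."""
    return central(solute, "C_pre")
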