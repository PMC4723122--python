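"""Virtual patients, sessions and sample sheets.

The generator emulates the calibration study's design so the whole pipeline
is testable without patient data: per-patient solute parameters are drawn
from the published summary statistics (mean ± SD entries → truncated normal;
median [IQR] entries → log-normal matched by quantiles), a 4-h session is
simulated with the two-pool model, and a sample sheet is emitted with the
study's sampling scheme — inlet plasma at 0/15/30/60/120/240 min, outlet at
30/120 min, dialysate at 30/120 min plus the full-session collection.

Protein-bound solute plasma samples are hemoconcentrated: total protein
rises as ultrafiltration shrinks the plasma volume (one third of the
ultrafiltrate is assumed to leave the vascular space between refill), and
the emitted "measured" concentration is the model concentration divided by
the correction factor ``F = TP_pre/TP_t``, so the standard correction
round-trips exactly.  Outlet and spot-dialysate concentrations are derived
from the clearance identities, so both clearance estimators recover the
generating ``K`` exactly in the noiseless limit.  Measurement noise is
multiplicative log-normal with unit mean and a configurable CV.

Between-solute parameter correlations within a patient are unreported in
the source summaries; solutes are sampled independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .clearance import Anthropometrics, plasma_volume_floor
from .errors import PbutkinError
from .kinetics import PhaseSpec, SoluteKinetics, initial_state, simulate_phase
from .samples import SamplePoint, SampleSheet, SessionPrescription
from .study import (
    COHORT_DISTRIBUTIONS,
    PARAMETER_DISTRIBUTIONS,
    REFERENCE_PRESCRIPTION,
    SOLUTES,
)

__all__ = ["CohortSpec", "VirtualPatient", "Cohort", "sample_cohort", "generate_sample_sheet"]

INLET_TIMES = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)
OUTLET_TIMES = (30.0, 120.0)
DIALYSATE_TIMES = (30.0, 120.0)

#: Fraction of the ultrafiltered volume drawn from plasma (vascular refill
#: replaces the rest), driving the synthetic total-protein course.
PLASMA_UF_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a virtual cohort."""

    n_patients: int = 10
    solutes: tuple[str, ...] = SOLUTES
    noise_cv: float = 0.05
    seed: int = 0
    parameter_distributions: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: PARAMETER_DISTRIBUTIONS
    )
    cohort_distributions: Mapping[str, tuple] = field(
        default_factory=lambda: COHORT_DISTRIBUTIONS
    )
    prescription: SessionPrescription = REFERENCE_PRESCRIPTION

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class VirtualPatient:
    patient_id: str
    anthropometrics: Anthropometrics
    kinetics: dict[str, SoluteKinetics]
    c_pre: dict[str, float]  # mg/L


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[VirtualPatient]

    def manifest(self) -> dict:
        """JSON-serialisable description of the cohort (for reproducibility)."""
        return {
            "n_patients": self.spec.n_patients,
            "solutes": list(self.spec.solutes),
            "noise_cv": self.spec.noise_cv,
            "seed": self.spec.seed,
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "body_weight": p.anthropometrics.body_weight,
                    "hematocrit": p.anthropometrics.hematocrit,
                    "TP_pre": p.anthropometrics.TP_pre,
                    "kinetics": {
                        s: {
                            "K": k.K,
                            "K21": k.K21,
                            "V1_0": k.V1_0,
                            "Vtot_0": k.Vtot_0,
                            "G": k.G,
                            "PB": k.PB,
                            "C_pre": p.c_pre[s],
                        }
                        for s, k in p.kinetics.items()
                    },
                }
                for p in self.patients
            ],
        }


def _lognormal_params(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matched to the median and IQR."""
    mu = np.log(median)
    if q75 <= q25 or q25 <= 0:
        return mu, 0.0
    sigma = np.log(q75 / q25) / (2.0 * 0.6744897501960817)
    return mu, sigma


def _draw(rng: np.random.Generator, dist: tuple, lo: float = -np.inf, hi: float = np.inf) -> float:
    """One draw from a summary-statistic family, truncated by rejection."""
    family = dist[0]
    for _ in range(1000):
        if family == "normal":
            _, mean, sd = dist
            x = rng.normal(mean, sd) if sd > 0 else mean
        elif family == "lognormal":
            _, median, q25, q75 = dist
            mu, sigma = _lognormal_params(median, q25, q75)
            x = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else median
        else:
            raise PbutkinError(f"unknown distribution family {family!r}")
        if lo <= x <= hi:
            return float(x)
        if dist[0] == "normal" and dist[2] == 0 or dist[0] == "lognormal" and dist[2] == dist[3]:
            break
    return float(min(max(dist[1], lo), hi))


def sample_cohort(spec: CohortSpec) -> Cohort:
    """Draw a reproducible virtual cohort.

    Per-solute parameters are resampled until they satisfy the kinetic
    invariants: clearances non-negative, ``V1`` at least the patient's
    plasma-volume floor, and ``V1 < Vtot``.
    """
    rng = np.random.default_rng(spec.seed)
    patients = []
    for i in range(spec.n_patients):
        cd = spec.cohort_distributions
        anth = Anthropometrics(
            body_weight=_draw(rng, cd["body_weight"], lo=30.0, hi=200.0),
            hematocrit=_draw(rng, cd["hematocrit"], lo=0.15, hi=0.65),
            TP_pre=_draw(rng, cd["TP_pre"], lo=30.0, hi=100.0),
        )
        floor = plasma_volume_floor(anth)
        kinetics: dict[str, SoluteKinetics] = {}
        c_pre: dict[str, float] = {}
        for s in spec.solutes:
            d = spec.parameter_distributions[s]
            for _ in range(1000):
                v1 = _draw(rng, d["V1"], lo=floor)
                vtot = _draw(rng, d["Vtot"], lo=v1 + 0.5)
                if v1 >= floor and vtot > v1:
                    break
            kinetics[s] = SoluteKinetics(
                solute_id=s,
                K=_draw(rng, d["K"], lo=0.1),
                K21=_draw(rng, d["K21"], lo=1.0),
                V1_0=v1,
                Vtot_0=vtot,
                G=_draw(rng, d["G"], lo=0.0),
                PB=_draw(rng, d["PB"], lo=0.0, hi=100.0),
            )
            c_pre[s] = _draw(rng, d["C_pre"], lo=1e-3)
        patients.append(
            VirtualPatient(
                patient_id=f"P{i + 1:03d}",
                anthropometrics=anth,
                kinetics=kinetics,
                c_pre=c_pre,
            )
        )
    return Cohort(spec=spec, patients=patients)


def _noise(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative log-normal factor with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def generate_sample_sheet(
    kin: SoluteKinetics,
    prescription: SessionPrescription = REFERENCE_PRESCRIPTION,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    c_pre: float,
    anthropometrics: Anthropometrics | None = None,
    patient_id: str = "P001",
    generation_during_session: bool = True,
) -> SampleSheet:
    """Simulate one session and emit its sample sheet.

    With ``noise_cv = 0`` every emitted value equals the model prediction
    (after undoing hemoconcentration for protein-bound solutes), the
    dialysate collection equals the trajectory's cumulative removal, and the
    free/total pair at t = 0 reproduces the bundle's protein binding exactly.
    """
    rng = np.random.default_rng(seed)
    tp_pre = anthropometrics.TP_pre if anthropometrics is not None else 61.4
    if anthropometrics is not None:
        vp0 = plasma_volume_floor(anthropometrics)
    else:
        vp0 = 3.6
    g = kin.G if generation_during_session else 0.0
    phase = PhaseSpec.dialysis(prescription.duration, kin.K, prescription.Q_UF, g)
    times = np.unique(np.concatenate([INLET_TIMES, OUTLET_TIMES, DIALYSATE_TIMES]))
    times = times[times <= prescription.duration]
    traj = simulate_phase(kin, phase, initial_state(kin, c_pre), t_eval=times)

    def model_c1(t: float) -> float:
        return float(traj.interp_C1(np.array([t]))[0])

    quf_l_min = prescription.Q_UF / 60.0
    protein_bound = kin.PB > 0

    def tp_at(t: float) -> float:
        vp = vp0 - PLASMA_UF_FRACTION * quf_l_min * t
        return tp_pre * vp0 / max(vp, 0.2 * vp0)

    def hemoconc(t: float) -> float:
        # F = TP_pre / TP_t; measured = model / F for protein-bound solutes
        return tp_pre / tp_at(t) if protein_bound else 1.0

    points: list[SamplePoint] = []
    for t in INLET_TIMES:
        if t > prescription.duration:
            continue
        c_meas = model_c1(t) / hemoconc(t) * _noise(rng, noise_cv)
        c_free = c_meas * (1.0 - kin.PB / 100.0) if t == 0.0 else None
        points.append(
            SamplePoint(
                patient_id=patient_id,
                solute_id=kin.solute_id,
                t=t,
                site="inlet",
                C_total=c_meas,
                C_free=c_free,
                TP=tp_at(t),
            )
        )
    quf_ml_min = prescription.quf_ml_per_min
    for t in OUTLET_TIMES:
        c_in = model_c1(t) / hemoconc(t)
        c_out = c_in * (prescription.Q_B - kin.K) / (prescription.Q_B - quf_ml_min)
        points.append(
            SamplePoint(
                patient_id=patient_id,
                solute_id=kin.solute_id,
                t=t,
                site="outlet",
                C_total=max(c_out, 0.0) * _noise(rng, noise_cv),
                TP=tp_at(t),
            )
        )
    for t in DIALYSATE_TIMES:
        c_in = model_c1(t) / hemoconc(t)
        c_d = kin.K * c_in / prescription.Q_D
        points.append(
            SamplePoint(
                patient_id=patient_id,
                solute_id=kin.solute_id,
                t=t,
                site="dialysate",
                C_total=c_d * _noise(rng, noise_cv),
            )
        )
    points.append(
        SamplePoint(
            patient_id=patient_id,
            solute_id=kin.solute_id,
            t=prescription.duration,
            site="dialysate_total",
            C_total=traj.removal * _noise(rng, noise_cv),
        )
    )
    return SampleSheet(points)
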