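"""Pointwise measured-quantity calculations for a dialysis session.

Dialyzer clearance is estimated two ways: from the inlet/outlet plasma drop
(blood side, used for urea) and from the spent dialysate (dialysate side,
used for protein-bound solutes, where only the free fraction crosses the
membrane but the dialysate collects everything that did).  Both are assumed
constant over the session and summarised as the mean of the 30-min and
120-min estimates.  The module also holds protein binding, hemoconcentration
correction, the plasma-volume floor used as a fitting bound, the generation
rate inferred from the full dialysate collection, reduction ratio, and the
second-generation single-pool Daugirdas Kt/V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import (
    InfeasiblePrescriptionError,
    InvalidSampleError,
    MeasurementInconsistencyError,
)

__all__ = [
    "Anthropometrics",
    "session_clearance",
    "blood_side_clearance",
    "dialysate_side_clearance",
    "protein_binding",
    "hemoconcentration_factor",
    "plasma_volume_floor",
    "generation_rate",
    "reduction_ratio",
    "sp_ktv_daugirdas",
    "MIDWEEK_CYCLE_MINUTES",
]

#: Midweek two-day interdialytic cycle including the 4-h session, minutes.
MIDWEEK_CYCLE_MINUTES = 2 * 24 * 60 + 240


@dataclass(frozen=True)
class Anthropometrics:
    """Patient body size descriptors used for the plasma-volume floor."""

    body_weight: float  # kg
    hematocrit: float  # fraction, 0-1
    TP_pre: float = float("nan")  # predialysis total protein, g/L

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        if not 0 < self.hematocrit < 1:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")


def blood_side_clearance(C_in: float, C_out: float, Q_B: float, Q_UF: float) -> float:
    """Dialyzer clearance from the inlet-to-outlet plasma concentration drop.

    ``K = (Q_B*C_in - (Q_B - Q_UF)*C_out) / C_in`` with all flows in mL/min;
    the outlet blood flow is the inlet flow minus ultrafiltration.
    """
    if C_in <= 0:
        raise InvalidSampleError(f"inlet concentration must be > 0, got {C_in}")
    if not 0 <= Q_UF < Q_B:
        raise ValueError(f"need 0 <= Q_UF < Q_B, got Q_UF={Q_UF}, Q_B={Q_B}")
    K = (Q_B * C_in - (Q_B - Q_UF) * C_out) / C_in
    if K < 0:
        raise MeasurementInconsistencyError(
            f"negative clearance ({K:.1f} mL/min): outlet concentration "
            f"{C_out} exceeds what inlet {C_in} allows at these flows"
        )
    return K


def dialysate_side_clearance(C_dialysate: float, Q_D: float, C_in_total: float) -> float:
    """Clearance referred to total blood concentration, from spent dialysate.

    ``K = Q_D * C_dialysate / C_in_total`` (mL/min).
    """
    if C_in_total <= 0:
        raise InvalidSampleError(
            f"total inlet concentration must be > 0, got {C_in_total}"
        )
    if Q_D <= 0:
        raise ValueError(f"Q_D must be > 0, got {Q_D}")
    if C_dialysate < 0:
        raise InvalidSampleError(
            f"dialysate concentration must be >= 0, got {C_dialysate}"
        )
    return Q_D * C_dialysate / C_in_total


def protein_binding(C_total: float, C_free: float) -> float:
    """Protein-bound fraction in percent, ``100*(C_total - C_free)/C_total``."""
    if C_total <= 0:
        raise InvalidSampleError(f"total concentration must be > 0, got {C_total}")
    if not 0 <= C_free <= C_total:
        raise InvalidSampleError(
            f"free concentration {C_free} outside [0, total={C_total}]"
        )
    return 100.0 * (C_total - C_free) / C_total


def hemoconcentration_factor(TP_pre: float, TP_t: float) -> float:
    """Correction factor ``F = TP_pre / TP_t`` for ultrafiltration-driven
    hemoconcentration; corrected concentration is ``F * C_measured``."""
    if TP_pre <= 0 or TP_t <= 0:
        raise InvalidSampleError(
            f"total protein must be > 0, got TP_pre={TP_pre}, TP_t={TP_t}"
        )
    return TP_pre / TP_t


def plasma_volume_floor(a: Anthropometrics) -> float:
    """Lower bound on the plasmatic volume, L.

    Total blood volume is taken as 1/13 of body weight (1 kg ≈ 1 L); the
    plasma fraction is ``1 - hematocrit``.
    """
    return a.body_weight / 13.0 * (1.0 - a.hematocrit)


def generation_rate(
    total_dialysate_mass: float,
    cycle_minutes: float = MIDWEEK_CYCLE_MINUTES,
) -> float:
    """Generation rate (mg/min) from the full-session dialysate collection.

    Removal and generation are assumed in equilibrium over the midweek cycle,
    so the mass recovered in the spent dialysate divided by the cycle length
    (default: two interdialytic days plus the 240-min session = 3120 min)
    estimates G.
    """
    if total_dialysate_mass < 0:
        raise InvalidSampleError(
            f"dialysate mass must be >= 0, got {total_dialysate_mass}"
        )
    if cycle_minutes <= 0:
        raise ValueError(f"cycle_minutes must be > 0, got {cycle_minutes}")
    return total_dialysate_mass / cycle_minutes


def reduction_ratio(C_pre: float, C_post: float) -> float:
    """Pre-to-post concentration reduction in percent."""
    if C_pre <= 0:
        raise InvalidSampleError(f"predialysis concentration must be > 0, got {C_pre}")
    if C_post < 0:
        raise InvalidSampleError(f"postdialysis concentration must be >= 0, got {C_post}")
    return 100.0 * (C_pre - C_post) / C_pre


def sp_ktv_daugirdas(
    C_pre: float,
    C_post: float,
    t_hours: float,
    UF_L: float,
    BW_kg: float,
) -> float:
    """Second-generation single-pool Daugirdas Kt/V.

    ``Kt/V = -ln(R - 0.008*t) + (4 - 3.5*R) * UF/W`` with ``R = C_post/C_pre``,
    ``t`` in hours, ultrafiltered volume in L and body weight in kg.
    """
    if C_pre <= 0 or C_post <= 0:
        raise InvalidSampleError("concentrations must be > 0")
    R = C_post / C_pre
    if not 0 < R < 1:
        raise InvalidSampleError(f"need 0 < C_post/C_pre < 1, got R={R:.3f}")
    arg = R - 0.008 * t_hours
    if arg <= 0:
        raise InfeasiblePrescriptionError(
            f"log-domain violation: R - 0.008*t = {arg:.4f} <= 0"
        )
    return -math.log(arg) + (4.0 - 3.5 * R) * UF_L / BW_kg


#: Session time points (min) at which clearance is estimated.
CLEARANCE_TIMES = (30.0, 120.0)


def session_clearance(sheet, prescription, solute_id=None, mode="auto"):
    """Session-constant dialyzer clearance from a sample sheet, mL/min.

    The clearance is estimated at 30 and 120 min and the two values averaged.
    ``mode`` selects the estimator: ``"blood"`` (inlet/outlet concentration
    drop, used for urea), ``"dialysate"`` (spent-dialysate concentration over
    total inlet concentration, used for protein-bound solutes), or ``"auto"``
    which picks ``"blood"`` for urea and ``"dialysate"`` otherwise.  Raw
    measured concentrations are used; hemoconcentration correction applies
    only to the plasma series prepared for kinetic fitting.

    Raises :class:`~pbutkin.errors.MissingDataError` when a required sample
    is absent.
    """
    from .samples import SampleSheet  # local import avoids a cycle

    if not isinstance(sheet, SampleSheet):
        raise TypeError("sheet must be a SampleSheet")
    if solute_id is None:
        solutes = sheet.solutes
        if len(solutes) != 1:
            raise ValueError("sheet holds several solutes; pass solute_id")
        solute_id = solutes[0]
    if mode == "auto":
        mode = "blood" if solute_id.lower() == "urea" else "dialysate"

    values = []
    for t in CLEARANCE_TIMES:
        c_in = sheet.sample_at("inlet", t, solute_id).C_total
        if mode == "blood":
            c_out = sheet.sample_at("outlet", t, solute_id).C_total
            values.append(
                blood_side_clearance(c_in, c_out, prescription.Q_B, prescription.quf_ml_per_min)
            )
        elif mode == "dialysate":
            c_d = sheet.sample_at("dialysate", t, solute_id).C_total
            values.append(dialysate_side_clearance(c_d, prescription.Q_D, c_in))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return sum(values) / len(values)
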