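"""Two-compartment, variable-volume solute kinetics.

The patient is modelled as a plasmatic pool (volume ``V1``, concentration
``C1``) exchanging solute with an extraplasmatic pool (``V2``, ``C2``) through
an intercompartment clearance ``K21``.  During dialysis the dialyzer clears
plasma at clearance ``K`` while ultrafiltration shrinks both volumes; between
sessions the dialyzer is disconnected (``K = 0``) and fluid re-accumulates.
Solute generation ``G`` is constant.  The governing mass balances are

    d(V1*C1)/dt = G - K*C1 + K21*(C2 - C1)
    d(V2*C2)/dt =          - K21*(C2 - C1)

with the net ultrafiltration flow partitioned over the compartments in
proportion to their volumes, so that the volume ratio ``V1/V2`` is constant
within a phase (quick refill from the deep pool is assumed).  Summing the two
balances shows that total mass obeys ``dM/dt = G - K*C1`` exactly, which the
solver output is audited against.

Canonical units: minutes, mL/min for clearances, L for volumes, mg/L for
concentrations and mg for mass.  ``PhaseSpec`` accepts the ultrafiltration
rate in L/h because prescriptions are written that way; it is converted on
entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InfeasiblePrescriptionError, IntegrationFailureError

__all__ = [
    "SoluteKinetics",
    "CompartmentState",
    "PhaseSpec",
    "Trajectory",
    "simulate_phase",
    "simulate_single_pool",
    "total_mass",
    "initial_state",
]


@dataclass(frozen=True)
class SoluteKinetics:
    """Per-solute kinetic parameter bundle.

    Parameters
    ----------
    solute_id : str
        Solute label (e.g. ``"urea"``, ``"IS"``).
    K : float
        Dialyzer clearance, mL/min (at the prescription it was measured under).
    K21 : float
        Intercompartment clearance, mL/min.
    V1_0 : float
        Predialysis plasmatic distribution volume, L.
    Vtot_0 : float
        Predialysis total distribution volume, L (``V2_0 = Vtot_0 - V1_0``).
    G : float
        Endogenous generation rate, mg/min.
    PB : float
        Protein-bound fraction at dialysis start, percent.
    """

    solute_id: str
    K: float
    K21: float
    V1_0: float
    Vtot_0: float
    G: float
    PB: float = 0.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.K21 < 0:
            raise ValueError(f"K21 must be >= 0, got {self.K21}")
        if not 0 < self.V1_0 < self.Vtot_0:
            raise ValueError(
                f"need 0 < V1_0 < Vtot_0, got V1_0={self.V1_0}, Vtot_0={self.Vtot_0}"
            )
        if self.G < 0:
            raise ValueError(f"G must be >= 0, got {self.G}")
        if not 0 <= self.PB <= 100:
            raise ValueError(f"PB must be in [0, 100], got {self.PB}")

    @property
    def V2_0(self) -> float:
        """Predialysis extraplasmatic volume, L."""
        return self.Vtot_0 - self.V1_0

    def with_clearance(self, K: float) -> "SoluteKinetics":
        """Copy of this bundle with a different dialyzer clearance."""
        return replace(self, K=K)


@dataclass(frozen=True)
class CompartmentState:
    """Instantaneous volumes (L) and concentrations (mg/L) of both pools."""

    t: float
    V1: float
    V2: float
    C1: float
    C2: float

    def __post_init__(self) -> None:
        if self.V1 <= 0:
            raise ValueError(f"V1 must be > 0, got {self.V1}")
        if self.V2 < 0:
            raise ValueError(f"V2 must be >= 0, got {self.V2}")
        if self.C1 < 0 or self.C2 < 0:
            raise ValueError("concentrations must be non-negative")


PhaseKind = Literal["dialysis", "interdialytic"]


@dataclass(frozen=True)
class PhaseSpec:
    """One homogeneous stretch of the weekly cycle.

    ``Q_UF`` is the net fluid removal rate in L/h; a negative value models
    interdialytic fluid accrual.  ``K_effective`` must be 0 for interdialytic
    phases.
    """

    phase_kind: PhaseKind
    duration: float  # min
    K_effective: float  # mL/min
    Q_UF: float  # L/h, positive = removal
    G: float  # mg/min

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.phase_kind == "interdialytic" and self.K_effective != 0:
            raise ValueError("interdialytic phases must have K_effective = 0")
        if self.K_effective < 0:
            raise ValueError("K_effective must be >= 0")

    @classmethod
    def dialysis(cls, duration: float, K: float, Q_UF: float, G: float) -> "PhaseSpec":
        return cls("dialysis", duration, K, Q_UF, G)

    @classmethod
    def interdialytic(cls, duration: float, Q_UF: float, G: float) -> "PhaseSpec":
        return cls("interdialytic", duration, 0.0, Q_UF, G)

    @property
    def quf_l_per_min(self) -> float:
        return self.Q_UF / 60.0


@dataclass
class Trajectory:
    """Simulated phase on a time grid, with removal bookkeeping.

    ``cumulative_removal`` is the dialyzer flux integral ``∫ K·C1 dτ`` (mg)
    from the start of the phase; ``auc1`` is ``∫ C1 dτ`` (mg·min/L) over the
    whole phase, used for time-averaged concentrations.
    """

    time_grid: np.ndarray  # absolute minutes
    C1: np.ndarray
    C2: np.ndarray
    V1: np.ndarray
    V2: np.ndarray
    cumulative_removal: np.ndarray  # mg
    auc1: float = field(default=0.0)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(np.diff(self.cumulative_removal) < -1e-9):
            raise ValueError("cumulative removal must be non-decreasing")

    @property
    def states(self) -> Sequence[CompartmentState]:
        return [
            CompartmentState(t=float(t), V1=float(v1), V2=float(v2), C1=float(c1), C2=float(c2))
            for t, v1, v2, c1, c2 in zip(self.time_grid, self.V1, self.V2, self.C1, self.C2)
        ]

    @property
    def initial_state(self) -> CompartmentState:
        return self.states[0]

    @property
    def final_state(self) -> CompartmentState:
        i = -1
        return CompartmentState(
            t=float(self.time_grid[i]),
            V1=float(self.V1[i]),
            V2=float(self.V2[i]),
            C1=float(self.C1[i]),
            C2=float(self.C2[i]),
        )

    @property
    def removal(self) -> float:
        """Total mass removed over the phase, mg."""
        return float(self.cumulative_removal[-1])

    def interp_C1(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.time_grid, self.C1)

    def to_frame(self, solute: str = "", phase: str = "") -> pd.DataFrame:
        """Tidy export (one row per grid point)."""
        return pd.DataFrame(
            {
                "solute": solute,
                "phase": phase,
                "t_min": self.time_grid,
                "C1": self.C1,
                "C2": self.C2,
                "V1": self.V1,
                "V2": self.V2,
                "cum_removal_mg": self.cumulative_removal,
            }
        )


def total_mass(state: CompartmentState) -> float:
    """Total solute mass in both pools, mg (``V1*C1 + V2*C2``)."""
    return state.V1 * state.C1 + state.V2 * state.C2


def initial_state(kin: SoluteKinetics, c_pre: float, t: float = 0.0) -> CompartmentState:
    """Predialysis state: both pools at the measured plasma concentration."""
    return CompartmentState(t=t, V1=kin.V1_0, V2=kin.V2_0, C1=c_pre, C2=c_pre)


def _make_grid(t0: float, duration: float, grid_minutes: float) -> np.ndarray:
    n = max(int(np.floor(duration / grid_minutes)), 1)
    grid = t0 + np.arange(n + 1) * grid_minutes
    if grid[-1] < t0 + duration - 1e-9:
        grid = np.append(grid, t0 + duration)
    else:
        grid[-1] = t0 + duration
    return grid


def simulate_phase(
    kin: SoluteKinetics,
    phase: PhaseSpec,
    init: CompartmentState,
    *,
    grid_minutes: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the two-pool mass balances over one phase.

    The dialyzer clearance and generation rate are taken from ``phase``
    (``phase.K_effective``, ``phase.G``); the intercompartment clearance from
    ``kin``.  Volumes follow the proportional-partition rule analytically:
    ``Vtot(t) = Vtot(0) - Q_UF·t`` and ``V1(t)/Vtot(t)`` constant, so only
    concentrations, the removal integral and the C1 area are integrated.

    Raises
    ------
    InfeasiblePrescriptionError
        If ultrafiltration would drive the volumes to zero within the phase.
    IntegrationFailureError
        If the solver fails or produces a non-finite state.
    """
    quf = phase.quf_l_per_min  # L/min
    vtot0 = init.V1 + init.V2
    if vtot0 - quf * phase.duration <= 0:
        raise InfeasiblePrescriptionError(
            f"ultrafiltration {phase.Q_UF} L/h over {phase.duration} min empties the "
            f"distribution volume ({vtot0:.2f} L)"
        )

    f1 = init.V1 / vtot0  # constant plasmatic volume fraction within the phase
    dv1 = -quf * f1
    dv2 = -quf * (1.0 - f1)
    k_l = phase.K_effective / 1000.0  # L/min
    k21_l = kin.K21 / 1000.0
    g = phase.G
    two_pool = init.V2 > 0

    t0 = init.t

    def rhs(t: float, y: np.ndarray) -> list[float]:
        c1, c2 = y[0], y[1]
        vtot = vtot0 - quf * (t - t0)
        v1 = f1 * vtot
        flux = k21_l * (c2 - c1) if two_pool else 0.0
        dc1 = (g - k_l * c1 + flux - c1 * dv1) / v1
        if two_pool:
            v2 = (1.0 - f1) * vtot
            dc2 = (-flux - c2 * dv2) / v2
        else:
            dc2 = 0.0
        return [dc1, dc2, k_l * c1, c1]

    if t_eval is not None:
        grid = np.union1d(
            np.asarray(t_eval, dtype=float), [init.t, init.t + phase.duration]
        )
        if grid[0] < init.t - 1e-9 or grid[-1] > init.t + phase.duration + 1e-9:
            raise ValueError("t_eval must lie within the phase span")
    else:
        grid = _make_grid(init.t, phase.duration, grid_minutes)
    sol = solve_ivp(
        rhs,
        (init.t, init.t + phase.duration),
        [init.C1, init.C2, 0.0, 0.0],
        method=method,
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationFailureError(
            f"integration failed for solute {kin.solute_id!r} "
            f"(K={phase.K_effective}, K21={kin.K21}, V1={init.V1}, V2={init.V2}, "
            f"Q_UF={phase.Q_UF} L/h): {sol.message}"
        )

    tau = sol.t - init.t
    vtot_t = vtot0 - quf * tau
    c1 = np.clip(sol.y[0], 0.0, None)
    c2 = np.clip(sol.y[1], 0.0, None)
    removal = np.maximum.accumulate(np.clip(sol.y[2], 0.0, None))
    return Trajectory(
        time_grid=sol.t,
        C1=c1,
        C2=c2,
        V1=f1 * vtot_t,
        V2=(1.0 - f1) * vtot_t,
        cumulative_removal=removal,
        auc1=float(sol.y[3, -1]),
    )


def simulate_single_pool(
    kin: SoluteKinetics,
    phase: PhaseSpec,
    init: CompartmentState,
    *,
    grid_minutes: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """One-pool comparison model: a single well-mixed volume ``V1 + V2``.

    The intercompartment term drops out; the mass balance is
    ``d(V*C)/dt = G - K*C`` with ``dV/dt = -Q_UF``.  The returned trajectory
    stores the whole volume in ``V1`` (``V2 = 0``, ``C2 = C1``) so that the
    mass-balance audit and removal bookkeeping carry over unchanged.
    """
    v0 = init.V1 + init.V2
    c0 = (init.V1 * init.C1 + init.V2 * init.C2) / v0
    one_pool_init = CompartmentState(t=init.t, V1=v0, V2=0.0, C1=c0, C2=c0)
    traj = simulate_phase(
        kin,
        phase,
        one_pool_init,
        grid_minutes=grid_minutes,
        rtol=rtol,
        atol=atol,
        method=method,
        t_eval=t_eval,
    )
    traj.C2 = traj.C1.copy()
    return traj
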