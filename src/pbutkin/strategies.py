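"""Weekly dialysis strategy catalogue and steady-state simulation.

Seven weekly timeframes are compared, spanning two weekly processed-blood
volumes (216 L and 432 L) across combinations of session count (3 or 6),
session length (2-8 h) and blood flow (150 or 300 mL/min):

    3x4h_300/w (reference), 3x8h_150/w, 6x2h_300/w, 6x4h_150/w,
    3x8h_300/w, 6x4h_300/w, 6x8h_150/w

For each solute the calibrated two-compartment model is run week after week,
alternating dialysis and interdialytic phases, until like-positioned
predialysis concentrations change by less than 1% between consecutive weeks.
Strategies are scored by total solute removal over the first session(s) of
the new strategy (TSR), the steady-state weekly time-averaged plasmatic
concentration (TAC1), and the steady-state predialysis concentration
(C1_pre).

Conventions (the calibration study does not pin them):

* thrice-weekly sessions fall on days 1/3/5, six-times-weekly on days 1-6;
  the "midweek" session used for reporting is the one preceded by the
  schedule's regular short gap (session index ``sessions_per_week // 2``);
* weekly fluid removal is fixed (default 4.92 L) and split evenly over the
  sessions; each interdialytic gap linearly regains exactly the next
  session's ultrafiltrate, so volumes are periodic and every session starts
  at the predialysis volumes;
* solute generation is constant throughout the week.

At 150 mL/min blood flow, clearances measured at 300 mL/min are rescaled via
the extraction ratio: ``ER = K/300`` is multiplied by 1.33 for urea and 1.00
for protein-bound solutes (capped at 1) and applied to the lower flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NonConvergenceError
from .kinetics import (
    CompartmentState,
    PhaseSpec,
    SoluteKinetics,
    Trajectory,
    simulate_phase,
)

__all__ = [
    "WeeklyStrategy",
    "SteadyStateResult",
    "AdequacyReport",
    "build_strategy_catalogue",
    "effective_clearance",
    "weekly_phases",
    "run_to_steady_state",
    "first_session_TSR",
    "compare_strategies",
    "WEEK_MINUTES",
    "DEFAULT_WEEKLY_UF_L",
]

logger = logging.getLogger(__name__)

WEEK_MINUTES = 7 * 24 * 60  # 10080
DAY_MINUTES = 24 * 60

#: Measured weekly fluid removal of the calibration study (0.41 L/h x 4 h x 3).
DEFAULT_WEEKLY_UF_L = 4.92

#: Extraction-ratio proportionality factors when halving blood flow to 150.
ER_SCALE_UREA_150 = 1.33
ER_SCALE_PBS_150 = 1.00


@dataclass(frozen=True)
class WeeklyStrategy:
    """One weekly dialysis timeframe."""

    name: str
    sessions_per_week: int
    session_minutes: float
    Q_B: float  # mL/min
    Q_D: float  # mL/min
    weekly_processed_blood: float  # L
    ER_scale_urea: float = 1.0
    ER_scale_pbs: float = 1.0
    session_days: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bv = self.sessions_per_week * self.session_minutes * self.Q_B / 1000.0
        if abs(bv - self.weekly_processed_blood) > 1e-6 * max(bv, 1.0):
            raise ValueError(
                f"{self.name}: sessions x minutes x Q_B/1000 = {bv} L does not "
                f"match weekly processed blood {self.weekly_processed_blood} L"
            )
        if self.ER_scale_urea <= 0 or self.ER_scale_pbs <= 0:
            raise ValueError("ER scale factors must be > 0")
        if len(self.session_days) != self.sessions_per_week:
            raise ValueError("session_days must list one day per session")

    @property
    def midweek_index(self) -> int:
        """Index of the session preceded by the regular short gap."""
        return self.sessions_per_week // 2

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sessions_per_week": self.sessions_per_week,
            "session_minutes": self.session_minutes,
            "Q_B": self.Q_B,
            "Q_D": self.Q_D,
            "weekly_processed_blood": self.weekly_processed_blood,
            "ER_scale_urea": self.ER_scale_urea,
            "ER_scale_pbs": self.ER_scale_pbs,
            "session_days": list(self.session_days),
        }


def build_strategy_catalogue() -> list[WeeklyStrategy]:
    """The seven weekly timeframes of the strategy comparison."""
    thrice = (1, 3, 5)
    six = (1, 2, 3, 4, 5, 6)

    def s(name, n, minutes, qb, bv, days):
        if qb == 150:
            scales = {"ER_scale_urea": ER_SCALE_UREA_150, "ER_scale_pbs": ER_SCALE_PBS_150}
        else:
            scales = {}
        return WeeklyStrategy(
            name=name,
            sessions_per_week=n,
            session_minutes=minutes,
            Q_B=qb,
            Q_D=700.0,
            weekly_processed_blood=bv,
            session_days=days,
            **scales,
        )

    return [
        s("3x4h_300/w", 3, 240.0, 300.0, 216.0, thrice),
        s("3x8h_150/w", 3, 480.0, 150.0, 216.0, thrice),
        s("6x2h_300/w", 6, 120.0, 300.0, 216.0, six),
        s("6x4h_150/w", 6, 240.0, 150.0, 216.0, six),
        s("3x8h_300/w", 3, 480.0, 300.0, 432.0, thrice),
        s("6x4h_300/w", 6, 240.0, 300.0, 432.0, six),
        s("6x8h_150/w", 6, 480.0, 150.0, 432.0, six),
    ]


def effective_clearance(K_300: float, strategy: WeeklyStrategy, solute_class: str) -> float:
    """Dialyzer clearance at the strategy's blood flow, mL/min.

    ``K_300`` is the clearance measured at 300 mL/min.  At the same flow it
    is reused unchanged; at lower flow the extraction ratio ``K_300/300`` is
    rescaled by the class-specific proportionality factor, capped at 1, and
    applied to the new flow.
    """
    if solute_class not in ("urea", "pbs"):
        raise ValueError(f"solute_class must be 'urea' or 'pbs', got {solute_class!r}")
    if strategy.Q_B == 300.0:
        return K_300
    er = K_300 / 300.0
    scale = strategy.ER_scale_urea if solute_class == "urea" else strategy.ER_scale_pbs
    er_eff = er * scale
    if er_eff > 1.0:
        logger.warning(
            "extraction ratio %.3f > 1 for %s at Q_B=%s; capped at 1",
            er_eff,
            strategy.name,
            strategy.Q_B,
        )
        er_eff = 1.0
    return er_eff * strategy.Q_B


def solute_class_of(kin: SoluteKinetics) -> str:
    return "urea" if kin.solute_id.lower() == "urea" else "pbs"


def weekly_phases(
    strategy: WeeklyStrategy,
    K_effective: float,
    G: float,
    weekly_uf_l: float = DEFAULT_WEEKLY_UF_L,
) -> list[PhaseSpec]:
    """Alternating dialysis/interdialytic phases covering one week.

    The week starts immediately before the first session of the day pattern.
    Each interdialytic gap regains the next session's ultrafiltrate at a
    constant rate (negative ultrafiltration).
    """
    n = strategy.sessions_per_week
    uf_per_session = weekly_uf_l / n  # L
    quf_dialysis = uf_per_session / (strategy.session_minutes / 60.0)  # L/h
    days = strategy.session_days
    phases: list[PhaseSpec] = []
    for i in range(n):
        phases.append(
            PhaseSpec.dialysis(strategy.session_minutes, K_effective, quf_dialysis, G)
        )
        next_day = days[(i + 1) % n] + (7 if i == n - 1 else 0)
        gap = (next_day - days[i]) * DAY_MINUTES - strategy.session_minutes
        if gap <= 0:
            raise ValueError(f"{strategy.name}: session days leave no interdialytic gap")
        phases.append(
            PhaseSpec.interdialytic(gap, -uf_per_session / (gap / 60.0), G)
        )
    return phases


@dataclass
class SteadyStateResult:
    """Converged weekly simulation of one solute under one strategy."""

    solute_id: str
    strategy: str
    C1_pre: float  # steady-state midweek predialysis concentration, mg/L
    TAC1: float  # weekly time-averaged plasmatic concentration, mg/L
    convergence_weeks: int
    converged: bool
    session_removals: list[float] = field(default_factory=list)  # mg per session
    weekly_removal: float = 0.0  # mg over the converged week
    weekly_min_C1: float = 0.0
    weekly_max_C1: float = 0.0
    predialysis_states: list[tuple[float, float]] = field(default_factory=list)
    #: (C1, C2) immediately before the midweek session, mg/L
    midweek_state: tuple[float, float] = (0.0, 0.0)

    @property
    def midweek_removal(self) -> float:
        i = len(self.session_removals) // 2
        return self.session_removals[i]


def _simulate_week(
    kin_eff: SoluteKinetics,
    phases: Sequence[PhaseSpec],
    c1: float,
    c2: float,
    *,
    grid_minutes: float,
    rtol: float,
    atol: float,
) -> dict:
    """One week from predialysis state (c1, c2); volumes start at (V1_0, V2_0)."""
    state = CompartmentState(t=0.0, V1=kin_eff.V1_0, V2=kin_eff.V2_0, C1=c1, C2=c2)
    pres: list[tuple[float, float]] = []
    removals: list[float] = []
    auc = 0.0
    weekly_removal = 0.0
    cmin, cmax = np.inf, -np.inf
    for phase in phases:
        if phase.phase_kind == "dialysis":
            pres.append((state.C1, state.C2))
        traj = simulate_phase(
            kin_eff, phase, state, grid_minutes=grid_minutes, rtol=rtol, atol=atol
        )
        if phase.phase_kind == "dialysis":
            removals.append(traj.removal)
        weekly_removal += traj.removal
        auc += traj.auc1
        cmin = min(cmin, float(traj.C1.min()))
        cmax = max(cmax, float(traj.C1.max()))
        state = traj.final_state
    return {
        "pres": pres,
        "removals": removals,
        "auc": auc,
        "weekly_removal": weekly_removal,
        "cmin": cmin,
        "cmax": cmax,
        "final": (state.C1, state.C2),
    }


def run_to_steady_state(
    kin: SoluteKinetics,
    strategy: WeeklyStrategy,
    init_C: float | tuple[float, float],
    *,
    weekly_uf_l: float = DEFAULT_WEEKLY_UF_L,
    tol: float = 0.01,
    max_weeks: int = 200,
    grid_minutes: float = 10.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SteadyStateResult:
    """Iterate weekly cycles until predialysis concentrations settle.

    ``init_C`` is either a single predialysis concentration (both pools
    equilibrated, used when bootstrapping the reference strategy from the
    measured value) or a ``(C1, C2)`` pair (when chaining from another
    strategy's steady state).  Convergence requires the relative change of
    the predialysis concentration of every like-positioned session between
    consecutive weeks to fall below ``tol``.

    Raises :class:`NonConvergenceError` after ``max_weeks`` weeks.
    """
    k_eff = effective_clearance(kin.K, strategy, solute_class_of(kin))
    kin_eff = kin.with_clearance(k_eff)
    phases = weekly_phases(strategy, k_eff, kin.G, weekly_uf_l)
    if isinstance(init_C, tuple):
        c1, c2 = init_C
    else:
        c1 = c2 = float(init_C)

    prev_pre: np.ndarray | None = None
    for week in range(1, max_weeks + 1):
        stats = _simulate_week(
            kin_eff, phases, c1, c2, grid_minutes=grid_minutes, rtol=rtol, atol=atol
        )
        pre = np.array([p[0] for p in stats["pres"]])
        if prev_pre is not None and np.all(
            np.abs(pre - prev_pre) / np.maximum(prev_pre, 1e-12) < tol
        ):
            mid = strategy.midweek_index
            return SteadyStateResult(
                solute_id=kin.solute_id,
                strategy=strategy.name,
                C1_pre=float(pre[mid]),
                TAC1=stats["auc"] / WEEK_MINUTES,
                convergence_weeks=week,
                converged=True,
                session_removals=stats["removals"],
                weekly_removal=stats["weekly_removal"],
                weekly_min_C1=stats["cmin"],
                weekly_max_C1=stats["cmax"],
                predialysis_states=stats["pres"],
                midweek_state=stats["pres"][mid],
            )
        prev_pre = pre
        c1, c2 = stats["final"]
    raise NonConvergenceError(
        f"{kin.solute_id} under {strategy.name}: no steady state within {max_weeks} weeks"
    )


def first_session_TSR(
    kin: SoluteKinetics,
    strategy: WeeklyStrategy,
    reference_steady_state: float | tuple[float, float],
    *,
    weekly_uf_l: float = DEFAULT_WEEKLY_UF_L,
    grid_minutes: float = 10.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Removal (mg) over the first session(s) of a newly adopted strategy.

    Starting from the reference strategy's steady-state predialysis
    concentrations, the first session of the new strategy is simulated (for
    six-times-weekly strategies, the first two sessions including the gap
    between them) and the dialyzer removal flux integrated.
    """
    k_eff = effective_clearance(kin.K, strategy, solute_class_of(kin))
    kin_eff = kin.with_clearance(k_eff)
    phases = weekly_phases(strategy, k_eff, kin.G, weekly_uf_l)
    if isinstance(reference_steady_state, tuple):
        c1, c2 = reference_steady_state
    else:
        c1 = c2 = float(reference_steady_state)
    state = CompartmentState(t=0.0, V1=kin.V1_0, V2=kin.V2_0, C1=c1, C2=c2)
    n_sessions = 2 if strategy.sessions_per_week >= 6 else 1
    total = 0.0
    counted = 0
    for phase in phases:
        traj = simulate_phase(
            kin_eff, phase, state, grid_minutes=grid_minutes, rtol=rtol, atol=atol
        )
        state = traj.final_state
        if phase.phase_kind == "dialysis":
            total += traj.removal
            counted += 1
            if counted == n_sessions:
                break
    return total


@dataclass
class AdequacyReport:
    """Tidy per-solute, per-strategy adequacy table.

    Columns: solute, strategy, TSR_mg, TAC1_mg_per_L, C1_pre_mg_per_L,
    weekly_removal_mg, convergence_weeks, converged.
    """

    table: pd.DataFrame

    METRICS = ("TSR_mg", "TAC1_mg_per_L", "C1_pre_mg_per_L")

    def to_wide(self, metric: str) -> pd.DataFrame:
        """Strategy-by-solute matrix of one metric."""
        if metric not in self.table.columns:
            raise KeyError(f"unknown metric {metric!r}")
        return self.table.pivot(index="strategy", columns="solute", values=metric)

    def cell(self, solute: str, strategy: str) -> pd.Series:
        sel = self.table[(self.table["solute"] == solute) & (self.table["strategy"] == strategy)]
        if sel.empty:
            raise KeyError(f"no cell for ({solute}, {strategy})")
        return sel.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "AdequacyReport":
        return cls(pd.read_csv(path))


def compare_strategies(
    kin_set: dict[str, SoluteKinetics] | Iterable[SoluteKinetics],
    catalogue: Sequence[WeeklyStrategy] | None = None,
    c_pre: dict[str, float] | None = None,
    *,
    weekly_uf_l: float = DEFAULT_WEEKLY_UF_L,
    tol: float = 0.01,
    max_weeks: int = 200,
    grid_minutes: float = 10.0,
) -> AdequacyReport:
    """Full adequacy comparison: every solute under every strategy.

    For each solute the reference strategy (first catalogue entry) is first
    run to steady state from the measured predialysis concentration; all
    strategies are then scored starting from that reference steady state.
    Non-convergence in one cell is recorded (``converged = False``) without
    aborting the remaining cells.
    """
    if catalogue is None:
        catalogue = build_strategy_catalogue()
    if not isinstance(kin_set, dict):
        kin_set = {k.solute_id: k for k in kin_set}
    if c_pre is None:
        from .study import reference_c_pre

        c_pre = {s: reference_c_pre(s) for s in kin_set}

    rows = []
    for solute, kin in kin_set.items():
        ref = run_to_steady_state(
            kin,
            catalogue[0],
            c_pre[solute],
            weekly_uf_l=weekly_uf_l,
            tol=tol,
            max_weeks=max_weeks,
            grid_minutes=grid_minutes,
        )
        for strategy in catalogue:
            row = {"solute": solute, "strategy": strategy.name}
            try:
                tsr = first_session_TSR(
                    kin,
                    strategy,
                    ref.midweek_state,
                    weekly_uf_l=weekly_uf_l,
                    grid_minutes=grid_minutes,
                )
                if strategy.name == catalogue[0].name:
                    res = ref
                else:
                    res = run_to_steady_state(
                        kin,
                        strategy,
                        ref.midweek_state,
                        weekly_uf_l=weekly_uf_l,
                        tol=tol,
                        max_weeks=max_weeks,
                        grid_minutes=grid_minutes,
                    )
                row.update(
                    TSR_mg=tsr,
                    TAC1_mg_per_L=res.TAC1,
                    C1_pre_mg_per_L=res.C1_pre,
                    weekly_removal_mg=res.weekly_removal,
                    convergence_weeks=res.convergence_weeks,
                    converged=res.converged,
                )
            except NonConvergenceError as exc:
                logger.warning("cell (%s, %s) did not converge: %s", solute, strategy.name, exc)
                row.update(
                    TSR_mg=np.nan,
                    TAC1_mg_per_L=np.nan,
                    C1_pre_mg_per_L=np.nan,
                    weekly_removal_mg=np.nan,
                    convergence_weeks=max_weeks,
                    converged=False,
                )
            rows.append(row)
    return AdequacyReport(pd.DataFrame(rows))
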