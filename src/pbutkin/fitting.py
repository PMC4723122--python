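"""Calibration of the kinetic model to intradialytic plasma concentrations.

Given the session-constant dialyzer clearance ``K``, the generation rate
``G`` and the ultrafiltration rate, the three remaining parameters —
plasmatic volume ``V1``, total distribution volume ``Vtot`` and
intercompartment clearance ``K21`` — are estimated by bound-constrained
least squares on the relative discrepancy between simulated and measured
plasmatic concentrations.  Relative residuals make the fit invariant to the
concentration unit, so solutes on a g/L scale and on a mg/L scale behave
identically.

The estimators follow the scikit-learn protocol: ``fit(X, y)`` with ``X``
the sample times (minutes, column vector or 1-d) and ``y`` the
hemoconcentration-corrected inlet concentrations; fitted parameters carry a
trailing underscore.  The K21 likelihood is shallow for strongly bound
solutes (low ``K``), so the optimiser is restarted from a Latin-hypercube of
initial points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import MissingDataError, UnderdeterminedError
from .kinetics import (
    CompartmentState,
    PhaseSpec,
    SoluteKinetics,
    simulate_phase,
    simulate_single_pool,
)
from .samples import SampleSheet

__all__ = [
    "FitSpec",
    "FitResult",
    "TwoCompartmentModel",
    "SinglePoolModel",
    "fit_kinetics",
    "fit_single_pool",
    "DEFAULT_SAMPLE_TIMES",
]

DEFAULT_SAMPLE_TIMES = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)


@dataclass(frozen=True)
class FitSpec:
    """Fixed inputs, bounds and optimiser settings for one calibration.

    ``v1_floor`` is the anthropometric plasma-volume lower bound (L);
    the postdialysis sample is treated as an inlet sample at the session end.
    """

    K: float  # mL/min, session-constant dialyzer clearance
    G: float  # mg/min
    Q_UF: float  # L/h
    c_pre: Optional[float] = None  # mg/L; default: the t=0 sample
    duration: float = 240.0  # min
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    v1_floor: float = 0.5  # L
    vtot_max: float = 60.0  # L
    k21_max: float = 2000.0  # mL/min
    n_starts: int = 8
    seed: int = 0
    generation_during_session: bool = True
    solute_id: str = "solute"

    def __post_init__(self) -> None:
        if len(set(self.sample_times)) < 4:
            raise ValueError("need at least 4 distinct sample times")
        if not 0 < self.v1_floor < self.vtot_max:
            raise ValueError("bounds are degenerate: need 0 < v1_floor < vtot_max")
        if self.k21_max <= 0:
            raise ValueError("k21_max must be > 0")


@dataclass
class FitResult:
    """Outcome of one calibration."""

    kin: SoluteKinetics
    residual_norm: float
    convergence_flag: bool
    n_restarts_used: int
    v1_at_floor: bool = False
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    sample_times: np.ndarray = field(default_factory=lambda: np.array([]))


class _KineticEstimatorBase(BaseEstimator, RegressorMixin):
    """Shared fit machinery; subclasses define the free parameters."""

    def __init__(
        self,
        K=27.0,
        G=0.0,
        Q_UF=0.41,
        c_pre=None,
        duration=240.0,
        v1_floor=0.5,
        vtot_max=60.0,
        k21_max=2000.0,
        n_starts=8,
        random_state=0,
        generation_during_session=True,
        solute_id="solute",
        rtol=1e-8,
        atol=1e-10,
    ):
        self.K = K
        self.G = G
        self.Q_UF = Q_UF
        self.c_pre = c_pre
        self.duration = duration
        self.v1_floor = v1_floor
        self.vtot_max = vtot_max
        self.k21_max = k21_max
        self.n_starts = n_starts
        self.random_state = random_state
        self.generation_during_session = generation_during_session
        self.solute_id = solute_id
        self.rtol = rtol
        self.atol = atol

    # -- helpers ----------------------------------------------------------
    def _validate(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have the same number of samples")
        order = np.argsort(t)
        t, y = t[order], y[order]
        n_free = len(self._bounds()[0])
        if len(np.unique(t)) < n_free + 1:
            raise UnderdeterminedError(
                f"{len(np.unique(t))} distinct sample times cannot determine "
                f"{n_free} kinetic parameters"
            )
        if np.any(y <= 0):
            raise ValueError("concentrations must be positive for a relative-residual fit")
        c_pre = self.c_pre
        if c_pre is None:
            if t[0] > 1e-9:
                raise MissingDataError(
                    "no t=0 sample and no explicit predialysis concentration"
                )
            c_pre = float(y[0])
        return t, y, float(c_pre)

    def _phase(self):
        g = self.G if self.generation_during_session else 0.0
        return PhaseSpec.dialysis(self.duration, self.K, self.Q_UF, g)

    def _predict_c1(self, theta, t, c_pre):
        kin = self._kin_from_theta(theta)
        init = CompartmentState(t=0.0, V1=kin.V1_0, V2=kin.V2_0, C1=c_pre, C2=c_pre)
        sim = simulate_single_pool if self._single_pool else simulate_phase
        traj = sim(
            kin,
            self._phase(),
            init,
            rtol=self.rtol,
            atol=self.atol,
            t_eval=t,
        )
        return traj.interp_C1(t)

    def _residuals(self, theta, t, y, c_pre):
        pred = self._predict_c1(theta, t, c_pre)
        res = pred / y - 1.0
        pen = self._penalty(theta)
        return np.concatenate([res, pen]) if pen.size else res

    def _penalty(self, theta):
        return np.array([])

    def fit(self, X, y):
        t, y, c_pre = self._validate(X, y)
        lo, hi = self._bounds()
        starts = self._starts(lo, hi)
        best = None
        n_used = 0
        for x0 in starts:
            n_used += 1
            sol = least_squares(
                self._residuals,
                x0,
                bounds=(lo, hi),
                args=(t, y, c_pre),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
            )
            if best is None or sol.cost < best.cost - 1e-14:
                best = sol
        self.n_restarts_used_ = n_used
        self.converged_ = bool(best.success)
        self.residual_norm_ = float(np.linalg.norm(best.fun[: len(t)]))
        self.residuals_ = best.fun[: len(t)].copy()
        self.sample_times_ = t
        self.c_pre_ = c_pre
        self._unpack(best.x)
        self.kinetics_ = self._kin_from_theta(best.x)
        self.result_ = FitResult(
            kin=self.kinetics_,
            residual_norm=self.residual_norm_,
            convergence_flag=self.converged_,
            n_restarts_used=self.n_restarts_used_,
            v1_at_floor=getattr(self, "v1_at_floor_", False),
            residuals=self.residuals_,
            sample_times=t,
        )
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self._predict_c1(self._theta_fitted(), t, self.c_pre_)

    def _starts(self, lo, hi):
        n_extra = max(self.n_starts - 1, 0)
        starts = [self._nominal_start(lo, hi)]
        if n_extra:
            sampler = qmc.LatinHypercube(d=len(lo), seed=self.random_state)
            u = sampler.random(n_extra)
            starts.extend(lo + u * (np.asarray(hi) - np.asarray(lo)))
        return starts


class TwoCompartmentModel(_KineticEstimatorBase):
    """Two-pool estimator: free parameters (V1, V2, K21).

    ``V1`` is bounded below by the anthropometric plasma-volume floor and the
    total volume above by ``vtot_max`` (enforced through a smooth penalty on
    ``V1 + V2``).  Fitted attributes: ``V1_``, ``V2_``, ``Vtot_``, ``K21_``,
    ``kinetics_``, ``residual_norm_``, ``converged_``, ``n_restarts_used_``,
    ``v1_at_floor_``, ``result_``.
    """

    _single_pool = False

    def _bounds(self):
        lo = np.array([self.v1_floor, 0.2, 0.0])
        hi = np.array([self.vtot_max - 0.2, self.vtot_max, self.k21_max])
        return lo, hi

    def _nominal_start(self, lo, hi):
        return np.array(
            [
                np.clip(8.0, lo[0], hi[0]),
                np.clip(15.0, lo[1], hi[1]),
                np.clip(200.0, lo[2], hi[2]),
            ]
        )

    def _penalty(self, theta):
        excess = max(theta[0] + theta[1] - self.vtot_max, 0.0)
        return np.array([10.0 * excess])

    def _kin_from_theta(self, theta):
        v1, v2, k21 = theta
        return SoluteKinetics(
            solute_id=self.solute_id,
            K=self.K,
            K21=k21,
            V1_0=v1,
            Vtot_0=v1 + v2,
            G=self.G,
        )

    def _unpack(self, theta):
        self.V1_, self.V2_, self.K21_ = map(float, theta)
        self.Vtot_ = self.V1_ + self.V2_
        self.v1_at_floor_ = bool(self.V1_ <= self.v1_floor * (1 + 1e-6))

    def _theta_fitted(self):
        return np.array([self.V1_, self.V2_, self.K21_])


class SinglePoolModel(_KineticEstimatorBase):
    """One-pool comparison estimator: single free parameter ``Vtot``."""

    _single_pool = True

    def _bounds(self):
        return np.array([1.0]), np.array([self.vtot_max])

    def _nominal_start(self, lo, hi):
        return np.array([np.clip(30.0, lo[0], hi[0])])

    def _kin_from_theta(self, theta):
        vtot = float(theta[0])
        # V1/V2 split is irrelevant for the one-pool simulation; K21 unused.
        return SoluteKinetics(
            solute_id=self.solute_id,
            K=self.K,
            K21=0.0,
            V1_0=vtot / 2.0,
            Vtot_0=vtot,
            G=self.G,
        )

    def _unpack(self, theta):
        self.Vtot_ = float(theta[0])
        self.v1_at_floor_ = False

    def _theta_fitted(self):
        return np.array([self.Vtot_])


def _series_from_sheet(sheet: SampleSheet, spec: FitSpec):
    solute = spec.solute_id if spec.solute_id in sheet.solutes else None
    if solute is None:
        solutes = sheet.solutes
        if len(solutes) != 1:
            raise ValueError(
                f"sheet holds solutes {solutes}; set FitSpec.solute_id to one of them"
            )
        solute = solutes[0]
    correct = solute.lower() != "urea"
    t, c = sheet.inlet_series(solute, correct_hemoconcentration=correct)
    want = np.asarray(spec.sample_times, dtype=float)
    sel = np.isin(t, want)
    missing = sorted(set(want) - set(t))
    if missing:
        raise MissingDataError(f"inlet samples missing at t={missing} for {solute!r}")
    return t[sel], c[sel], solute


def _make_estimator(cls, spec: FitSpec, solute: str):
    return cls(
        K=spec.K,
        G=spec.G,
        Q_UF=spec.Q_UF,
        c_pre=spec.c_pre,
        duration=spec.duration,
        v1_floor=spec.v1_floor,
        vtot_max=spec.vtot_max,
        k21_max=spec.k21_max,
        n_starts=spec.n_starts,
        random_state=spec.seed,
        generation_during_session=spec.generation_during_session,
        solute_id=solute,
    )


def fit_kinetics(sheet: SampleSheet, spec: FitSpec) -> FitResult:
    """Calibrate (V1, Vtot, K21) for one solute from a sample sheet.

    Inlet concentrations at the spec's sample times are used; protein-bound
    solutes are hemoconcentration-corrected first.  Deterministic given
    ``spec.seed`` (multi-start initialisation).
    """
    t, c, solute = _series_from_sheet(sheet, spec)
    est = _make_estimator(TwoCompartmentModel, spec, solute).fit(t, c)
    return est.result_


def fit_single_pool(sheet: SampleSheet, spec: FitSpec) -> FitResult:
    """One-pool analogue of :func:`fit_kinetics` (free parameter: Vtot)."""
    t, c, solute = _series_from_sheet(sheet, spec)
    est = _make_estimator(SinglePoolModel, spec, solute).fit(t, c)
    return est.result_
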