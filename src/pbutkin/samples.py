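"""Sample-sheet container and CSV I/O.

A sample sheet holds the measured concentrations of one or more dialysis
sessions: inlet plasma samples over the session, paired outlet samples,
spot dialysate samples, and the full-session dialysate collection.  On disk
it is a CSV with columns

    patient_id, solute, time_min, site, conc_total, conc_free, total_protein, units

where ``site`` is one of ``inlet``, ``outlet``, ``dialysate``,
``dialysate_total`` and ``units`` comes from a controlled vocabulary
(mg/L, mg/dL, g/L, g/dL; ``mg`` for the collected-mass row).  In memory all
concentrations are canonical mg/L and the collected mass is mg.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import MissingDataError, SchemaError
from .units import CONCENTRATION_UNITS, to_mg_per_l

__all__ = ["SamplePoint", "SampleSheet", "SessionPrescription", "SITES"]

SITES = ("inlet", "outlet", "dialysate", "dialysate_total")

_COLUMNS = [
    "patient_id",
    "solute",
    "time_min",
    "site",
    "conc_total",
    "conc_free",
    "total_protein",
    "units",
]


@dataclass(frozen=True)
class SessionPrescription:
    """Operating point of one dialysis session."""

    Q_B: float = 300.0  # blood flow, mL/min
    Q_D: float = 700.0  # dialysate flow, mL/min
    Q_UF: float = 0.41  # ultrafiltration rate, L/h
    duration: float = 240.0  # min

    @property
    def quf_ml_per_min(self) -> float:
        return self.Q_UF * 1000.0 / 60.0

    @property
    def uf_volume_l(self) -> float:
        return self.Q_UF * self.duration / 60.0


@dataclass(frozen=True)
class SamplePoint:
    """One measured sample (canonical units)."""

    patient_id: str
    solute_id: str
    t: float
    site: str
    C_total: float
    C_free: Optional[float] = None
    TP: Optional[float] = None  # total protein, g/L

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise SchemaError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.t < 0:
            raise SchemaError(f"time must be >= 0, got {self.t}")
        if self.C_free is not None and self.C_free > self.C_total + 1e-12:
            raise SchemaError(
                f"free concentration {self.C_free} exceeds total {self.C_total}"
            )


class SampleSheet:
    """Measured concentrations by site and time, one row per sample."""

    def __init__(self, points: Iterable[SamplePoint]):
        self.points = list(points)
        self._df = pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.points],
                "solute": [p.solute_id for p in self.points],
                "time_min": [p.t for p in self.points],
                "site": [p.site for p in self.points],
                "conc_total": [p.C_total for p in self.points],
                "conc_free": [np.nan if p.C_free is None else p.C_free for p in self.points],
                "total_protein": [np.nan if p.TP is None else p.TP for p in self.points],
            }
        )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        """Build from a raw CSV frame, converting units to mg/L.

        Raises :class:`SchemaError` naming the first offending row.
        """
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"sample sheet is missing columns {missing}")
        points = []
        for i, row in df.iterrows():
            site = str(row["site"])
            unit = str(row["units"])
            try:
                if site == "dialysate_total":
                    if unit != "mg":
                        raise SchemaError(
                            "dialysate_total rows carry collected mass in 'mg'"
                        )
                    c_tot = float(row["conc_total"])
                    c_free = None
                elif unit in CONCENTRATION_UNITS:
                    c_tot = to_mg_per_l(float(row["conc_total"]), unit)
                    c_free = (
                        None
                        if pd.isna(row["conc_free"])
                        else to_mg_per_l(float(row["conc_free"]), unit)
                    )
                else:
                    raise SchemaError(
                        f"unknown unit {unit!r}; expected one of "
                        f"{sorted(CONCENTRATION_UNITS) + ['mg']}"
                    )
                tp = None if pd.isna(row["total_protein"]) else float(row["total_protein"])
                points.append(
                    SamplePoint(
                        patient_id=str(row["patient_id"]),
                        solute_id=str(row["solute"]),
                        t=float(row["time_min"]),
                        site=site,
                        C_total=c_tot,
                        C_free=c_free,
                        TP=tp,
                    )
                )
            except SchemaError as exc:
                raise SchemaError(f"row {i}: {exc}") from None
        return cls(points)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSheet":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        """Write canonical-unit CSV (mg/L concentrations, mg collected mass)."""
        df = self._df.copy()
        df["units"] = np.where(df["site"] == "dialysate_total", "mg", "mg/L")
        df[_COLUMNS].to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    # -- selection --------------------------------------------------------
    @property
    def patients(self) -> list[str]:
        return sorted(self._df["patient_id"].unique())

    @property
    def solutes(self) -> list[str]:
        return sorted(self._df["solute"].unique())

    def select(self, patient_id: str | None = None, solute_id: str | None = None) -> "SampleSheet":
        pts = [
            p
            for p in self.points
            if (patient_id is None or p.patient_id == patient_id)
            and (solute_id is None or p.solute_id == solute_id)
        ]
        return SampleSheet(pts)

    def _one(self, site: str, t: float, solute_id: str | None = None) -> SamplePoint:
        cand = [
            p
            for p in self.points
            if p.site == site
            and abs(p.t - t) < 1e-9
            and (solute_id is None or p.solute_id == solute_id)
        ]
        if not cand:
            raise MissingDataError(
                f"no {site} sample at t={t} min"
                + (f" for solute {solute_id!r}" if solute_id else "")
            )
        return cand[0]

    def sample_at(self, site: str, t: float, solute_id: str | None = None) -> SamplePoint:
        return self._one(site, t, solute_id)

    def inlet_series(
        self,
        solute_id: str | None = None,
        *,
        correct_hemoconcentration: bool = False,
    ) -> tuple[np.ndarray, np.ndarray]:
        """(times, total concentrations) of the inlet samples, time-sorted.

        With ``correct_hemoconcentration`` the measured concentrations are
        rescaled by ``F = TP_pre / TP_t`` (requires a total-protein course on
        the inlet rows); this is how protein-bound solute series are prepared
        for kinetic fitting.
        """
        pts = sorted(
            (p for p in self.points if p.site == "inlet" and (solute_id is None or p.solute_id == solute_id)),
            key=lambda p: p.t,
        )
        if not pts:
            raise MissingDataError(
                f"no inlet samples{f' for solute {solute_id!r}' if solute_id else ''}"
            )
        t = np.array([p.t for p in pts])
        c = np.array([p.C_total for p in pts], dtype=float)
        if correct_hemoconcentration:
            if any(p.TP is None for p in pts):
                raise MissingDataError(
                    "hemoconcentration correction requires total protein on every inlet row"
                )
            tp = np.array([p.TP for p in pts], dtype=float)
            tp_pre = tp[np.argmin(t)]
            c = c * tp_pre / tp
        return t, c

    def dialysate_total_mass(self, solute_id: str | None = None) -> float:
        """Collected solute mass (mg) from the full-session dialysate row."""
        cand = [
            p
            for p in self.points
            if p.site == "dialysate_total"
            and (solute_id is None or p.solute_id == solute_id)
        ]
        if not cand:
            raise MissingDataError(
                "no dialysate_total row"
                + (f" for solute {solute_id!r}" if solute_id else "")
            )
        return cand[0].C_total
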