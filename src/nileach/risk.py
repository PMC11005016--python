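"""Tolerable-intake (TI) risk assessment.

The parenteral TI for nickel, 0.5 ug/kg/day, is apportioned to
compartments by the time-averaged mass fractions <y_i> = <M_i>/<M_total>,
with M_total the accounting total (baselines + dietary intake + device
release).  Compartmental rate-of-change profiles dM_i/dt — or the raw
device release rate — are then compared against the TI_i thresholds and
maximal exceedance intervals are located.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import COMPARTMENTS, ControlState, DeviceReleaseParams, Physiology
from .engine import Trajectory, total_mass
from .uncertainty import MCEnsemble

__all__ = [
    "TI_NG_PER_KG_DAY",
    "TIReport",
    "mass_fractions",
    "compartment_ti",
    "exceedance",
    "ti_report",
]

#: Parenteral tolerable intake for nickel, ng per kg body mass per day.
TI_NG_PER_KG_DAY = 500.0


def mass_fractions(source: Union[Trajectory, MCEnsemble],
                   control: ControlState, phys: Physiology,
                   d: Optional[DeviceReleaseParams]) -> pd.Series:
    """Time-averaged mass fractions <y_i> over the source's horizon.

    Averages M_i(t)/M_total(t) by the trapezoid rule on the source grid
    (for an ensemble, the per-time median masses are used) and
    renormalizes so the fractions sum to exactly 1.
    """
    if isinstance(source, MCEnsemble):
        t = source.t
        m = np.percentile(source.samples, 50, axis=0, method="linear")
    else:
        t, m = source.t, source.m
    mtot = total_mass(t, control, phys, d)
    if np.any(mtot <= 0):
        raise ValueError("degenerate zero total mass")
    y = m / mtot[:, None]
    span = t[-1] - t[0]
    if span <= 0:
        ybar = y[0]
    else:
        ybar = np.trapezoid(y, t, axis=0) / span
    ybar = np.clip(ybar, 0.0, None)
    ybar = ybar / ybar.sum()
    return pd.Series(ybar, index=list(COMPARTMENTS), name="y_mean")


def compartment_ti(y: pd.Series, body_mass: float,
                   ti_per_kg: float = TI_NG_PER_KG_DAY) -> pd.Series:
    """Compartmental TI thresholds (ng/day): TI_i = <y_i> x TI x body mass."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive (kg)")
    return (y * ti_per_kg * body_mass).rename("ti_ng_per_day")


def exceedance(t: np.ndarray, rate: np.ndarray,
               threshold: float) -> List[Tuple[float, float]]:
    """Maximal intervals (days) where ``rate`` exceeds ``threshold``.

    Crossing times between grid points are located by linear root
    bracketing on ``rate - threshold``.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(rate, dtype=float) - threshold
    if t.shape != r.shape or t.size < 2:
        raise ValueError("need matching rate/time series of length >= 2")
    above = r > 0
    intervals: List[Tuple[float, float]] = []
    start: Optional[float] = None

    def cross(i: int) -> float:
        # root of the linear interpolant on [t_i, t_{i+1}]
        return float(t[i] - r[i] * (t[i + 1] - t[i]) / (r[i + 1] - r[i]))

    if above[0]:
        start = float(t[0])
    for i in range(t.size - 1):
        if not above[i] and above[i + 1]:
            start = cross(i) if r[i] != r[i + 1] else float(t[i + 1])
        elif above[i] and not above[i + 1]:
            end = cross(i) if r[i] != r[i + 1] else float(t[i])
            intervals.append((start, end))
            start = None
    if start is not None:
        intervals.append((start, float(t[-1])))
    return intervals


@dataclass
class TIReport:
    """Compartmental tolerable-intake report.

    ``exceedance_intervals`` maps compartment names (plus the pseudo-entry
    "device_release", compared against the whole-body TI) to lists of
    (start, end) day intervals where the rate tops its threshold.
    """

    y: pd.Series
    ti: pd.Series
    body_mass: float
    horizon: Tuple[float, float]
    provenance: str
    exceedance_intervals: Dict[str, List[Tuple[float, float]]] = field(
        default_factory=dict)

    @property
    def total_ti(self) -> float:
        return float(self.ti.sum())

    def intervals_frame(self) -> pd.DataFrame:
        rows = [{"compartment": comp, "start_days": s, "end_days": e}
                for comp, ivals in self.exceedance_intervals.items()
                for s, e in ivals]
        return pd.DataFrame(rows, columns=["compartment", "start_days", "end_days"])

    def to_dict(self) -> dict:
        return {
            "body_mass_kg": self.body_mass,
            "horizon_days": list(self.horizon),
            "provenance": self.provenance,
            "total_ti_ng_per_day": self.total_ti,
            "y_mean": {c: float(v) for c, v in self.y.items()},
            "ti_ng_per_day": {c: float(v) for c, v in self.ti.items()},
            "exceedance_intervals": {
                c: [[float(s), float(e)] for s, e in iv]
                for c, iv in self.exceedance_intervals.items()},
        }


def ti_report(traj: Trajectory, control: ControlState, phys: Physiology,
              d: Optional[DeviceReleaseParams], *,
              ensemble: Optional[MCEnsemble] = None,
              ti_per_kg: float = TI_NG_PER_KG_DAY) -> TIReport:
    """Assemble the full TI analysis for one device.

    Mass fractions come from the ensemble medians when ``ensemble`` is
    given (the headline convention), else from the deterministic
    trajectory.  Compartment dM_i/dt profiles from the trajectory RHS and
    the device release rate are screened against the thresholds.
    """
    src = ensemble if ensemble is not None else traj
    y = mass_fractions(src, control, phys, d)
    ti = compartment_ti(y, phys.body_mass, ti_per_kg)
    intervals: Dict[str, List[Tuple[float, float]]] = {}
    for comp in COMPARTMENTS:
        intervals[comp] = exceedance(traj.t, traj.rate_of(comp), float(ti[comp]))
    if d is not None:
        from .core import release_rate
        whole_body = ti_per_kg * phys.body_mass
        intervals["device_release"] = exceedance(
            traj.t, release_rate(traj.t, d), whole_body)
    return TIReport(y=y, ti=ti, body_mass=phys.body_mass,
                    horizon=(float(traj.t[0]), float(traj.t[-1])),
                    provenance="ensemble-median" if ensemble is not None else "deterministic",
                    exceedance_intervals=intervals)
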