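"""Nine-compartment time-variant ODE system: assembly, integration, balance.

The state vector carries the nine compartment masses plus two bookkeeping
states (cumulative nickel excreted with urine and feces), so the global
mass balance

    sum_i M_i(T) + excreted(T) = sum_i M_i(0) + M_d(T) + k_diet * T

can be audited to solver tolerance at every output time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .core import (
    COMPARTMENTS,
    ControlState,
    DeviceReleaseParams,
    KineticRateSet,
    Physiology,
    cumulative_release,
    release_rate,
)

__all__ = [
    "IntegrationError",
    "Trajectory",
    "rhs",
    "simulate",
    "total_mass",
    "default_time_grid",
]

# state indices
_LT, _BL, _LIV, _BR, _LU, _K, _G, _U, _F = range(9)
_OUT_U, _OUT_F = 9, 10

#: Default tolerance below which a negative solver excursion is treated as
#: numerical noise rather than a rejected trajectory.
NEGATIVE_TOL_NG = 1e-9


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a solution."""


def rhs(t: float, state, k: KineticRateSet, d: Optional[DeviceReleaseParams],
        phys: Physiology):
    """Time derivative of the 9 compartment masses (ng/day).

    ``state`` may carry 9 or 11 entries; with 11 the last two are the
    cumulative urinary/fecal outflows and their derivatives are returned
    too.  ``d=None`` means no device (zero release).
    """
    state = np.asarray(state, dtype=float)
    if np.any(~np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to rhs")
    m = state[:9]
    mdot_d = float(release_rate(t, d)) if d is not None else 0.0
    f = float(k.fraction(t))
    r = k.rates_at(t)

    c_u_out = m[_U] / phys.v_u * phys.q_u   # urinary outflux, ng/day
    c_f_out = m[_F] / phys.v_f * phys.q_f   # fecal outflux, ng/day

    dm = np.empty(state.shape)
    dm[_LT] = (1.0 - f) * mdot_d + r["k_bllt"] * m[_BL] - r["k_ltbl"] * m[_LT]
    dm[_LIV] = r["k_blliv"] * m[_BL] - r["k_livbl"] * m[_LIV]
    dm[_BR] = r["k_blbr"] * m[_BL] - r["k_brbl"] * m[_BR]
    dm[_LU] = r["k_bllu"] * m[_BL] - r["k_lubl"] * m[_LU]
    dm[_K] = r["k_blk"] * m[_BL] - (r["k_kbl"] + r["k_u"]) * m[_K]
    dm[_G] = phys.k_diet + r["k_blg"] * m[_BL] - (r["k_gbl"] + r["k_f"]) * m[_G]
    dm[_BL] = (
        f * mdot_d
        + r["k_ltbl"] * m[_LT] - r["k_bllt"] * m[_BL]
        + r["k_livbl"] * m[_LIV] - r["k_blliv"] * m[_BL]
        + r["k_brbl"] * m[_BR] - r["k_blbr"] * m[_BL]
        + r["k_lubl"] * m[_LU] - r["k_bllu"] * m[_BL]
        + r["k_kbl"] * m[_K] - r["k_blk"] * m[_BL]
        + r["k_gbl"] * m[_G] - r["k_blg"] * m[_BL]
    )
    dm[_U] = r["k_u"] * m[_K] - c_u_out
    dm[_F] = r["k_f"] * m[_G] - c_f_out
    if state.size == 11:
        dm[_OUT_U] = c_u_out
        dm[_OUT_F] = c_f_out
    return dm


def _rhs_fast(t, y, A, B, C, D, fa, fb, plateau_over_tau, inv_tau, k_diet,
              inv_vu_qu, inv_vf_qf):
    """Allocation-light RHS used inside the solver loop."""
    r = A * np.exp(-((B * (t - C)) ** 2)) + D
    mdot_d = plateau_over_tau * np.exp(-t * inv_tau)
    f = fa * np.exp(-fb * t)
    m = y
    c_u_out = m[_U] * inv_vu_qu
    c_f_out = m[_F] * inv_vf_qf
    dm = np.empty(11)
    dm[_LT] = (1.0 - f) * mdot_d + r[1] * m[_BL] - r[0] * m[_LT]
    dm[_LIV] = r[3] * m[_BL] - r[2] * m[_LIV]
    dm[_BR] = r[5] * m[_BL] - r[4] * m[_BR]
    dm[_LU] = r[7] * m[_BL] - r[6] * m[_LU]
    dm[_K] = r[9] * m[_BL] - (r[8] + r[12]) * m[_K]
    dm[_G] = k_diet + r[11] * m[_BL] - (r[10] + r[13]) * m[_G]
    dm[_BL] = (
        f * mdot_d
        + r[0] * m[_LT] - r[1] * m[_BL]
        + r[2] * m[_LIV] - r[3] * m[_BL]
        + r[4] * m[_BR] - r[5] * m[_BL]
        + r[6] * m[_LU] - r[7] * m[_BL]
        + r[8] * m[_K] - r[9] * m[_BL]
        + r[10] * m[_G] - r[11] * m[_BL]
    )
    dm[_U] = r[12] * m[_K] - c_u_out
    dm[_F] = r[13] * m[_G] - c_f_out
    dm[_OUT_U] = c_u_out
    dm[_OUT_F] = c_f_out
    return dm


@dataclass
class Trajectory:
    """Solved biodistribution time course.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Output time grid (days), strictly increasing from 0.
    m : ndarray, shape (n, 9)
        Compartment masses (ng) in :data:`~nileach.core.COMPARTMENTS` order.
    cum_out : ndarray, shape (n, 2)
        Cumulative urinary and fecal nickel excreted (ng).
    dm : ndarray, shape (n, 9)
        RHS-evaluated rates of change dM_i/dt (ng/day).
    rejected : bool
        True when any compartment went below ``-NEGATIVE_TOL_NG`` anywhere
        on the output grid (the trajectory is reported, never clipped).
    """

    t: np.ndarray
    m: np.ndarray
    cum_out: np.ndarray
    dm: np.ndarray
    rejected: bool
    min_mass: float

    def compartment(self, name: str) -> np.ndarray:
        return self.m[:, COMPARTMENTS.index(name)]

    def rate_of(self, name: str) -> np.ndarray:
        return self.dm[:, COMPARTMENTS.index(name)]

    def blood_concentration(self, phys: Physiology) -> np.ndarray:
        """Blood nickel concentration (ng/mL)."""
        return self.compartment("blood") / phys.v_b

    def urine_concentration(self, phys: Physiology) -> np.ndarray:
        """Bladder urine nickel concentration (ng/mL)."""
        return self.compartment("urine") / phys.v_u

    def interp(self, name: str, times) -> np.ndarray:
        """Monotone-cubic interpolation of one compartment mass."""
        return PchipInterpolator(self.t, self.compartment(name))(np.asarray(times, float))

    def balance_residual(self, control: ControlState, phys: Physiology,
                         d: Optional[DeviceReleaseParams]) -> np.ndarray:
        """Relative mass-balance residual at every output time."""
        released = cumulative_release(self.t, d) if d is not None else 0.0
        expected = control.masses(phys).sum() + released + phys.k_diet * self.t
        actual = self.m.sum(axis=1) + self.cum_out.sum(axis=1)
        return (actual - expected) / expected


def default_time_grid(horizon: float = 126.0, n: int = 400) -> np.ndarray:
    """Output grid with log-dense early coverage of the release transient."""
    early = np.geomspace(1e-3, 1.0, 32)
    late = np.linspace(0.0, horizon, n)
    return np.unique(np.concatenate(([0.0], early, late)))


def simulate(k: KineticRateSet, d: Optional[DeviceReleaseParams],
             phys: Physiology, control: ControlState,
             grid: Optional[np.ndarray] = None, *,
             rtol: float = 1e-8, atol: float = 1e-12,
             method: str = "LSODA") -> Trajectory:
    """Integrate the PBTK system from the control state over ``grid``.

    Initial conditions are the control/baseline masses.  Negative states
    are flagged (``Trajectory.rejected``), never clipped, matching the
    Monte Carlo discard semantics.
    """
    if grid is None:
        grid = default_time_grid()
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must start at 0 and be strictly increasing")

    y0 = np.concatenate([control.masses(phys), [0.0, 0.0]])
    A, B, C, D = k.rate_arrays()
    fa, fb = k.fraction.a, k.fraction.b
    if d is not None:
        plateau_over_tau, inv_tau = d.plateau / d.tau, 1.0 / d.tau
    else:
        plateau_over_tau, inv_tau = 0.0, 0.0
    args = (A, B, C, D, fa, fb, plateau_over_tau, inv_tau, phys.k_diet,
            phys.q_u / phys.v_u, phys.q_f / phys.v_f)

    sol = solve_ivp(_rhs_fast, (grid[0], grid[-1]), y0, t_eval=grid,
                    args=args, method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")

    m = sol.y[:9].T.copy()
    cum_out = sol.y[9:].T.copy()
    dm = np.empty_like(m)
    for i, t in enumerate(sol.t):
        dm[i] = _rhs_fast(t, sol.y[:, i], *args)[:9]
    min_mass = float(m.min())
    return Trajectory(t=sol.t.copy(), m=m, cum_out=cum_out, dm=dm,
                      rejected=min_mass < -NEGATIVE_TOL_NG, min_mass=min_mass)


def total_mass(t, control: ControlState, phys: Physiology,
               d: Optional[DeviceReleaseParams]):
    """System accounting total (ng): baselines + dietary intake + device release.

    This is the denominator of the time-averaged mass fractions used in
    the tolerable-intake analysis.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    released = cumulative_release(t, d) if d is not None else np.zeros_like(t)
    return control.masses(phys).sum() + phys.k_diet * t + released
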