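"""Model calibration: release-law fits, data-confidence weights, objective.

Two stages mirror the study design.  The device-specific release
parameters (alpha, tau) come from a nonlinear least-squares fit to in
vitro immersion data.  The host-specific kinetic parameters come from a
derivative-free direct search minimizing the equal-trade-off mean of
per-compartment weighted RMSEs against in vivo biodistribution data,
with Gaussian-RBF confidence weights down-weighting observations that
violate physical plausibility bounds (below control, or above control
plus everything the device could have released).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    COMPARTMENTS,
    EXCHANGE_PAIRS,
    MEASURED_COMPARTMENTS,
    ControlState,
    DegenerateControlError,
    DeviceReleaseParams,
    FeasibilityError,
    FractionParams,
    KineticRateSet,
    Physiology,
    PulseParams,
    cumulative_release,
    initial_rate_relations,
)
from .engine import IntegrationError, Trajectory, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "ReleaseFit",
    "fit_release",
    "ObservationSet",
    "compute_weights",
    "weighted_rmse",
    "objective",
    "SteadyStateScheme",
    "FullScheme",
    "FitResult",
    "fit_device",
]

_PENALTY = 1e12


# ---------------------------------------------------------------------------
# in vitro release-parameter fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseFit:
    """Result of the immersion-data fit."""

    params: DeviceReleaseParams
    residual_norm: float
    flag: Optional[str] = None  # "degenerate_zero" | "tau_boundary" | None


def fit_release(times: Sequence[float], cumulative: Sequence[float],
                a_surf: float) -> ReleaseFit:
    """Least-squares fit of (alpha, tau) to cumulative immersion data.

    Parameters
    ----------
    times, cumulative : sequences
        Sampling days and cumulative released mass (ng).
    a_surf : float
        Device active surface area (mm²).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(cumulative, dtype=float)
    if t.size < 3 or np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct immersion time points")
    if np.any(y < 0):
        raise ValueError("cumulative release values must be nonnegative")
    if np.any(np.diff(y[np.argsort(t)]) < 0):
        warnings.warn("cumulative immersion data are not monotone; fitting anyway",
                      stacklevel=2)
    if np.all(y == 0):
        return ReleaseFit(DeviceReleaseParams(0.0, 1.0, a_surf), 0.0,
                          flag="degenerate_zero")

    def resid(p):
        alpha, tau = p
        return alpha * a_surf * (-np.expm1(-t / tau)) - y

    alpha0 = y.max() / a_surf
    tau0 = max(float(np.median(t)) / 3.0, 1e-3)
    tau_lo = 1e-6
    sol = optimize.least_squares(resid, x0=[alpha0, tau0],
                                 bounds=([0.0, tau_lo], [np.inf, np.inf]),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    alpha, tau = sol.x
    # tau below a tenth of the first sampling time is unresolvable by the
    # design: the data look like instantaneous release
    t_min = float(t[t > 0].min()) if np.any(t > 0) else 1.0
    flag = "tau_boundary" if tau <= 0.1 * t_min else None
    return ReleaseFit(DeviceReleaseParams(float(alpha), float(tau), a_surf),
                      float(np.linalg.norm(sol.fun)), flag=flag)


# ---------------------------------------------------------------------------
# observation weights
# ---------------------------------------------------------------------------

@dataclass
class ObservationSet:
    """Weighted in vivo observations, mass scale (ng).

    ``data`` columns: compartment, time_days, mass_ng, weight; the first
    record of each compartment (time 0) is the control value and always
    carries weight 1.  ``sigma`` maps (compartment, kind) with kind in
    {"control", "release"} to the fitted kernel scale for that violation
    type, when any violation occurred.
    """

    data: pd.DataFrame
    sigma: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def compartments(self) -> List[str]:
        return [c for c in COMPARTMENTS if c in set(self.data["compartment"])]

    def for_compartment(self, name: str) -> pd.DataFrame:
        return self.data[self.data["compartment"] == name]

    def control_value(self, name: str) -> float:
        sub = self.for_compartment(name).sort_values("time_days")
        return float(sub["mass_ng"].iloc[0])


def _rbf(dist: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-(np.asarray(dist, float) / sigma) ** 2)


def _common_sigma(dists: np.ndarray, targets: np.ndarray) -> float:
    """Single kernel scale for several violations in one compartment.

    Per-point scales are found by inverting the kernel at each point's
    target weight; when they disagree, a 1-D direct search (seeded at
    their mean) minimizes the squared mismatch between kernel weights and
    targets, and the common scale is used to recompute all weights.
    """
    per_point = dists / np.sqrt(-np.log(targets))
    if per_point.size == 1:
        return float(per_point[0])
    s0 = float(per_point.mean())

    def loss(log_s):
        return float(np.sum((_rbf(dists, math.exp(log_s[0])) - targets) ** 2))

    res = optimize.minimize(loss, x0=[math.log(s0)], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14})
    return float(math.exp(res.x[0]))


def compute_weights(raw: pd.DataFrame, control: ControlState, phys: Physiology,
                    d: DeviceReleaseParams,
                    sigma: Optional[Mapping[Tuple[str, str], float]] = None,
                    ) -> ObservationSet:
    """Assign Gaussian-RBF confidence weights to raw observations.

    ``raw`` needs columns compartment, time_days, mass_ng, with a control
    row at time 0 per compartment.  A point inside the plausibility band
    [control, control + M_d(t)] gets weight 1; a violating point gets
    ``exp(-(violation/σ)²)`` with σ chosen so a lone sub-control point at
    fraction q of control receives weight exactly q (and symmetrically
    for release-cap violations).  Preset scales can be passed in
    ``sigma``.
    """
    required = {"compartment", "time_days", "mass_ng"}
    if not required.issubset(raw.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    df = raw.copy().reset_index(drop=True)
    df["weight"] = 1.0
    sigmas: Dict[Tuple[str, str], float] = dict(sigma or {})

    for comp, sub in df.groupby("compartment", sort=False):
        sub = sub.sort_values("time_days")
        m_c = float(sub["mass_ng"].iloc[0])
        if float(sub["time_days"].iloc[0]) != 0.0:
            raise ValueError(f"compartment {comp!r} lacks a control row at time 0")
        rest = sub.iloc[1:]
        if rest.empty:
            continue
        t_j = rest["time_days"].to_numpy(float)
        m_j = rest["mass_ng"].to_numpy(float)
        hi = cumulative_release(t_j, d) + m_c

        low_mask = m_j < m_c
        high_mask = m_j > hi
        if np.any(low_mask) and m_c == 0.0:
            raise DegenerateControlError(
                f"sub-control observation with zero control in {comp!r}")

        for kind, mask, dist_all, target_all in (
            ("control", low_mask, m_c - m_j, np.divide(m_j, m_c if m_c else 1.0)),
            ("release", high_mask, m_j - hi, np.divide(hi, m_j,
                                                       out=np.ones_like(m_j),
                                                       where=m_j > 0)),
        ):
            if not np.any(mask):
                continue
            dists = dist_all[mask]
            targets = np.clip(target_all[mask], 1e-12, 1.0 - 1e-15)
            key = (str(comp), kind)
            if key not in sigmas:
                sigmas[key] = _common_sigma(dists, targets)
            w = _rbf(dists, sigmas[key])
            df.loc[rest.index[mask], "weight"] = w

    return ObservationSet(data=df, sigma=sigmas)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def weighted_rmse(traj: Trajectory, obs: ObservationSet, compartment: str) -> float:
    """Weighted root-mean-square deviation (ng) for one compartment.

    ``sqrt(sum_j w_j (M_model(t_j) - M_j)² / sum_j w_j)``; the weight sum
    in the denominator normalizes data counts among compartments.  The
    time-0 control row is an initial condition, not a measurement, and is
    excluded from the sum.
    """
    sub = obs.for_compartment(compartment)
    sub = sub[sub["time_days"] > 0.0]
    if sub.empty:
        raise ValueError(f"no observations for compartment {compartment!r}")
    t = sub["time_days"].to_numpy(float)
    m_obs = sub["mass_ng"].to_numpy(float)
    w = sub["weight"].to_numpy(float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError(f"all weights zero in compartment {compartment!r}")
    model = traj.interp(compartment, t)
    return float(np.sqrt(np.sum(w * (model - m_obs) ** 2) / wsum))


def objective(traj: Trajectory, obs: ObservationSet,
              compartments: Optional[Sequence[str]] = None) -> float:
    """Equal-trade-off scalar objective: mean of per-compartment RMSEs (ng)."""
    comps = list(compartments) if compartments is not None else obs.compartments()
    rmses = []
    for comp in comps:
        if obs.for_compartment(comp).empty:
            logger.info("compartment %s has no observations; excluded", comp)
            continue
        rmses.append(weighted_rmse(traj, obs, comp))
    if len(rmses) < 2:
        raise ValueError("objective needs at least 2 populated compartments")
    return float(np.mean(rmses))


# ---------------------------------------------------------------------------
# parameterization schemes
# ---------------------------------------------------------------------------

_ORGANS = tuple(EXCHANGE_PAIRS)  # local_tissue, liver, brain, lungs, kidney, gut


class SteadyStateScheme:
    """Pulse-free parameterization: 6 uptake steady rates + F(t) params.

    Free vector (named): ``k_blx.D`` for each exchange organ, plus
    ``fraction.A`` and ``fraction.B``.  Return rates and the two excretion
    rates are tied to their t = 0 fixed-point relations, so every
    candidate keeps the control state stationary before device release.
    Optimization runs in log space for the (positive) rates.
    """

    def __init__(self, control: ControlState, phys: Physiology):
        self.control = control
        self.phys = phys
        self.relations = initial_rate_relations(control, phys)
        self.names = [f"{EXCHANGE_PAIRS[o][0]}.D" for o in _ORGANS] + [
            "fraction.A", "fraction.B"]

    def default_x0(self) -> np.ndarray:
        ku_floor = (self.control.c_u * self.phys.q_u) / self.control.m_bl
        x = []
        for organ in _ORGANS:
            x.append(1.5 * ku_floor if organ == "kidney" else 0.1)
        x += [0.5, 0.01]
        return np.array(x)

    def build(self, x: np.ndarray) -> KineticRateSet:
        x = np.asarray(x, float)
        rel = self.relations
        kw: Dict[str, PulseParams] = {}
        for organ, up in zip(_ORGANS, x[:6]):
            up_name, ret_name = EXCHANGE_PAIRS[organ]
            kw[up_name] = PulseParams.steady(float(up))
            kw[ret_name] = PulseParams.steady(rel.partner0(organ, float(up)))
        kw["k_u"] = PulseParams.steady(rel.ku0)
        kw["k_f"] = PulseParams.steady(rel.kf0)
        frac = FractionParams(float(x[6]), float(x[7]))
        return KineticRateSet(fraction=frac, **kw)

    def to_opt(self, x: np.ndarray) -> np.ndarray:
        z = np.asarray(x, float).copy()
        z[:6] = np.log(z[:6])
        return z

    def from_opt(self, z: np.ndarray) -> np.ndarray:
        x = np.asarray(z, float).copy()
        x[:6] = np.exp(np.clip(x[:6], -700, 700))
        return x

    def opt_bounds(self):
        from .core import FRACTION_DECAY_MAX_PER_DAY, RATE_MAX_PER_DAY
        return ([(math.log(1e-4), math.log(RATE_MAX_PER_DAY))] * 6
                + [(0.0, 1.0), (0.0, FRACTION_DECAY_MAX_PER_DAY)])

    def default_starts(self) -> List[np.ndarray]:
        """Multi-start points spanning the blood-fraction axis, where the
        objective is prone to distinct basins."""
        starts = []
        for fa in (0.25, 0.5, 0.75):
            x = self.default_x0()
            x[6] = fa
            starts.append(x)
        return starts

    def as_dict(self, x: np.ndarray) -> Dict[str, float]:
        return dict(zip(self.names, np.asarray(x, float)))


class FullScheme:
    """Full transient parameterization with the pair-partner D tie.

    Free parameters: (A, B, C, D) for each blood→organ uptake rate,
    (A, B, C) for each organ→blood return rate and for the two excretion
    rates — their steady-state D is derived from the t = 0 relations —
    plus the two F(t) parameters.  50 parameters in total.
    """

    def __init__(self, control: ControlState, phys: Physiology):
        self.control = control
        self.phys = phys
        self.relations = initial_rate_relations(control, phys)
        names: List[str] = []
        for organ in _ORGANS:
            up, ret = EXCHANGE_PAIRS[organ]
            names += [f"{up}.{p}" for p in "ABCD"]
            names += [f"{ret}.{p}" for p in "ABC"]
        names += [f"k_u.{p}" for p in "ABC"] + [f"k_f.{p}" for p in "ABC"]
        names += ["fraction.A", "fraction.B"]
        self.names = names

    def default_x0(self, steady: Optional[Mapping[str, float]] = None) -> np.ndarray:
        ku_floor = (self.control.c_u * self.phys.q_u) / self.control.m_bl
        x: List[float] = []
        for organ in _ORGANS:
            d0 = (steady or {}).get(organ,
                                    1.5 * ku_floor if organ == "kidney" else 0.1)
            x += [0.0, 0.0, 0.0, d0]   # uptake A,B,C,D
            x += [0.0, 0.0, 0.0]       # return A,B,C
        x += [0.0, 0.0, 0.0] * 2       # k_u, k_f A,B,C
        x += [0.5, 0.01]
        return np.array(x)

    @staticmethod
    def _derived_d(k0: float, a: float, b: float, c: float) -> float:
        dd = k0 - a * math.exp(-((b * c) ** 2))
        if dd < 0:
            raise FeasibilityError("derived steady-state D is negative")
        return dd

    def build(self, x: np.ndarray) -> KineticRateSet:
        x = np.asarray(x, float)
        rel = self.relations
        kw: Dict[str, PulseParams] = {}
        i = 0
        for organ in _ORGANS:
            up_name, ret_name = EXCHANGE_PAIRS[organ]
            ua, ub, uc, ud = x[i:i + 4]; i += 4
            ra, rb, rc = x[i:i + 3]; i += 3
            up = PulseParams(ua, ub, uc, ud)
            ret0 = rel.partner0(organ, up.at0())
            kw[up_name] = up
            kw[ret_name] = PulseParams(ra, rb, rc, self._derived_d(ret0, ra, rb, rc))
        for name, k0 in (("k_u", rel.ku0), ("k_f", rel.kf0)):
            a, b, c = x[i:i + 3]; i += 3
            kw[name] = PulseParams(a, b, c, self._derived_d(k0, a, b, c))
        frac = FractionParams(float(x[i]), float(x[i + 1]))
        return KineticRateSet(fraction=frac, **kw)

    def to_opt(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float).copy()

    def from_opt(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, float).copy()

    def opt_bounds(self):
        from .core import FRACTION_DECAY_MAX_PER_DAY, RATE_MAX_PER_DAY
        abc = [(0.0, RATE_MAX_PER_DAY), (0.0, 5.0), (0.0, 126.0)]
        bounds = []
        for _ in _ORGANS:
            bounds += abc + [(0.0, RATE_MAX_PER_DAY)]  # uptake A,B,C,D
            bounds += abc                              # return A,B,C
        bounds += abc * 2                              # k_u, k_f A,B,C
        bounds += [(0.0, 1.0), (0.0, FRACTION_DECAY_MAX_PER_DAY)]
        return bounds

    def as_dict(self, x: np.ndarray) -> Dict[str, float]:
        return dict(zip(self.names, np.asarray(x, float)))


# ---------------------------------------------------------------------------
# in vivo fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of the direct-search kinetic-parameter fit."""

    rates: KineticRateSet
    x: Dict[str, float]
    rmse_by_compartment: Dict[str, float]
    objective: float
    initial_objective: float
    n_eval: int
    success: bool
    algorithm: str
    seed: Optional[int]
    message: str
    trace: List[float] = field(default_factory=list)


def fit_device(obs: ObservationSet, control: ControlState, phys: Physiology,
               d: DeviceReleaseParams, *,
               scheme=None,
               compartments: Optional[Sequence[str]] = None,
               x0: Optional[np.ndarray] = None,
               maxfev: int = 700,
               ftol: float = 1e-6,
               restarts: int = 0,
               seed: Optional[int] = None,
               grid: Optional[np.ndarray] = None,
               solver_rtol: float = 1e-6,
               solver_atol: float = 1e-9) -> FitResult:
    """Fit kinetic-rate parameters to weighted in vivo observations.

    Nelder-Mead direct search over the scheme's free parameters, with
    infeasible candidates (constraint violations, negative derived rates,
    negative-mass trajectories) rejected by penalty.  Restarts perturb
    the start point with the seeded RNG and keep the best minimum.
    """
    scheme = scheme or SteadyStateScheme(control, phys)
    comps = list(compartments) if compartments is not None else [
        c for c in MEASURED_COMPARTMENTS if c in obs.compartments()]
    obs_times = np.unique(obs.data["time_days"].to_numpy(float))
    if grid is None:
        horizon = max(126.0, float(obs_times.max()))
        grid = np.unique(np.concatenate([
            np.linspace(0.0, horizon, 85), np.geomspace(1e-3, 1.0, 16), obs_times]))
    rng = np.random.default_rng(seed)
    trace: List[float] = []
    n_eval = 0
    best_f = math.inf
    best_z: Optional[np.ndarray] = None

    def fun(z: np.ndarray) -> float:
        nonlocal n_eval, best_f, best_z
        n_eval += 1
        try:
            rates = scheme.build(scheme.from_opt(z))
            traj = simulate(rates, d, phys, control, grid,
                            rtol=solver_rtol, atol=solver_atol)
        except (FeasibilityError, FloatingPointError, IntegrationError,
                OverflowError, ValueError):
            return _PENALTY
        if traj.rejected:
            return _PENALTY
        val = objective(traj, obs, comps)
        trace.append(val)
        if val < best_f:
            best_f, best_z = val, np.asarray(z, float).copy()
        return val

    if x0 is not None:
        x_starts = [np.asarray(x0, float)]
    elif hasattr(scheme, "default_starts"):
        x_starts = scheme.default_starts()
    else:
        x_starts = [scheme.default_x0()]
    z_start = scheme.to_opt(x_starts[0])
    f0 = fun(z_start)
    if not np.isfinite(f0) or f0 >= _PENALTY:
        for _ in range(max(restarts, 5)):
            z_try = z_start + rng.normal(scale=0.3, size=z_start.shape)
            f0 = fun(z_try)
            if f0 < _PENALTY:
                x_starts[0] = scheme.from_opt(z_try)
                break
        else:
            raise FeasibilityError("no feasible start point found after seeded restarts")

    def run_from(z_init: np.ndarray) -> None:
        # iterated simplex: restart from the endpoint until the round
        # stops improving (Nelder-Mead with restarts)
        z = np.asarray(z_init, float).copy()
        f_prev = math.inf
        for _ in range(4):
            res = optimize.minimize(fun, z, method="Nelder-Mead",
                                    options={"maxfev": maxfev, "fatol": ftol,
                                             "xatol": 1e-9, "adaptive": True})
            z = res.x
            if f_prev - res.fun < ftol:
                break
            f_prev = res.fun

    for x_s in x_starts:
        run_from(scheme.to_opt(x_s))
    for _ in range(restarts):
        run_from(z_start + rng.normal(scale=0.5, size=z_start.shape))

    x_best = scheme.from_opt(best_z)
    rates = scheme.build(x_best)
    traj = simulate(rates, d, phys, control, grid,
                    rtol=solver_rtol, atol=solver_atol)
    rmses = {c: weighted_rmse(traj, obs, c) for c in comps}
    return FitResult(
        rates=rates,
        x=scheme.as_dict(x_best),
        rmse_by_compartment=rmses,
        objective=float(best_f),
        initial_objective=float(f0),
        n_eval=n_eval,
        success=bool(best_f <= f0),
        algorithm="nelder-mead-multistart",
        seed=seed,
        message="best evaluated point",
        trace=trace,
    )
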