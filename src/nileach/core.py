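"""Model symbols and primitive evaluations for the stent-leaching PBTK model.

The model tracks nickel mass (ng) in nine compartments of an implanted
mouse: peri-implant (local) tissue, whole blood, liver, brain, lungs,
kidney, gut, bladder urine and gut-resident feces.  The device sheds its
surface nickel inventory by an exponential-saturation law; every transfer
between compartments is first order with a time-dependent rate shaped as a
Gaussian pulse riding on a steady-state value, and a bounded fraction
``F(t)`` of the instantaneous device release enters blood directly (the
remainder enters local tissue).

All times are in days, masses in ng, volumes in mL and concentrations in
ng/mL throughout the package; unit conversion happens at the I/O boundary
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, Mapping

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "MEASURED_COMPARTMENTS",
    "RATE_NAMES",
    "EXCHANGE_PAIRS",
    "FeasibilityError",
    "DegenerateControlError",
    "DeviceReleaseParams",
    "PulseParams",
    "FractionParams",
    "KineticRateSet",
    "Physiology",
    "ControlState",
    "InitialRates",
    "cumulative_release",
    "release_rate",
    "eval_device_release",
    "eval_rate",
    "eval_fraction",
    "audit_rate_nonnegative",
    "audit_fraction_bounds",
    "initial_rate_relations",
    "steady_state_rates",
]

#: Canonical compartment order used by every array in the package.
COMPARTMENTS = (
    "local_tissue",
    "blood",
    "liver",
    "brain",
    "lungs",
    "kidney",
    "gut",
    "urine",
    "feces",
)

#: Compartments sampled in the in vivo study design (gut and feces are
#: dominated by dietary intake and excluded from the default objective).
MEASURED_COMPARTMENTS = (
    "local_tissue",
    "blood",
    "liver",
    "brain",
    "lungs",
    "kidney",
    "urine",
)

#: The 14 first-order kinetic rates.  Naming follows source→destination:
#: e.g. ``k_bllt`` moves nickel from blood to local tissue.
RATE_NAMES = (
    "k_ltbl", "k_bllt",
    "k_livbl", "k_blliv",
    "k_brbl", "k_blbr",
    "k_lubl", "k_bllu",
    "k_kbl", "k_blk",
    "k_gbl", "k_blg",
    "k_u", "k_f",
)

#: Reversible exchange pairs: organ -> (uptake rate blood→organ,
#: return rate organ→blood).
EXCHANGE_PAIRS = {
    "local_tissue": ("k_bllt", "k_ltbl"),
    "liver": ("k_blliv", "k_livbl"),
    "brain": ("k_blbr", "k_brbl"),
    "lungs": ("k_bllu", "k_lubl"),
    "kidney": ("k_blk", "k_kbl"),
    "gut": ("k_blg", "k_gbl"),
}

#: Default audit grid: horizon (days) and number of points used when
#: checking k(t) ≥ 0 and F(t) ∈ [0, 1] numerically.
AUDIT_HORIZON_DAYS = 126.0
AUDIT_POINTS = 10_000

#: Domain upper bounds of the feasible set: a first-order exchange rate
#: above 50/day (residence time under ~30 min) or a blood-fraction decay
#: faster than 10/day is outside the physiological envelope of the host.
RATE_MAX_PER_DAY = 50.0
FRACTION_DECAY_MAX_PER_DAY = 10.0


class FeasibilityError(ValueError):
    """Parameters violate the feasible set of the kinetic model."""


class DegenerateControlError(ValueError):
    """A control (baseline) quantity required in a denominator is zero."""


# ---------------------------------------------------------------------------
# device release law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviceReleaseParams:
    """Two-parameter exponential-saturation leach law of one device.

    Parameters
    ----------
    alpha : float
        Releasable surface nickel inventory per unit area (ng/mm²).
    tau : float
        Characteristic release time (days).
    a_surf : float
        Active device surface area (mm²).
    """

    alpha: float
    tau: float
    a_surf: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise FeasibilityError(f"alpha must be >= 0, got {self.alpha}")
        if self.tau <= 0:
            raise FeasibilityError(f"tau must be > 0, got {self.tau}")
        if self.a_surf <= 0:
            raise FeasibilityError(f"a_surf must be > 0, got {self.a_surf}")

    @property
    def plateau(self) -> float:
        """Total releasable mass alpha × a_surf (ng)."""
        return self.alpha * self.a_surf


def cumulative_release(t, p: DeviceReleaseParams):
    """Cumulative nickel mass (ng) released by the device up to time ``t``.

    ``M_d(t) = alpha * a_surf * (1 - exp(-t / tau))``: zero at implantation,
    nondecreasing, saturating at the total surface inventory.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative (days since implantation)")
    return p.plateau * (-np.expm1(-t / p.tau))


def release_rate(t, p: DeviceReleaseParams):
    """Instantaneous device release rate dM_d/dt (ng/day): positive, decreasing."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative (days since implantation)")
    return p.plateau / p.tau * np.exp(-t / p.tau)


def eval_device_release(t, p: DeviceReleaseParams):
    """Return ``(cumulative ng, rate ng/day)`` of the device at time ``t``."""
    return cumulative_release(t, p), release_rate(t, p)


# ---------------------------------------------------------------------------
# kinetic rate pulse and blood fraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseParams:
    """Gaussian-pulse kinetic rate ``k(t) = A exp(-(B (t - C))²) + D``.

    ``A`` is the pulse height above the asymptote (1/day, same scale as the
    first-order rate it parameterizes), ``B`` the inverse width (1/day),
    ``C`` the abscissa of the pulse maximum (days) and ``D`` the
    steady-state rate the pulse relaxes to (1/day).
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise FeasibilityError(
                    f"pulse parameter {name.upper()} must be finite and >= 0, got {v}"
                )
        if self.a > RATE_MAX_PER_DAY or self.d > RATE_MAX_PER_DAY:
            raise FeasibilityError(
                f"pulse height/steady value exceeds the {RATE_MAX_PER_DAY}/day "
                "physiological bound")

    def __call__(self, t):
        return eval_rate(t, self)

    def at0(self) -> float:
        """Rate value at t = 0."""
        return self.a * math.exp(-((self.b * self.c) ** 2)) + self.d

    @classmethod
    def steady(cls, d: float) -> "PulseParams":
        """A pulse-free (constant) rate of value ``d``."""
        return cls(0.0, 0.0, 0.0, d)


def eval_rate(t, p: PulseParams):
    """Evaluate the Gaussian-pulse rate at time ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    return p.a * np.exp(-((p.b * (t - p.c)) ** 2)) + p.d


@dataclass(frozen=True)
class FractionParams:
    """Blood-routing fraction ``F(t) = A exp(-B t)``.

    ``A`` in [0, 1] is the fraction of device release entering blood at
    implantation; ``B`` ≥ 0 (1/day) is the decay rate as peri-implant
    tissue coverage grows.  The complement ``1 - F(t)`` routes to local
    tissue.  The bounds 0 ≤ F ≤ 1 hold for every t ≥ 0 by construction and
    are additionally audited on a dense grid.
    """

    a: float = 0.5
    b: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise FeasibilityError(f"fraction parameter A must be in [0, 1], got {self.a}")
        if not math.isfinite(self.b) or not (0.0 <= self.b <= FRACTION_DECAY_MAX_PER_DAY):
            raise FeasibilityError(
                f"fraction parameter B must be in [0, {FRACTION_DECAY_MAX_PER_DAY}], "
                f"got {self.b}")

    def __call__(self, t):
        return eval_fraction(t, self)


def eval_fraction(t, p: FractionParams):
    """Evaluate F(t), the share of device release routed to blood."""
    t = np.asarray(t, dtype=float)
    return p.a * np.exp(-p.b * t)


def audit_rate_nonnegative(p: PulseParams, horizon: float = AUDIT_HORIZON_DAYS,
                           n: int = AUDIT_POINTS) -> None:
    """Raise :class:`FeasibilityError` if k(t) < 0 anywhere on a dense grid."""
    grid = np.linspace(0.0, horizon, n)
    k = eval_rate(grid, p)
    if np.any(k < 0):
        raise FeasibilityError("kinetic rate evaluates negative on the audit grid")


def audit_fraction_bounds(p: FractionParams, horizon: float = AUDIT_HORIZON_DAYS,
                          n: int = AUDIT_POINTS) -> None:
    """Raise :class:`FeasibilityError` if F(t) leaves [0, 1] on a dense grid."""
    grid = np.linspace(0.0, horizon, n)
    f = eval_fraction(grid, p)
    if np.any(f < 0) or np.any(f > 1):
        raise FeasibilityError("fraction F(t) leaves [0, 1] on the audit grid")


# ---------------------------------------------------------------------------
# full rate set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticRateSet:
    """The 14 Gaussian-pulse kinetic rates plus the blood fraction F(t)."""

    k_ltbl: PulseParams
    k_bllt: PulseParams
    k_livbl: PulseParams
    k_blliv: PulseParams
    k_brbl: PulseParams
    k_blbr: PulseParams
    k_lubl: PulseParams
    k_bllu: PulseParams
    k_kbl: PulseParams
    k_blk: PulseParams
    k_gbl: PulseParams
    k_blg: PulseParams
    k_u: PulseParams
    k_f: PulseParams
    fraction: FractionParams = field(default_factory=FractionParams)

    def pulses(self) -> Dict[str, PulseParams]:
        return {name: getattr(self, name) for name in RATE_NAMES}

    def rate_arrays(self):
        """Stacked (A, B, C, D) arrays in :data:`RATE_NAMES` order (solver fast path)."""
        ps = [getattr(self, name) for name in RATE_NAMES]
        a = np.array([p.a for p in ps])
        b = np.array([p.b for p in ps])
        c = np.array([p.c for p in ps])
        d = np.array([p.d for p in ps])
        return a, b, c, d

    def rates_at(self, t: float) -> Dict[str, float]:
        return {name: float(eval_rate(t, p)) for name, p in self.pulses().items()}

    def audit(self, horizon: float = AUDIT_HORIZON_DAYS, n: int = AUDIT_POINTS) -> None:
        """Dense-grid feasibility audit of all rates and the fraction."""
        for p in self.pulses().values():
            audit_rate_nonnegative(p, horizon, n)
        audit_fraction_bounds(self.fraction, horizon, n)

    def steady_state_values(self) -> Dict[str, float]:
        """The 14 steady-state rate parameters D (1/day), by rate name."""
        return {name: p.d for name, p in self.pulses().items()}

    def replace(self, **kwargs) -> "KineticRateSet":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# physiology and control state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Physiology:
    """Host (mouse) physiology and fluid-handling constants.

    Defaults are the printed values for a 45 g CD1 mouse.  The fecal
    residence volume ``v_f`` closes the fecal pool dynamics (one day's
    output at ``q_f``, adopting the 1 g ≡ 1 mL excreta convention); the
    steady-state rate relations do not depend on it.
    """

    v_b: float = 3.6       # blood volume, mL
    q_u: float = 1.0       # urine output, mL/day
    v_u: float = 0.15      # bladder urine volume, mL
    q_f: float = 0.094     # fecal output, g/day (1 g ≡ 1 mL)
    k_diet: float = 1250.0  # zero-order dietary nickel intake, ng/day
    body_mass: float = 0.045  # kg
    v_f: float = 0.094     # fecal residence volume, mL

    def __post_init__(self) -> None:
        if self.k_diet < 0:
            raise ValueError("k_diet must be >= 0")
        for f in fields(self):
            if f.name != "k_diet" and getattr(self, f.name) <= 0:
                raise ValueError(f"physiology field {f.name} must be > 0")


@dataclass(frozen=True)
class ControlState:
    """Baseline (unimplanted) nickel levels.

    Masses (ng) for the seven tissue/organ compartments and baseline
    excreta concentrations (ng/mL).  Bladder and fecal baseline masses are
    derived as concentration × residence volume.  The default excretion
    split balances the default dietary intake (k_diet = C_u·Q_u + C_f·Q_f)
    so the control state is an exact fixed point of the kinetic system.
    """

    m_lt: float = 25.0
    m_bl: float = 15.0
    m_liv: float = 120.0
    m_br: float = 35.0
    m_lu: float = 30.0
    m_k: float = 60.0
    m_g: float = 2180.0
    c_u: float = 160.258
    c_f: float = 11_593.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"control field {f.name} must be >= 0")

    def m_u(self, phys: Physiology) -> float:
        """Baseline bladder nickel mass (ng)."""
        return self.c_u * phys.v_u

    def m_f(self, phys: Physiology) -> float:
        """Baseline fecal-pool nickel mass (ng)."""
        return self.c_f * phys.v_f

    def masses(self, phys: Physiology) -> np.ndarray:
        """Baseline masses (ng) in :data:`COMPARTMENTS` order."""
        return np.array([
            self.m_lt, self.m_bl, self.m_liv, self.m_br, self.m_lu,
            self.m_k, self.m_g, self.m_u(phys), self.m_f(phys),
        ])

    def mass_of(self, compartment: str, phys: Physiology) -> float:
        return float(self.masses(phys)[COMPARTMENTS.index(compartment)])


# ---------------------------------------------------------------------------
# t = 0 steady-state rate relations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitialRates:
    """The eight t = 0 rate relations implied by the control fixed point.

    Holds the closed excretion values ``k_u(0)``, ``k_f(0)`` and, for each
    reversible exchange pair, the relation returning the organ→blood rate
    from the blood→organ rate.  These are exactly the relations that make
    the control state stationary under zero device release.
    """

    control: ControlState
    phys: Physiology
    ku0: float
    kf0: float

    def partner0(self, organ: str, uptake0: float) -> float:
        """t = 0 organ→blood rate implied by the blood→organ rate ``uptake0``.

        Raises :class:`FeasibilityError` if the implied return rate is
        negative (possible for kidney when uptake cannot carry the baseline
        urinary flux).
        """
        c, phys = self.control, self.phys
        m_bl = c.m_bl
        if organ == "local_tissue":
            out = uptake0 * m_bl / c.m_lt
        elif organ == "liver":
            out = uptake0 * m_bl / c.m_liv
        elif organ == "brain":
            out = uptake0 * m_bl / c.m_br
        elif organ == "lungs":
            out = uptake0 * m_bl / c.m_lu
        elif organ == "kidney":
            out = uptake0 * m_bl / c.m_k - self.ku0
        elif organ == "gut":
            out = (phys.k_diet + uptake0 * m_bl) / c.m_g - self.kf0
        else:
            raise KeyError(f"unknown exchange organ {organ!r}")
        if out < 0:
            raise FeasibilityError(
                f"implied t=0 return rate for {organ} is negative ({out:.4g}/day); "
                "uptake rate too small to carry the baseline elimination flux"
            )
        return out

    def diet_balanced(self, rtol: float = 1e-9) -> bool:
        """Whether dietary intake balances baseline excretion (blood fixed point)."""
        c, phys = self.control, self.phys
        out = c.c_u * phys.q_u + c.c_f * phys.q_f
        return math.isclose(phys.k_diet, out, rel_tol=rtol)


def initial_rate_relations(control: ControlState, phys: Physiology) -> InitialRates:
    """Build the t = 0 rate relations from a control state.

    ``k_u(0) = C_u·Q_u / M_k`` and ``k_f(0) = C_f·Q_f / M_g`` follow from
    the excreta balance; pair relations follow from per-compartment
    stationarity.  Raises :class:`DegenerateControlError` when a control
    mass needed in a denominator is zero.
    """
    for name in ("m_lt", "m_bl", "m_liv", "m_br", "m_lu", "m_k", "m_g"):
        if getattr(control, name) == 0:
            raise DegenerateControlError(f"control mass {name} is zero")
    ku0 = control.c_u * phys.q_u / control.m_k
    kf0 = control.c_f * phys.q_f / control.m_g
    return InitialRates(control=control, phys=phys, ku0=ku0, kf0=kf0)


def steady_state_rates(control: ControlState, phys: Physiology,
                       uptake0: Mapping[str, float],
                       fraction: FractionParams | None = None) -> KineticRateSet:
    """Pulse-free rate set fixing the control state, from uptake rates.

    ``uptake0`` maps each exchange organ to its (constant) blood→organ
    rate; every return rate plus ``k_u``, ``k_f`` is derived from the
    t = 0 relations, so the control state is a fixed point of the resulting
    constant-rate system (exact for blood too when the diet balance holds).
    """
    rel = initial_rate_relations(control, phys)
    kw: Dict[str, PulseParams] = {}
    for organ, (up_name, ret_name) in EXCHANGE_PAIRS.items():
        up = float(uptake0[organ])
        kw[up_name] = PulseParams.steady(up)
        kw[ret_name] = PulseParams.steady(rel.partner0(organ, up))
    kw["k_u"] = PulseParams.steady(rel.ku0)
    kw["k_f"] = PulseParams.steady(rel.kf0)
    return KineticRateSet(fraction=fraction or FractionParams(), **kw)
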