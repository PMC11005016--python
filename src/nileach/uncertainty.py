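"""Parameter distributions and Monte Carlo propagation.

Per-parameter probability distributions are fitted across the device
family by maximum likelihood (normal or log-normal by parameter domain);
the physiological hypothesis is that kinetic parameters are host
properties, so device-to-device scatter of the fitted values is sampling
uncertainty.  Monte Carlo propagation draws independent parameter
vectors, pre-checks feasibility, simulates, and discards any virtual
experiment whose trajectory shows a negative mass at any solver output
time; accepted trajectories are summarized per compartment and time by
median, quartiles and Tukey whiskers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    COMPARTMENTS,
    ControlState,
    DeviceReleaseParams,
    FeasibilityError,
    Physiology,
)
from .engine import IntegrationError, default_time_grid, simulate

__all__ = [
    "ParameterPDF",
    "fit_parameter_pdfs",
    "draw_parameters",
    "whisker_summary",
    "MCEnsemble",
    "MonteCarloError",
    "monte_carlo",
]


class MonteCarloError(RuntimeError):
    """Monte Carlo acceptance rate fell below the configured floor."""


# ---------------------------------------------------------------------------
# parameter PDFs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterPDF:
    """MLE-fitted marginal distribution of one model parameter.

    ``family`` is "normal" (location mu, scale² sigma²) or "lognormal"
    (theta, omega² on the log scale).  ``scale2`` is the biased 1/n
    maximum-likelihood variance.
    """

    family: str
    loc: float
    scale2: float
    sample: tuple

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale2 < 0:
            raise ValueError("scale2 must be >= 0")

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.scale2))

    def draw(self, rng: np.random.Generator, size=None):
        if self.scale2 == 0.0:
            base = self.loc if size is None else np.full(size, self.loc)
        else:
            base = rng.normal(self.loc, self.scale, size=size)
        return np.exp(base) if self.family == "lognormal" else base

    def mean(self) -> float:
        if self.family == "normal":
            return self.loc
        return float(np.exp(self.loc + self.scale2 / 2.0))

    def median(self) -> float:
        return float(np.exp(self.loc)) if self.family == "lognormal" else self.loc


def fit_parameter_pdfs(samples: Mapping[str, Sequence[float]],
                       domain: Optional[Mapping[str, str]] = None,
                       ) -> Dict[str, ParameterPDF]:
    """MLE normal/log-normal fits of per-device parameter samples.

    ``domain`` maps parameter names to "positive" (log-normal) or "real"
    (normal); unlisted names default to "positive", the domain of every
    kinetic parameter in the feasible set.  Estimators are the closed
    forms: sample mean and 1/n variance (of the values, or their logs).
    """
    pdfs: Dict[str, ParameterPDF] = {}
    for name, values in samples.items():
        x = np.asarray(list(values), dtype=float)
        if x.size < 1:
            raise ValueError(f"empty sample for parameter {name!r}")
        fam = (domain or {}).get(name, "positive")
        fam = "lognormal" if fam == "positive" else "normal"
        if fam == "lognormal" and np.any(x <= 0):
            warnings.warn(f"nonpositive sample for {name!r}; falling back to "
                          "normal family", stacklevel=2)
            fam = "normal"
        if x.size == 1:
            warnings.warn(f"single observation for {name!r}; degenerate PDF",
                          stacklevel=2)
        vals = np.log(x) if fam == "lognormal" else x
        mu = float(vals.mean())
        var = float(np.mean((vals - mu) ** 2))
        pdfs[name] = ParameterPDF(fam, mu, var, tuple(x.tolist()))
    return pdfs


def draw_parameters(pdfs: Mapping[str, ParameterPDF],
                    rng: np.random.Generator) -> Dict[str, float]:
    """One independent draw per parameter, in mapping order."""
    return {name: float(pdf.draw(rng)) for name, pdf in pdfs.items()}


# ---------------------------------------------------------------------------
# whisker summaries
# ---------------------------------------------------------------------------

def whisker_summary(values) -> Dict[str, float]:
    """Median, quartiles, IQR and Tukey whisker bounds of a sample.

    Quartiles use linear interpolation between order statistics; whiskers
    are ``Q3 + 1.5·IQR`` and ``Q1 - 1.5·IQR``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    iqr = q3 - q1
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "iqr": float(iqr), "lo": float(q1 - 1.5 * iqr),
            "hi": float(q3 + 1.5 * iqr)}


# ---------------------------------------------------------------------------
# Monte Carlo propagation
# ---------------------------------------------------------------------------

@dataclass
class MCEnsemble:
    """Accepted Monte Carlo trajectories and their per-time summaries.

    ``samples`` has shape (n_accepted, n_times, 9) on ``t`` (days).
    ``runs`` records every virtual experiment: index, drawn parameters,
    status ("accepted" | "infeasible" | "negative" | "solver_failure").
    """

    t: np.ndarray
    samples: np.ndarray
    runs: List[dict]
    n_requested: int
    n_accepted: int
    n_rejected: int
    seed: Optional[int]
    rejection_reasons: Dict[str, int] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-compartment, per-time whisker summary."""
        q1, med, q3 = np.percentile(self.samples, [25, 50, 75], axis=0,
                                    method="linear")
        iqr = q3 - q1
        rows = []
        for ci, comp in enumerate(COMPARTMENTS):
            for ti, t in enumerate(self.t):
                rows.append({
                    "compartment": comp, "time_days": float(t),
                    "median": med[ti, ci], "q1": q1[ti, ci], "q3": q3[ti, ci],
                    "iqr": iqr[ti, ci],
                    "lo": q1[ti, ci] - 1.5 * iqr[ti, ci],
                    "hi": q3[ti, ci] + 1.5 * iqr[ti, ci],
                    "n_accepted": self.n_accepted,
                })
        return pd.DataFrame(rows)

    def band(self, compartment: str, level: str = "whisker"):
        """(t, lo, hi) band for one compartment: "whisker" or "iqr"."""
        ci = COMPARTMENTS.index(compartment)
        q1, q3 = np.percentile(self.samples[:, :, ci], [25, 75], axis=0,
                               method="linear")
        if level == "iqr":
            return self.t, q1, q3
        iqr = q3 - q1
        return self.t, q1 - 1.5 * iqr, q3 + 1.5 * iqr

    def median_trajectory(self, compartment: str) -> np.ndarray:
        ci = COMPARTMENTS.index(compartment)
        return np.percentile(self.samples[:, :, ci], 50, axis=0, method="linear")


def monte_carlo(pdfs: Mapping[str, ParameterPDF], scheme,
                control: ControlState, phys: Physiology,
                d: Optional[DeviceReleaseParams], *,
                n: int = 5000,
                seed: Optional[int] = None,
                report_times: Optional[np.ndarray] = None,
                horizon: float = 126.0,
                acceptance_floor: float = 0.1,
                max_redraws: int = 0,
                solver_rtol: float = 1e-7,
                solver_atol: float = 1e-10) -> MCEnsemble:
    """Rejection-filtered Monte Carlo propagation of parameter PDFs.

    Each virtual experiment draws one value per parameter in
    ``scheme.names`` order from ``pdfs`` (independent marginals), builds
    the rate set through ``scheme.build`` (an infeasible vector is a
    discarded experiment; ``max_redraws`` > 0 allows redraws first),
    simulates, and discards trajectories with any negative mass on the
    dense solver grid.  Substream RNGs keep runs reproducible regardless
    of the rejection pattern.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    missing = [name for name in scheme.names if name not in pdfs]
    if missing:
        raise KeyError(f"PDFs missing for parameters: {missing}")
    if report_times is None:
        report_times = np.unique(np.concatenate(
            [[0.0, 0.25, 0.5], np.linspace(1.0, horizon, 126)]))
    report_times = np.asarray(report_times, dtype=float)
    sim_grid = np.unique(np.concatenate([default_time_grid(horizon), report_times]))
    idx = np.searchsorted(sim_grid, report_times)

    children = np.random.SeedSequence(seed).spawn(n)
    accepted: List[np.ndarray] = []
    runs: List[dict] = []
    reasons: Dict[str, int] = {}
    neg_param_counts: Dict[str, int] = {}

    for i in range(n):
        rng = np.random.default_rng(children[i])
        status, params, rates = "infeasible", None, None
        for _ in range(max_redraws + 1):
            params = draw_parameters({name: pdfs[name] for name in scheme.names}, rng)
            x = np.array([params[name] for name in scheme.names])
            try:
                rates = scheme.build(x)
                status = "drawn"
                break
            except FeasibilityError:
                continue
        if status == "infeasible":
            for name, v in params.items():
                if v < 0:
                    neg_param_counts[name] = neg_param_counts.get(name, 0) + 1
            reasons["infeasible"] = reasons.get("infeasible", 0) + 1
            runs.append({"index": i, "params": params, "status": "infeasible"})
            continue
        try:
            traj = simulate(rates, d, phys, control, sim_grid,
                            rtol=solver_rtol, atol=solver_atol)
        except (IntegrationError, FloatingPointError):
            reasons["solver_failure"] = reasons.get("solver_failure", 0) + 1
            runs.append({"index": i, "params": params, "status": "solver_failure"})
            continue
        if traj.rejected:
            reasons["negative"] = reasons.get("negative", 0) + 1
            runs.append({"index": i, "params": params, "status": "negative"})
            continue
        accepted.append(traj.m[idx])
        runs.append({"index": i, "params": params, "status": "accepted"})

    n_acc = len(accepted)
    if n_acc / n < acceptance_floor:
        worst = sorted(neg_param_counts.items(), key=lambda kv: -kv[1])[:5]
        raise MonteCarloError(
            f"acceptance rate {n_acc / n:.3f} below floor {acceptance_floor}; "
            f"rejections {reasons}; most frequently negative draws: {worst}")
    samples = np.stack(accepted) if n_acc else np.empty((0, report_times.size, 9))
    return MCEnsemble(t=report_times, samples=samples, runs=runs,
                      n_requested=n, n_accepted=n_acc, n_rejected=n - n_acc,
                      seed=seed, rejection_reasons=reasons)
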