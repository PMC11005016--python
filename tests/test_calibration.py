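"""Calibration: release fits, RBF confidence weights, objective, device fit."""

import math

import numpy as np
import pandas as pd
import pytest

from nileach.calibration import (
    FullScheme,
    SteadyStateScheme,
    compute_weights,
    fit_device,
    fit_release,
    objective,
    weighted_rmse,
)
from nileach.core import (
    DegenerateControlError,
    DeviceReleaseParams,
    cumulative_release,
    initial_rate_relations,
)
from nileach.engine import rhs, simulate, default_time_grid
from nileach.synthetic import (
    DEFAULT_UPTAKE0,
    IMMERSION_DAYS,
    default_scenario,
    gen_biodistribution,
)

UPTAKE_D_NAMES = ("k_bllt", "k_blliv", "k_blbr", "k_bllu", "k_blk", "k_blg")


class TestFitRelease:
    def test_noiseless_recovery_at_study_days(self):
        p = DeviceReleaseParams(alpha=100.0, tau=5.0, a_surf=11.0)
        t = np.array(IMMERSION_DAYS)
        fit = fit_release(t, cumulative_release(t, p), 11.0)
        assert fit.params.alpha == pytest.approx(100.0, rel=1e-6)
        assert fit.params.tau == pytest.approx(5.0, rel=1e-6)
        assert fit.flag is None

    def test_all_zero_data_flagged_degenerate(self):
        fit = fit_release([1, 2, 3], [0.0, 0.0, 0.0], 11.0)
        assert fit.params.alpha == 0.0
        assert fit.flag == "degenerate_zero"

    def test_instantaneous_release_hits_tau_boundary(self):
        t = np.array(IMMERSION_DAYS)
        fit = fit_release(t, np.full(t.size, 1100.0), 11.0)
        assert fit.flag == "tau_boundary"
        assert fit.params.alpha == pytest.approx(100.0, rel=1e-4)

    def test_nonmonotone_data_warn_but_fit(self):
        with pytest.warns(UserWarning, match="not monotone"):
            fit = fit_release([1, 2, 3, 5], [10.0, 30.0, 25.0, 40.0], 11.0)
        assert fit.params.alpha > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_release([1, 2], [5.0, 9.0], 11.0)


def _obs_frame(comp, times, masses, control_mass):
    rows = [{"compartment": comp, "time_days": 0.0, "mass_ng": control_mass}]
    rows += [{"compartment": comp, "time_days": t, "mass_ng": m}
             for t, m in zip(times, masses)]
    return pd.DataFrame(rows)


class TestWeights:
    def test_inside_band_gets_full_confidence(self, control, phys, device):
        df = _obs_frame("liver", [10.0], [control.m_liv + 5.0], control.m_liv)
        obs = compute_weights(df, control, phys, device)
        assert obs.data["weight"].iloc[1] == 1.0

    def test_exactly_at_control_boundary(self, control, phys, device):
        df = _obs_frame("liver", [10.0], [control.m_liv], control.m_liv)
        obs = compute_weights(df, control, phys, device)
        assert obs.data["weight"].iloc[1] == 1.0

    def test_exactly_at_release_cap_boundary(self, control, phys, device):
        cap = float(cumulative_release(10.0, device)) + control.m_liv
        df = _obs_frame("liver", [10.0], [cap], control.m_liv)
        obs = compute_weights(df, control, phys, device)
        assert obs.data["weight"].iloc[1] == 1.0

    def test_subcontrol_point_gets_its_mass_ratio_as_weight(
            self, control, phys, device):
        m = 0.8 * control.m_liv
        df = _obs_frame("liver", [10.0], [m], control.m_liv)
        obs = compute_weights(df, control, phys, device)
        assert obs.data["weight"].iloc[1] == pytest.approx(0.8, abs=1e-12)
        # kernel-consistent sigma: forward re-evaluation reproduces w
        sigma = obs.sigma[("liver", "control")]
        dist = control.m_liv - m
        assert math.exp(-((dist / sigma) ** 2)) == pytest.approx(0.8)

    def test_above_cap_point_weighted_by_cap_ratio(self, control, phys, device):
        cap = float(cumulative_release(10.0, device)) + control.m_liv
        df = _obs_frame("liver", [10.0], [1.25 * cap], control.m_liv)
        obs = compute_weights(df, control, phys, device)
        assert obs.data["weight"].iloc[1] == pytest.approx(cap / (1.25 * cap))
        assert ("liver", "release") in obs.sigma

    def test_common_sigma_for_multiple_violations(self, control, phys, device):
        # two sub-control points with different implied sigmas share one
        df = _obs_frame("liver", [10.0, 20.0],
                        [0.9 * control.m_liv, 0.6 * control.m_liv],
                        control.m_liv)
        obs = compute_weights(df, control, phys, device)
        w = obs.data["weight"].to_numpy()[1:]
        sigma = obs.sigma[("liver", "control")]
        d1, d2 = 0.1 * control.m_liv, 0.4 * control.m_liv
        assert w[0] == pytest.approx(math.exp(-((d1 / sigma) ** 2)))
        assert w[1] == pytest.approx(math.exp(-((d2 / sigma) ** 2)))
        assert np.all(w < 1.0)

    def test_weight_continuity_at_the_boundary(self, control, phys, device):
        # w -> 1 as a violating point approaches the control bound
        for eps, w_min in ((1e-3, 0.99), (1e-6, 0.9999)):
            m = control.m_liv * (1.0 - eps)
            df = _obs_frame("liver", [10.0], [m], control.m_liv)
            obs = compute_weights(df, control, phys, device)
            assert obs.data["weight"].iloc[1] > w_min

    def test_zero_control_with_subcontrol_violation_degenerate(
            self, control, phys, device):
        df = _obs_frame("liver", [10.0], [-1.0], 0.0)
        with pytest.raises(DegenerateControlError):
            compute_weights(df, control, phys, device)

    def test_missing_control_row_rejected(self, control, phys, device):
        df = pd.DataFrame([{"compartment": "liver", "time_days": 10.0,
                            "mass_ng": 100.0}])
        with pytest.raises(ValueError, match="control row"):
            compute_weights(df, control, phys, device)

    def test_preset_sigma_honored(self, control, phys, device):
        m = 0.8 * control.m_liv
        df = _obs_frame("liver", [10.0], [m], control.m_liv)
        sigma = {("liver", "control"): 1000.0}
        obs = compute_weights(df, control, phys, device, sigma=sigma)
        dist = control.m_liv - m
        assert obs.data["weight"].iloc[1] == pytest.approx(
            math.exp(-((dist / 1000.0) ** 2)))


class TestObjective:
    @pytest.fixture()
    def traj(self, control, phys, ss_rates):
        return simulate(ss_rates, None, phys, control,
                        default_time_grid(126.0, 60))

    def _obs(self, control, traj, comp, residuals, weights):
        t = np.array([20.0, 40.0])
        model = traj.interp(comp, t)
        from nileach.calibration import ObservationSet
        rows = [{"compartment": comp, "time_days": 0.0,
                 "mass_ng": float(traj.interp(comp, [0.0])[0]), "weight": 1.0}]
        # control row residual is 0 by construction; weight 1
        for tj, r, w in zip(t, residuals, weights):
            rows.append({"compartment": comp, "time_days": tj,
                         "mass_ng": float(model[list(t).index(tj)]) + r,
                         "weight": w})
        return ObservationSet(data=pd.DataFrame(rows))

    def test_perfect_fit_gives_zero(self, control, traj):
        obs = self._obs(control, traj, "liver", [0.0, 0.0], [1.0, 1.0])
        assert weighted_rmse(traj, obs, "liver") == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_weighted_rmse(self, control, traj):
        # residuals {3, 4}, weights {1, 1} -> sqrt((9 + 16) / 2); the
        # time-0 control row is an initial condition and does not count
        obs = self._obs(control, traj, "liver", [3.0, 4.0], [1.0, 1.0])
        assert weighted_rmse(traj, obs, "liver") == pytest.approx(
            math.sqrt(25.0 / 2.0), rel=1e-9)

    def test_zero_weight_point_drops_out(self, control, traj):
        # residuals {3, 4}, weights {1, 0} -> the zero-weight point drops
        # out of the normalized sum, leaving exactly 3 ng
        obs = self._obs(control, traj, "liver", [3.0, 4.0], [1.0, 0.0])
        assert weighted_rmse(traj, obs, "liver") == pytest.approx(3.0, rel=1e-9)

    def test_objective_is_mean_of_compartment_rmses(self, control, traj):
        from nileach.calibration import ObservationSet
        frames = []
        for comp, resid in (("liver", 3.0), ("brain", 6.0), ("lungs", 9.0)):
            o = self._obs(control, traj, comp, [resid, resid], [1.0, 1.0])
            frames.append(o.data)
        obs = ObservationSet(data=pd.concat(frames, ignore_index=True))
        rmses = [weighted_rmse(traj, obs, c) for c in ("liver", "brain", "lungs")]
        assert objective(traj, obs) == pytest.approx(np.mean(rmses))
        # permutation symmetry
        shuffled = ObservationSet(
            data=obs.data.sample(frac=1.0, random_state=0).reset_index(drop=True))
        assert objective(traj, shuffled) == pytest.approx(objective(traj, obs))

    def test_objective_needs_two_compartments(self, control, traj):
        obs = self._obs(control, traj, "liver", [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            objective(traj, obs)


class TestSchemes:
    def test_steady_scheme_preserves_control_fixed_point(self, control, phys):
        scheme = SteadyStateScheme(control, phys)
        x = scheme.default_x0()
        rates = scheme.build(x)
        dm = rhs(0.0, control.masses(phys), rates, None, phys)
        assert np.max(np.abs(dm)) < 1e-9

    def test_full_scheme_ties_derived_steady_values(self, control, phys):
        scheme = FullScheme(control, phys)
        x = scheme.default_x0(steady=DEFAULT_UPTAKE0)
        # add transients on the local-tissue uptake and on k_u
        names = scheme.names
        x[names.index("k_bllt.A")] = 0.05
        x[names.index("k_bllt.B")] = 0.3
        x[names.index("k_bllt.C")] = 4.0
        x[names.index("k_u.A")] = 0.5
        x[names.index("k_u.B")] = 0.2
        x[names.index("k_u.C")] = 2.0
        rates = scheme.build(x)
        rel = initial_rate_relations(control, phys)
        # the t=0 excretion value stays at its closed form
        assert rates.k_u.at0() == pytest.approx(rel.ku0)
        # each pair's t=0 relation holds, so the control state is fixed
        dm = rhs(0.0, control.masses(phys), rates, None, phys)
        assert np.max(np.abs(dm)) < 1e-9

    def test_full_scheme_rejects_negative_derived_d(self, control, phys):
        scheme = FullScheme(control, phys)
        x = scheme.default_x0(steady=DEFAULT_UPTAKE0)
        names = scheme.names
        # a huge t=0 pulse on k_u would need D < 0 to keep the tie
        x[names.index("k_u.A")] = 40.0
        from nileach.core import FeasibilityError
        with pytest.raises(FeasibilityError):
            scheme.build(x)


@pytest.fixture(scope="module")
def noiseless_fit():
    # dense-design noiseless recovery: truth inside the model class
    days = (1.0, 3.0, 7.0, 14.0, 28.0, 56.0, 126.0)
    scn = default_scenario(seed=3, noise_cv=0.0,
                           pulse_height_ratio=0.0).with_(
        outlier_rate_low=0.0, outlier_rate_high=0.0,
        invivo_weeks=tuple(d / 7.0 for d in days))
    bio = gen_biodistribution(scn)
    obs = compute_weights(bio, scn.control, scn.phys, scn.release)
    x_truth = np.array([DEFAULT_UPTAKE0[o] for o in (
        "local_tissue", "liver", "brain", "lungs", "kidney", "gut")]
        + [0.6, 0.05])
    x0 = x_truth * np.array([1.3, 0.8, 1.25, 0.75, 1.3, 1.3, 0.85, 1.3])
    fit = fit_device(obs, scn.control, scn.phys, scn.release,
                     x0=x0, maxfev=500, seed=0)
    return fit, x_truth


class TestFitDevice:
    def test_noiseless_objective_near_zero(self, noiseless_fit):
        fit, _ = noiseless_fit
        assert fit.objective < 1e-3

    def test_noiseless_steady_rates_recovered(self, noiseless_fit):
        fit, x_truth = noiseless_fit
        fitted = np.array([fit.x[f"{n}.D"] for n in UPTAKE_D_NAMES])
        assert np.max(np.abs(fitted - x_truth[:6]) / x_truth[:6]) < 0.01

    def test_direct_search_never_worsens_start(self, noiseless_fit):
        fit, _ = noiseless_fit
        assert fit.objective <= fit.initial_objective
        assert fit.success

    def test_downweighted_outlier_helps_a_correct_model(
            self, control, phys):
        # with injected outliers, the weighted objective at the truth is
        # below the unit-weight objective: down-weighting absorbs them
        scn = default_scenario(seed=11, noise_cv=0.0).with_(
            outlier_rate_low=0.3, outlier_rate_high=0.3)
        rng = np.random.default_rng(scn.seed)
        bio = gen_biodistribution(scn, rng)
        assert bio["is_outlier"].sum() > 0
        obs = compute_weights(bio, control, phys, scn.release)
        flat = obs.data.copy()
        flat["weight"] = 1.0
        from nileach.calibration import ObservationSet
        obs_flat = ObservationSet(data=flat)
        traj = simulate(scn.rates, scn.release, phys, control,
                        default_time_grid(126.0, 120))
        assert objective(traj, obs) < objective(traj, obs_flat)
        # every injected outlier is down-weighted
        injected = obs.data[bio["is_outlier"].to_numpy()]
        assert np.all(injected["weight"] < 1.0)
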