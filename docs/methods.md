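# Methods

`nileach` models the fate of nickel ions leaching from an implanted
vascular stent in a mouse. This note records the model, the numerical
choices, what the synthetic data generator does and does not emulate,
and the known limits of what the test suite demonstrates.

## Model

### Device release

The device sheds its releasable surface inventory by an
exponential-saturation law,

    M_d(t) = α · A_surf · (1 − e^(−t/τ)),    Ṁ_d(t) = (α · A_surf / τ) · e^(−t/τ),

with α the releasable nickel per unit area (ng/mm²), A_surf the active
surface area (mm²) and τ the characteristic release time (days).
Cumulative release is zero at implantation, nondecreasing, and bounded
by α·A_surf. This is a lumped two-parameter description; no diffusion
PDE or oxide-layer electrochemistry is modelled.

### Compartments and kinetics

Nine compartments hold nickel mass (ng): peri-implant (local) tissue,
whole blood, liver, brain, lungs, kidney, gut, bladder urine and
gut-resident feces. A fraction F(t) of the instantaneous device release
enters blood directly; the remainder enters local tissue. Six organs
exchange reversibly with blood by first-order kinetics; the kidney
additionally eliminates irreversibly to urine (k_u) and the gut to
feces (k_f); the gut receives a zero-order dietary inflow k_diet.
Urine and feces are residence pools: the bladder (volume V_u) empties
at the urine output rate Q_u with outflux C_u·Q_u, and the fecal pool
(residence volume v_f) at Q_f with outflux C_f·Q_f, where C = M/V. The
excreted fluxes leave the system and are tracked as two cumulative
bookkeeping states so that

    Σᵢ Mᵢ(T) + excreted(T) = Σᵢ Mᵢ(0) + M_d(T) + k_diet·T

can be audited at every output time.

Every kinetic rate is a Gaussian pulse riding on a steady value,

    k(t) = A · exp(−(B·(t−C))²) + D,

with height A above the asymptote, inverse width B (1/day), pulse
abscissa C (days) and steady-state value D (1/day). The blood-routing
fraction is F(t) = A_F · e^(−B_F·t) with 0 ≤ A_F ≤ 1, B_F ≥ 0, so
F ∈ [0, 1] for all t by construction; both bounds and rate
nonnegativity are additionally audited on a 10⁴-point grid over the
simulation horizon. The feasible set further imposes D, A ≤ 50/day and
B_F ≤ 10/day: a first-order exchange faster than ~30 minutes of
residence, or a routing fraction that decays within hours, is outside
the physiological envelope of the host, and without these domain bounds
the weakly identified directions of the calibration run away
arbitrarily.

### Initial conditions and the t = 0 rate relations

All compartments start at their control (unimplanted baseline) values.
Requiring the control state to be a fixed point of the kinetic system
under zero device release yields eight relations: closed values

    k_u(0) = C_u·Q_u / M_k,      k_f(0) = C_f·Q_f / M_g,

pure ratio ties for the local-tissue, liver, brain and lungs pairs
(k_organ→blood(0) = k_blood→organ(0) · M_bl / M_organ), and kidney/gut
relations that include the elimination fluxes. Blood stationarity
additionally requires the diet balance k_diet = C_u·Q_u + C_f·Q_f; the
default control state satisfies it exactly.

## Parameters and defaults

Physiology of a 45 g CD1 mouse: V_b = 3.6 mL, Q_u = 1 mL/day,
V_u = 0.15 mL, Q_f = 0.094 g/day (1 g ≡ 1 mL for excreta),
k_diet = 1250 ng/day. The fecal residence volume v_f = 0.094 mL
(one day's output, i.e. ~1-day gut transit) closes the fecal pool
dynamics; the steady-state relations do not depend on it.

Control state: M_g = 2180 ng and C_f = 11 593 ng/mL are measured
values; C_u = 160.258 ng/mL is the value implied by the diet balance
above. The remaining baselines are plausible CD1 values chosen once:
local tissue 25 ng, blood 15 ng (≈ 4 ng/mL), liver 120 ng, brain
35 ng, lungs 30 ng, kidney 60 ng. With blood at 15 ng, the renal
uptake rate must satisfy k_blk(0) ≥ C_u·Q_u/M_bl ≈ 10.7/day to carry
the baseline urinary flux — renal handling of nickel is fast, and this
floor is a structural feature of the balanced control state.

Time is days, mass ng, volume mL everywhere inside the package; unit
conversion (weeks, hours, concentrations) happens only in the I/O
layer.

## Calibration

Device-specific (α, τ) come from bounded nonlinear least squares on
cumulative immersion data. A fitted τ below a tenth of the first
sampling time is flagged as unresolvable (the data look like
instantaneous release); all-zero data yield α = 0 with a degeneracy
flag.

Host-specific kinetics are fitted to in vivo biodistribution data by
minimizing the equal-trade-off objective: the mean over compartments of
the weighted RMSE

    RMSE_i = sqrt( Σ_j w_ij (M_i(t_j) − M_ij)² / Σ_j w_ij ),

in ng, over the measured compartments (gut and feces excluded by
default — their content is dominated by dietary throughput). The
time-0 control row is the initial condition, not a measurement, and
does not enter the sum. Model values at observation times come from
monotone-cubic (PCHIP) interpolation of the solved trajectory.

Confidence weights: an observation below its control value, or above
control plus the device's cumulative release at that time, is
physically implausible; it receives w = exp(−(violation/σ)²) with σ
inverted from the kernel so a lone sub-control point at fraction q of
control gets w = q exactly (symmetrically, a cap violation gets the
cap-to-value ratio). Several violations of the same kind in one
compartment share a single σ, found by a 1-D search seeded at the mean
of the per-point inversions, after which all weights in that
compartment are recomputed with the common σ.

The default parameterization is steady-state: the six blood→organ
uptake D values plus the two F(t) parameters are free; every
organ→blood return and both excretion rates are tied to their t = 0
relations so each candidate keeps the control state stationary, and
within each exchange pair the partner's steady value is derived rather
than fitted. A full scheme with the transient A, B, C parameters free
(50 parameters, same ties) is available. The optimizer is multi-start
iterated Nelder-Mead: starts spanning the blood-fraction axis
(A_F ∈ {0.25, 0.5, 0.75}), each start restarted from its own endpoint
until a round stops improving, infeasible candidates rejected by
penalty, and the best evaluated point kept. The multi-start matters:
the objective has distinct basins along A_F at sparse designs. Rates
are optimized in log space. Default budget is 700 evaluations per
round with objective tolerance 10⁻⁶ ng; solver tolerances during
fitting are relaxed to rtol 10⁻⁶ for speed.

## Integration

`scipy.integrate.solve_ivp` with LSODA, defaults rtol 10⁻⁸ /
atol 10⁻¹² (configurable). The output grid starts at 0, is strictly
increasing, and by default carries a log-dense early section
(geomspace 10⁻³–1 day) to resolve the release bolus. Negative states
are flagged on the dense output (`Trajectory.rejected`), never clipped.
Reported dM_i/dt profiles are RHS evaluations on the trajectory, not
finite differences.

## Uncertainty propagation

Per-parameter distributions across the device family are maximum
likelihood: sample mean and 1/n variance of the values (normal) or of
their logs (log-normal). The family follows the parameter's domain —
every kinetic parameter here is positive, hence log-normal; a
nonpositive sample falls back to normal with a warning. Parameters are
sampled independently (no covariance information exists at n = 2–3
devices).

Monte Carlo (default n = 5000) draws one vector per virtual
experiment from per-run substreams of a seeded `SeedSequence`, so
results are bit-reproducible regardless of the rejection pattern. An
infeasible draw is a discarded experiment (no redraw by default); an
accepted draw is simulated and discarded if any compartment goes
negative anywhere on the dense solver output. Acceptance below a
configurable floor (default 10%) raises a diagnostic naming the most
frequently offending parameters. Summaries per compartment and time:
median, quartiles by linear interpolation between order statistics
(the convention is fixed here; equivalent to numpy's default), IQR,
and Tukey whiskers Q3 + 1.5·IQR / Q1 − 1.5·IQR.

## Tolerable-intake analysis

The parenteral tolerable intake for nickel is 0.5 µg/kg/day. It is
apportioned to compartments by time-averaged mass fractions
⟨y_i⟩ = avg(M_i(t)/M_total(t)) (trapezoid rule over the horizon,
renormalized to sum to one), with M_total the accounting total
(baselines + dietary intake + cumulative device release). TI_i =
⟨y_i⟩ · 0.5 µg/kg/day · body mass, so Σ TI_i equals the whole-body TI
(22.5 ng/day at 45 g). Exceedance screening compares the net
compartmental dM_i/dt (and the raw device rate Ṁ_d against the
whole-body TI) to the thresholds, locating crossings between grid
points by linear root bracketing. By default the fractions come from
the ensemble medians when an ensemble is supplied; the averaging
horizon defaults to the 126-day simulation horizon.

## Synthetic study conditions

The generator reproduces the study design: immersion sampling at days
1, 2, 3, 5, 7, 14, 21, 28, 42, 60; in vivo sampling at 4, 8 and 18
weeks across the seven measured compartments (local tissue, blood,
liver, brain, lungs, kidney, urine); one pooled observation per
compartment and time; multiplicative log-normal noise (mean one,
default CV 10%); and occasional implausible outliers (default 5%
sub-control, 5% above the release cap), labeled in a side channel so
weighting tests can target them exactly. Control rows are exact and
the ground-truth rate set keeps them a fixed point by construction.

The reference device is a high-release heat-treated-like surface:
α = 300 ng/mm², τ = 5 days, A_surf = 11 mm² (a ~3.3 µg bolus-dominated
release — the magnitude regime implied by per-compartment errors of
tens to hundreds of ng and an early whole-body TI exceedance).
Ground-truth kinetics carry a transient uptake pulse (height equal to
the steady value, centered at day 14, width parameter 0.12/day)
emulating the inflammatory redistribution phase, and steady uptakes of
0.05–0.15/day for the slow organs with control-tied returns giving
tissue residence times of weeks to months, so organ burdens remain
measurably elevated across the 18-week study. Renal uptake is 12/day
(above its structural floor).

Device suites share the host but not the cohort: release parameters
scatter with log-variance 0.09 and kinetic parameters with
log-variance 0.04 (~20% CV) per device cohort, with returns re-derived
so every cohort's control state stays a fixed point.

What the generator does **not** emulate: instrument physics (detection
limits, digestion recovery), replicate-level variation within a pooled
sample, inter-animal variation within a cohort, time-varying control
baselines, and any misspecification of the kinetic model class itself.
Passing tests therefore demonstrate internal consistency of the
estimator chain under the declared noise model, not performance on
ICP-MS data.

## Problem sizes used by the tests and the acceptance script

Conservation is audited on 50 random admissible parameter sets;
release-law robustness on 100 noisy replicates at 5% CV; Monte Carlo
semantics at n = 5000 for the rejection-fraction check and n = 200–300
elsewhere; the calibration harness fits two devices at the sparse
study design with a 500-evaluation-per-round budget and predicts the
third with an n = 1000 ensemble. These are the package's choices for a
thorough-but-routine run; all are plain arguments and scale up freely.

## Known limitations

- The sparse in vivo design (three time points) identifies the
  local-tissue kinetics and the well-signed organ rates, but the renal
  uptake above its floor, the gut uptake (gut data excluded from the
  objective), and the late-time fraction decay are weakly identified;
  their fitted values should be read as regularized by the feasible
  set, not as measurements. The acceptance suite documents the
  resulting recovery accuracy honestly.
- With only two training devices, the MLE 1/n scales are themselves
  noisy; whisker bands from n = 2 PDFs understate uncertainty where
  the two fits happen to agree, and the exactly-computed excretion
  rates pin late-time blood/kidney/urine trajectories, so parametric
  bands there are narrow by construction and do not absorb measurement
  noise.
- Parameters are sampled independently in Monte Carlo; correlated
  draws would narrow or widen bands where the calibration surface has
  strong parameter couplings (notably A_F with the local-tissue
  uptake).
- The model assumes a static implant environment; geometry change,
  flow-limited transport and toxicodynamics are out of scope.
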