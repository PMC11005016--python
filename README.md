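# nileach

A predictive toxicokinetic engine for metal-ion leaching from implanted
vascular stents: a nine-compartment, time-variant PBTK
(physiologically based toxicokinetic) model of nickel biodistribution
in a mouse stent-implantation study, with device-release calibration
from immersion tests, data-confidence-weighted fitting of the
biokinetic parameters from in vivo measurements, Monte Carlo
uncertainty propagation, and a compartmental tolerable-intake (TI)
risk assessment.

It is written for biomaterials and regulatory-science groups that need
to connect in vitro ion-release testing of a device to predicted in
vivo exposure — concentration–time profiles in tissues, body fluids
and excreta, with confidence bands, screened against permissible
exposure limits.

## The model

The device sheds its releasable surface nickel by an
exponential-saturation law

    M_d(t) = α A_surf (1 − e^(−t/τ)),

and the host is a compartmental system — peri-implant (local) tissue,
blood, liver, brain, lungs, kidney, gut, urine and feces — with
first-order exchange between blood and each organ, irreversible
elimination kidney→urine and gut→feces, a zero-order dietary inflow,
and flushed excreta pools. A fraction F(t) = A_F e^(−B_F t) ∈ [0, 1] of
the instantaneous release enters blood directly; the rest enters local
tissue. Every kinetic rate is time-variant with a Gaussian-pulse form

    k_i(t) = A e^(−(B(t−C))²) + D,

whose steady value D is tied, within each exchange pair, to the
requirement that the unimplanted control state is a fixed point of the
system. Calibration minimizes the equal-trade-off mean of
per-compartment weighted RMSEs (in ng), where Gaussian-RBF weights
down-weight observations that violate physical plausibility (below
control, or above control plus everything the device could have
released). Per-parameter distributions across a device family are
maximum-likelihood normal/log-normal fits, propagated by
rejection-filtered Monte Carlo and summarized as median/IQR/Tukey
whiskers. Compartmental TI values are TI_i = ⟨y_i⟩ × 0.5 µg/kg/day ×
body mass, with ⟨y_i⟩ the time-averaged mass fraction from the mass
balance.

Full details, defaults and numerical choices: [docs/methods.md](docs/methods.md).

## Worked example

Fit the release law of a high-release device from immersion data,
simulate the implanted mouse, and screen against the nickel TI:

```python
import numpy as np
from nileach import (ControlState, Physiology, DeviceReleaseParams,
                     steady_state_rates, simulate, default_time_grid,
                     fit_release, cumulative_release)
from nileach.risk import ti_report
from nileach.synthetic import DEFAULT_UPTAKE0, IMMERSION_DAYS

phys, control = Physiology(), ControlState()      # 45 g CD1 mouse
truth = DeviceReleaseParams(alpha=300.0, tau=5.0, a_surf=11.0)
t = np.array(IMMERSION_DAYS)                      # days 1..60
fit = fit_release(t, cumulative_release(t, truth), a_surf=11.0)
print(f"alpha = {fit.params.alpha:.1f} ng/mm^2, tau = {fit.params.tau:.2f} d")

rates = steady_state_rates(control, phys, DEFAULT_UPTAKE0)
traj = simulate(rates, fit.params, phys, control, default_time_grid(126.0, 1000))
print(f"peak local-tissue nickel: {traj.compartment('local_tissue').max():.0f} ng")
print(f"peak blood concentration: {traj.blood_concentration(phys).max():.2f} ng/mL")

report = ti_report(traj, control, phys, fit.params)
print(f"whole-body TI: {report.total_ti:.1f} ng/day")
s, e = report.exceedance_intervals["device_release"][0]
print(f"device release exceeds TI from day {s:.0f} to day {e:.1f}")
```

Output:

```
alpha = 300.0 ng/mm^2, tau = 5.00 d
peak local-tissue nickel: 1212 ng
peak blood concentration: 11.54 ng/mL
whole-body TI: 22.5 ng/day
device release exceeds TI from day 0 to day 16.9
```

The release fit recovers the generating parameters exactly on clean
data. The ~3.3 µg release bolus drives peri-implant tissue nickel from
its 25 ng baseline to ~1.2 µg, and the raw device release rate exceeds
the 22.5 ng/day whole-body TI of a 45 g mouse until day
5·ln(660/22.5) ≈ 16.9 — after which the release rate has decayed below
the parenteral limit. Compartment-level screening
(`report.exceedance_intervals`) does the same against each TI_i.

## Command line

The same pipeline is scriptable:

```bash
nileach synth --seed 1 --devices 3 --out-dir out
nileach fit-release --immersion out/immersion_0.csv --a-surf 11 --out out/release_0.json
nileach calibrate --biodistribution out/biodistribution_0.csv \
    --release out/release_0.json --out out/fit_0.json
nileach montecarlo --fits out/fit_0.json,out/fit_1.json \
    --release out/release_2.json --out out/ensemble.csv
nileach ti-report --release out/release_0.json --fit out/fit_0.json --out out/ti.json
```

Each command writes a manifest (config hash, seed, version) next to its
artifact. `calibrate --exclude-compartments gut,feces` (the default)
controls which compartments enter the objective.

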