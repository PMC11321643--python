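# Methods

## Model

Dissolved O2 in the media column of a culture vessel is modelled as 1-D
unsteady diffusion with a Robin (mass-transfer) boundary at the gas–media
interface and a no-flux boundary at the vessel bottom, plus Michaelis–
Menten cellular consumption:

    ∂C/∂t = D ∂²C/∂x² − R(C),   0 < x < L
    ∂C/∂x(0, t) = 0
    −D ∂C/∂x(L, t) = kL (C(L, t) − Cgas(t))
    R(C) = Vmax_vol · C / (Km + C)

Assumptions: the column is stagnant (no convection, evaporation or
meniscus effects), isothermal at 37 °C, and laterally uniform; the
incubator gas phase is an infinite reservoir at the setpoint; cell density
is constant over a run (growth is not modelled; a density-vs-time input is
out of scope for this version); O2–CO2/pH coupling is ignored.

`C` is carried internally in % O2, the unit incubators and optical sensors
report.  Two linear constants connect the reporting units: 7.7 mmHg per
% O2 and a Henry-law solubility of 1.27 µM/mmHg (medium at 37 °C).  The
solubility matters only where molar quantities (Km, per-cell consumption)
meet the % O2 field; both constants are configurable and the model's
structure is independent of their values.

### Consumption localisation

The consumption term is volumetric as written, but adherent cells sit on
the vessel floor.  Two modes are implemented:

* `monolayer` (default for adherent work): the sink is confined to the
  bottom finite-volume cell with areal rate
  `density · vmax_per_cell · C_b/(Km + C_b)`, where `C_b` is the
  concentration extrapolated to the vessel floor.  As Δx → 0 this
  converges to a flux boundary condition at x = 0.
* `suspension`: the sink is uniform over the column with volumetric
  saturation rate `density · vmax_per_cell` (density per mL ≡ per cm³).

Unit chain: amol·cell⁻¹·s⁻¹ × density → mol·cm⁻²·s⁻¹ (monolayer) or
mol·cm⁻³·s⁻¹ (suspension) → %O2·cm/h or %O2/h through the solubility
constants; Km is converted µM → %O2 once per run.  The Michaelis–Menten
factor is evaluated with C clamped at 0 and no smoothing.

## Numerics

**Spatial discretisation.** Cell-centered finite volumes (default 64
cells).  This is algebraically equivalent to second-order central
differences with ghost nodes but conserves mass exactly at the discrete
level, which makes the mass-balance checks sharp.  The Robin condition is
closed by eliminating the interface concentration
`C_s = (kL·Cgas + (2D/Δx)·C_top) / (kL + 2D/Δx)`, i.e. series resistance
of the surface film and the half-cell of medium.  The pericellular value
is reported as the second-order extrapolation of the two bottom cell
centers to the floor (clamped at 0); using the same value inside the
monolayer sink makes the discrete steady state match the continuous
two-resistance balance to second order.

**Time integration.** Method of lines with `scipy.integrate.solve_ivp`
(BDF, rtol 1e−6, atol 1e−9, tridiagonal Jacobian sparsity).  Setpoint
changes and consumption-scale events are handled by restarting the
integrator at the exact discontinuity times, never by step rejection.
Tiny negative excursions are clamped to 0 after each segment and the
clamped mass is recorded on the result.

**Analytic cross-check.** For the cell-free problem the dimensionless
deficit has the classical slab series

    Θ(ζ, τ) = Σ_m 2 sin λ_m e^{−λ_m² τ} cos(λ_m ζ) / (cos λ_m sin λ_m + λ_m)

with `λ tan λ = Bi`.  The eigencondition follows from the Robin boundary
in dimensionless form and is verified *numerically* against the PDE solver
(RMS < 1e−3 in Θ over Bi ∈ {0.1, 1, 10, 100}) rather than assumed.  Roots
are bracketed in ((m−1)π, (m−1)π + π/2) and solved as
`λ sin λ − Bi cos λ = 0` (continuous across the bracket) to residuals
< 1e−10.  Default truncation is 50 terms with a warning when the bound on
the first neglected term exceeds 1e−8 at the requested τ; note Θ(τ) can
decay no faster than `e^{−λ₁²τ}`, so "fully equilibrated" is
Bi-dependent.

**Steady states.** Two independent paths, cross-checked in the tests to
< 1e−3 %O2: (a) the time-independent problem — a closed-form
two-resistance balance for monolayers (root of
`kL(Cgas − C_b − F(C_b)L/D) = F(C_b)`; the profile above the cells is
linear), `scipy.integrate.solve_bvp` for suspensions — and (b) long-time
integration until max|dC/dt| < 1e−6 %O2/h.

## Parameters

| parameter | units | default | basis |
|---|---|---|---|
| D | cm²/h | 0.09684 | literature diffusivity of O2 in medium at 37 °C |
| kL | cm/h | 0.1 | order of magnitude for a stagnant film; fit per setup |
| Vmax (per cell) | amol·cell⁻¹·s⁻¹ | 450 | breast-epithelial respirometry scale |
| Km | µM | 1 | mitochondrial half-saturation, literature constant |
| mmHg per % | mmHg/% | 7.7 | sea-level conversion |
| solubility | µM/mmHg | 1.27 | medium at 37 °C |
| anoxia threshold | % O2 | 0.5 | operational sensor-floor definition |
| time-to-threshold band | % O2 | 0.1 | optical-sensor resolution; an asymptotic approach needs a finite band |

Vessel growth areas (96-well 0.32, 24-well 1.9, 12-well 3.8, 6-well 9.6,
60 mm 21.5, T25 25, T75 75 cm²) are manufacturer-standard defaults, all
overridable.

## Estimation

Both fits are bounded nonlinear least squares in % O2
(`scipy.optimize.least_squares`, trust-region reflective; soft-L1 loss by
flag) with 5 log-spaced starts screened by SSE before the single
trust-region run.  Sensor noise is treated as homoscedastic, which matches
optical sensors away from their floor.

* **kL** from a cell-free equilibration trace.  With a constant setpoint
  the forward model is the analytic series (exact for the same PDE; a test
  asserts the analytic and numeric forward models give the same estimate);
  `forward="numeric"` uses the solver, which also handles stepped
  schedules.  Constant traces and C0 = Cgas raise non-identifiability
  errors.
* **Vmax** (optionally Km) from a pericellular trace with transport fixed.
  Km is fixed at its literature value by default: near-anoxic traces carry
  almost no Km information, and a fully anoxic trace bounds Vmax only from
  below — the fit warns and records the warning.

Uncertainty: residual-resampling bootstrap percentile intervals (90 %
nominal), refitting each resample from the point estimate.  A desk-scale
coverage study (20 synthetic replicates × 60 resamples at 0.05 %O2 noise)
keeps empirical coverage ≥ 80 %.

## Synthetic traces

`generate_synthetic_trace` emulates an optical dissolved-O2 sensor: the
forward model sampled at a fixed interval plus i.i.d. Gaussian noise
(default studies use σ = 0.05 %O2, a typical optical-sensor floor),
clipped at 0, deterministic per seed.  It does **not** emulate sensor
drift, temperature compensation artefacts, photobleaching, or convection
in the real column — parameter-recovery results therefore demonstrate
identifiability under the model's own assumptions, not robustness to
real-world model error.

## Design utilities

Setpoint inversion exploits that pericellular O2 is monotone increasing in
the setpoint (asserted on a coarse scan before bisection; 0.01 %O2
tolerance, bracket [target, 21 %]).  "Steady" planning predictions default
to a 48 h horizon, long enough for every standard vessel to pass its
transport transient.  Anoxia is flagged below 0.5 %O2 with the
interpolated first-crossing time; 1–2 %O2 is labelled hypoxic.

A consequence worth knowing: with the stagnant-film default kL = 0.1 cm/h
and default kinetics, a 30 000 cells/cm² monolayer in a 24-well (1 mL)
cannot be held at 1.5 % pericellular by any setpoint ≤ 21 % — the required
flux implies a >25 % O2 drop across the diffusive resistance L/D alone.
`solve_setpoint` returns an explicit infeasible result with the achievable
bound in such cases.  Real incubators with door events and tray vibration
can have substantially larger effective kL; fit kL for quantitative use.

## Problem sizes

Default runs use 64 spatial cells; fitting studies and planning grids use
32 cells and 12–24 h traces at 15 min sampling, which keeps every
simulation under ~0.1 s while leaving discretisation error far below
sensor noise (the 16→32-cell RMS error ratio test confirms second-order
convergence).  Recovery studies use 20 noise seeds; the bootstrap coverage
study uses 20 replicates × 60 resamples.

## Known limitations

* No convective mixing: effective transport in real incubators (door
  openings, vibration) can exceed the stagnant-film default several-fold;
  kL should be fitted per setup for quantitative predictions.
* Constant density: multi-day runs with proliferating (or dying) cells
  violate this; predicted drawdown is then a lower (upper) bound.
* 1-D: meniscus and edge effects in small wells are not represented.
* The monolayer sink occupies the bottom grid cell, so sub-cell-scale
  boundary-layer structure (<Δx ≈ 80 µm at defaults) is unresolved —
  comparable to a confluent cell layer's own thickness.
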