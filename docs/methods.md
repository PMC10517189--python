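# Methods

This note documents the models, conventions and numerical choices behind
fluctlight, and what the synthetic fixtures do and do not establish about
real measurements.

## Cuvette mass balance and the dynamic correction

An open gas-exchange cuvette at steady state obeys
`A = u·(C_ref − C_s)/S`: inflow at reference mole fraction `C_ref`,
outflow at sample mole fraction `C_s`, flow `u`, leaf area `S`. Under
changing light the headspace itself stores or releases gas, and the
steady-state equation misattributes that storage to the leaf. With the
ideal-gas mole count `n = PV/RT` of the chamber (volume
`V = 8.67e-5 m³`), the instantaneous balance is

    A_true(t) = u·(C_ref − C_s)/S − (n/S)·dC_s/dt.

The correction therefore adds `−(n/S)·ΔCO2_s/Δt` to the logged rate, with
the derivative taken as a backward first difference over the inter-log
interval (mirroring per-log instrument arithmetic; the first record gets
zero storage flux). The H2O/transpiration term is identical with a
positive sign, because transpiration adds gas to the headspace while
assimilation removes it. The composite sign convention — corrected rate =
steady-state rate + storage flux as written above — is fixed by requiring
that a known assimilation profile pushed through the simulated cuvette is
recovered.

Accuracy: with 2-Hz logs, 600 µmol s⁻¹ flow and the default chamber
(mixing constant n/u ≈ 5.9 s), the corrected trace recovers a fluctuating
true profile to ≤ 0.12 µmol m⁻² s⁻¹ once three mixing constants have
elapsed, versus ≈ 1.4 µmol m⁻² s⁻¹ uncorrected; the residual error
vanishes as the mixing constant shrinks. No smoothing is applied to the
concentration series before differencing (an optional boxcar width exists
in the API, default off). The 0.5-s instrument averaging window behind
each log is ignored; each log is treated as an instantaneous sample.

## Steady-state light responses

* **Rd** is the negated OLS intercept of A against incident PFD over the
  quasi-linear levels {75, 100, 200} µmol m⁻² s⁻¹ (configurable); 0 and
  30 are always excluded to avoid the Kok-effect bend. Negative estimates
  are reported with a warning, never clamped. On a strongly curved
  response (NRH curvature θ ≈ 0.7 with a high initial slope) this
  intercept is biased low by the curvature of the 75–200 limb — by up to
  ~1 µmol m⁻² s⁻¹ on the synthetic roster — which is inherent to the
  intercept method, not a defect of the regression; the bias shrinks as
  the limb approaches linearity (φ·200 ≪ A_max recovers Rd within 5%).
* **NRH fit**: bounded least squares over (φ, A_max, θ, Rd) with
  θ ∈ (0, 1], initialised from the low-light slope, max(A)+Rd and
  θ = 0.7. θ → 1 reduces exactly to the Blackman form
  min(φI, A_max) − Rd and θ → 0 to the rectangular hyperbola
  φI·A_max/(φI + A_max) − Rd (evaluated analytically below θ = 1e-9).
  The NRH Rd is descriptive only; the regression Rd above is the one used
  in quantum-yield arithmetic, being the more specific procedure.
* **Quantum yield**: ΦCO2 = (A + Rd)/PFD_abs, with PFD_abs = incident
  PFD × L_abs and L_abs = 0.9·L_red + 0.1·L_blue the source-weighted
  scalar absorptance (L = 1 − T − R per band). Per-species band
  absorptances come from configuration; synthetic fixtures default to
  0.85/0.85. Whether absorptance should be applied per band separately or
  as this weighted scalar is an open choice; the weighted scalar is used
  throughout.

## Fluctuation analysis

Traces are windowed to [3000, 3600) s — the last ten minutes of the
one-hour treatment, excluding initial induction — and segmented by the
*commanded* program (phase boundaries every step duration from treatment
start), not by measured PFD, since 2-Hz logs straddle switches; a
consistency warning fires if measured PFD contradicts the command for
more than 10% of samples. Samples belong to the half-open step
[switch, switch + d); additionally the sample falling exactly on the
closing switch is appended to the step's integration series (t_rel = d).
This closing-sample convention exists because the trapezoidal mean of a
step otherwise covers only d minus one sampling interval, which biases
the mean of a decaying exponential upward by ~1% at d = 6 s. For
physically continuous corrected traces the closing sample is unambiguous;
only an artificial discontinuous square wave can straddle it, at a cost
of at most one sample interval's worth of area.

Relative assimilation is computed pointwise (100·A_dyn/A_ss of the
matching phase) and AUC-averaged per step with the trapezoidal rule over
the observed span; per-phase values are unweighted means across the steps
in the window, and species-level statistics are unweighted means across
replicates. Because the reference is constant within a phase,
average-then-ratio would be algebraically identical. Sub-100% and
negative relative values enter the averages as-is.

ΦCO2 within fluctuation phases uses the commanded phase PFD converted to
absorbed PFD, and the matching-O2 regression Rd of the steady-state
reference. The PIB windows are half-open [10, 30) s (30-s steps) and
[10, 70) s (300-s steps) after the high→low switch; 6-s steps return a
not-applicable signal since the burst needs ≥ 10 s to express. The
decoupling excess is the signed difference between the low-phase mean
ΦCO2 and the pathway-specific theoretical maximum (0.111, 0.064 or 0.075
CO2/photon); only positive values are evidence of decoupling.

## Factorial ANOVA

Each genus is an independent experiment. Steady-state parameters:
two-way pathway × O2 ANOVA, Type-II sums of squares (identical to Type I
on these balanced designs; unbalance triggers a warning and Type II is
reported anyway). Fluctuation metrics: three-way pathway × length × O2
with fluctuation length entered as a 1-df continuous covariate, so a
balanced 2 × 3 × 2, n = 5 design leaves 52 residual df (a categorical
length would leave 48). Adding steady state as an extra pseudo-length for
the ΦCO2 analysis is supported but changes the residual df and is
flagged. P-values are printed to two decimals with a "≤ 0.001" floor; no
multiple-testing correction is applied.

## The synthetic generator

The generator exists so that every stage of the analysis has a ground
truth. It emulates the study conditions: 2-Hz logs over one hour of
800 ↔ 100 µmol m⁻² s⁻¹ steps of 6, 30 or 300 s after acclimation at
150 µmol m⁻² s⁻¹, at 21% and 2% O2, five replicates, for three C3/C4
pairs anchored to published per-species steady-state means.

*Leaf layer.* Within each step the true rate relaxes exponentially to the
phase's steady value — induction constant τ_ind on the way up, buffering
constant τ_buf on the way down — continuously across switches. Defaults:
τ_ind 40 s (C4) vs 15 s (C3); τ_buf 30 s (C4) vs 5 s (C3), which
reproduces the qualitative C4-over-C3 low-phase ordering. C3 leaves at
21% O2 get a PIB dip `pib_amp·(t/20)·e^(1−t/20)` (amplitude 1.5
µmol m⁻² s⁻¹, peak 20 s, forced to zero at 2% O2); the NAD-ME species
gets a high-onset CO2 gulp/burst pulse pair (amplitudes 2.0/1.5, peaks
3/15 s) regardless of O2, as that transient is not photorespiratory.
These are shape-level stand-ins chosen once for realism; they are not
estimates for any real species, and none of the time constants should be
read as measurements.

*Cuvette layer.* A first-order mixing chamber, `n·dC/dt =
u(C_ref − C) − A·S`, integrated by explicit Euler at 0.05 s (stable and
fast given the ≈ 6 s mixing constant; implemented as a linear recursion
evaluated with an IIR filter). Logged `a_raw` is back-computed from the
steady-state flux equation plus Gaussian noise (σ = 0.15 µmol m⁻² s⁻¹)
at a fixed seed. Flow 600 µmol s⁻¹, reference CO2 410 µmol mol⁻¹, leaf
area 6 cm². Ci and gsw are smooth placeholders; no stomatal dynamics,
humidity control loops, IRGA lag or leak corrections are modelled.

*Light curves.* 14-level tables on the standard descending gradient,
generated from an NRH whose φ and A_max are solved so the curve passes
exactly through the species' 800- and 100-PFD anchor means with the
anchor Rd. Generating curvature is θ = 0.9: flatter low-light limbs keep
the intercept-based Rd regression close to truth, whereas θ = 0.7 curves
drive it negative for most roster species (see above).

*Closed-form oracle.* For the pulse-free two-exponential leaf in its
periodic steady state, the low-phase relative mean has the closed form
`100·[a_L + (y − a_L)·τ_b(1 − e^(−d/τ_b))/d]/a_L`, where the periodic
entry rates solve a 2 × 2 fixed point in e^(−d/τ_ind) and e^(−d/τ_b).
The full pipeline (generator → cuvette → correction → segmentation → AUC)
reproduces this within 1% across d ∈ {6, 30, 300} s and
τ_b ∈ {10, 30, 60} s. A 5-s decay at 6-s steps exceeds 1% purely from
2-Hz discretisation, which is why the C3 default is outside the recovery
family.

## What the fixtures do and do not show

Passing tests establish that the implementation computes the intended
quantities: the correction inverts the simulated mixing chamber, the
metrics recover known generator kinetics, the df bookkeeping matches the
designs, and the qualitative C4/C3, duration and O2 patterns are
reproduced *given* generator parameters chosen to embody them. They do
not validate the phenomenological kinetics against real leaves, estimate
any biological parameter, or reproduce measured fluctuating-light
datasets (none are bundled). Real instrument data additionally contain
IRGA drift and matching offsets, stomatal dynamics, leak and dilution
effects, and logging jitter, none of which the generator emulates.

## Problem sizes

The bundled demo grid is 3 genera × 2 pathways × 2 O2 × 3 durations ×
5 replicates = 180 one-hour traces at 2 Hz (7,200 logs each, simulated at
0.05-s internal resolution), plus 120 light-response tables; it completes
in a few seconds. The acceptance script's targets use one 600-s
correction oracle trace, nine one-hour closed-form recovery traces, 36
single-replicate fixture traces for the qualitative margins, 500-point
irregular AUC samples against a 400,001-point fine grid, and the standard
n = 5 ANOVA designs.
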