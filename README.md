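# fluctlight

Analysis of leaf gas exchange under fluctuating light, built for comparing
C3 and C4 photosynthesis.

Leaves in real canopies see light that switches on a seconds-to-minutes
scale, and C3 and C4 leaves respond differently: the large metabolite
pools that drive the C4 carbon-concentrating mechanism can buffer
assimilation through low-light periods, while C3 leaves show a
photorespiratory post-illumination CO2 burst (PIB) after each high-to-low
transition. Quantifying this from open-cuvette measurements takes several
coupled steps, which this package implements as a tested pipeline:

1. **Dynamic storage-flux correction.** Under changing light the
   instrument's steady-state rate equations are biased by gas storage in
   the cuvette headspace. Per log interval the correction adds the
   ideal-gas storage term back onto the reported rates:

   `A_dyn = A_raw − (P·V)/(R·T) · ΔCO2_s / (Δt · S)`

   with cuvette volume `V = 8.67e-5 m3`, pressure `P`, temperature `T`,
   leaf area `S`, and `ΔCO2_s` the change in sample CO2 mole fraction
   since the previous log (the H2O term enters with the opposite sign).
2. **Steady-state references.** From a 14-level light-response table the
   package estimates day respiration `Rd` (OLS intercept over the
   quasi-linear levels, excluding 0 and 30 µmol m⁻² s⁻¹ to avoid the Kok
   bend), fits the nonrectangular hyperbola
   `A(I) = [φI + A_max − √((φI + A_max)² − 4θφI·A_max)]/(2θ) − Rd`,
   and computes quantum yields `ΦCO2 = (A + Rd)/PFD_abs`, where absorbed
   PFD uses a 90/10 red/blue source-weighted leaf absorptance.
3. **Fluctuation metrics.** One-hour traces of repetitive 800 ↔ 100
   µmol m⁻² s⁻¹ PFD steps (6, 30 or 300 s per step, 2-Hz logging) are
   windowed to minutes 50–60, cut into commanded steps, and summarised per
   phase as trapezoidal AUC means of assimilation relative to steady state
   (% of the matching 800- or 100-PFD reference rate) and of ΦCO2. The PIB
   window (10–30 s or 10–70 s after the high→low switch) is scored
   separately, and the low-phase ΦCO2 is compared against the pathway's
   theoretical maximum (0.111 CO2/photon for C3, 0.064 for NADP-ME and
   NAD-ME, 0.075 for NADP-ME-PEPCK): a positive excess is conservative
   evidence that CO2 fixation was decoupled from concurrent photochemistry.
4. **Reporting.** Two-way (pathway × O2) and three-way (pathway ×
   fluctuation length × O2, length as a continuous covariate) Type-II
   ANOVAs per genus, plus mean ± SEM summary tables.

Because instrument data of this kind are rarely shared, the package ships
a first-class synthetic generator: phenomenological two-exponential leaf
kinetics (with PIB and NAD-ME gulp/burst transients) pushed through a
first-order mixing-cuvette model, anchored to published steady-state means
for three phylogenetically paired C3/C4 species from *Alloteropsis*,
*Flaveria* and *Cleome* at 21% and 2% O2. Every analysis step is testable
against the generator's known ground truth.

## Worked example

```sh
fluctlight simulate --species G_gynandra --regime step30 --o2 0.21 \
    --seed 1 --out trace.csv --light-curve-out lrc.csv
fluctlight correct --in trace.csv --out corrected.csv
fluctlight fluct --trace corrected.csv --lrc lrc.csv \
    --species G_gynandra --regime step30 --out metrics.csv
```

`metrics.csv` then holds (rounded):

| rel_a_mean_high | rel_a_mean_low | phi_mean_low | pib_rel_a | decoupling_excess |
|---|---|---|---|---|
| 49.0 | 330.2 | 0.136 | 291.1 | 0.072 |

Read: during the 30-s low-light steps this NAD-ME C4 leaf assimilates at
330% of its 100-PFD steady-state rate (the buffered metabolite pools keep
fixing carbon), while during the high steps it only reaches 49% of the
800-PFD rate (slow induction). Its low-phase quantum yield, 0.136
CO2/photon, exceeds the 0.064 theoretical C4 maximum by 0.072 — fixation
decoupled from instantaneous light capture. A C3 partner run the same way
shows a PIB window mean *below* 100% at 21% O2 that recovers at 2% O2.

The full demo grid (3 genera × 2 pathways × 2 O2 × 3 durations × 5
replicates) runs with `fluctlight run --demo --seed 1 --out-dir results/demo`
and writes tidy reference, metric, ANOVA and summary tables plus a
manifest; a repeat run with the same config is byte-identical.

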