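# Methods

`spraydry` models the outlet drying-gas temperature (Tout) of a benchtop
glass-tower spray dryer and maps it over the equipment's feasible operating
volume.  This note records the model, its assumptions, the numerical
choices, and the places where the design was genuinely open.

## The balance

The dryer is treated as a vertical cylinder in steady state with the drying
gas as an ideal gas.  The overall balance between the inlet and outlet
probes is

    Qin = Qfeed + Qloss + Qout,

with

* `Qin = Gin·cp(Tin)·Tin` and `Qout = Gin·cp(Tout)·Tout` — enthalpy rates of
  the gas stream (flows converted internally to kg/s; all computation SI).
  `cp` is a linear fit `a + b·T` (a = 969.8 J·kg⁻¹·K⁻¹,
  b = 0.116 J·kg⁻¹·K⁻²) to tabulated dry-air specific heat over 300–500 K;
  residuals stay below 0.3% on that window.  By default cp is evaluated
  per stream (at Tin for Qin, at Tout for Qout); a config switch
  (`cp_mode: average`) evaluates both at Tavg = (Tin+Tout)/2.
* `Qfeed = FR·[c_w·(T_wb − Text) + (1 − cfeed)·λ(T_wb)]` — sensible heating
  of the feed droplets from ambient to the wet-bulb temperature of the
  drying gas plus latent vaporization of the solvent fraction.  The
  wet-bulb temperature solves the adiabatic-saturation balance
  `(cp + w·cp_v)(T_db − T_wb) = (w_s(T_wb) − w)·λ(T_wb)` with the
  dehumidified-inlet humidity w = 0.003 kg/kg (configurable); the root is
  bracketed below the ambient-pressure boiling point, where the
  mixing-ratio algebra degenerates.  λ(T) is linear in T
  (2.501 MJ/kg at 273.15 K, slope −2444 J·kg⁻¹·K⁻¹), within 1% of steam
  tables over 273–373 K.  The feed is assumed to enter at ambient
  temperature (the feed line is unheated), and the atomization-gas
  enthalpy is not added to the balance (the balance contains no such
  term; its neglect is one known limitation).
* `QlossR = (Tavg − Textwall)/(R_conv + R_cond)` — internal forced
  convection in series with conduction through the 4 mm glass wall.  The
  film coefficient uses Dittus–Boelter (`Nu = 0.023·Re^0.8·Pr^0.4`,
  Gnielinski available by config) evaluated at Tavg, with the superficial
  tower velocity in Re (`Re = 4ṁ/(πDμ)`) and the tower diameter as the
  characteristic length.  At these flows Re ≈ 1000–3500, so h_i is small
  (≈1–3 W·m⁻²·K⁻¹) and radiation dominates the loss.
* `Qlossrad = A_ext·σ·ε·(Textwall⁴ − Text⁴)` — Stefan–Boltzmann radiation
  from the outer glass surface (ε = 0.92 by default, configurable within
  the 0.62–0.95 range quoted for glass towers).

Default geometry: inner diameter 0.165 m, height 0.60 m, glass 4 mm with
k = 1.05 W·m⁻¹·K⁻¹ — nominal benchtop (B-290 class) tower dimensions, all
configurable in the versioned YAML config.

## Wall temperature: inversion and surrogate

`Textwall` is not instrumented.  For every measured run it is *derived* by
solving

    QlossR(Textwall) + Qlossrad(Textwall) = Qin − Qout − Qfeed

for Textwall, a strictly monotone scalar equation solved by Brent's method
on (Text, Tin).  Most labels land below Tavg; labels slightly above Tavg
(radiation carrying more than the through-wall term supplies) are
admitted, because the simplified network averages a wall that is locally
hotter near the inlet jet.  Records whose loss target falls outside the
attainable range are flagged, logged and excluded from training; with the
packaged fixtures and default geometry none are flagged.

A random forest (500 unpruned trees, seeded; scikit-learn) maps the five
process features (Tin, Text, RHext, FR, Gin) to the derived labels.  The
forest is evaluated on a seeded 80/20 split; because the packaged dataset
is only 28 runs, a leave-one-out mode is provided and used for pipeline
validation (a 20% test set would be six points).  Tree ensembles cannot
extrapolate beyond their training-label range, which bounds predictions
physically but also concentrates error at the corners of the design;
predictions are additionally clipped to (Text, Tin).

## Solving for Tout

Dividing the balance by `cp·Gin` gives the implicit relation
`Tout = h(Tout)` with

    h(T) = (Qin − Qfeed − Qloss(T, Textwall)) / (Gin·cp(T)).

The surrogate's Textwall depends only on the inputs and is held fixed
during iteration.  Plain fixed-point iteration from T₀ = Tin converges in
3–6 steps on all fixture conditions: the loss term is small against the
gas enthalpy, so |h′| ≈ 0.01–0.05.  Controls: at most 10 iterations,
tolerance 0.01 K (well under the ±1 K stability window the measurements
were recorded at), damping 1.0 with 0.5 auto-engaged if gaps grow, and a
non-converged result (never an exception) on persistent divergence.  After
tolerance convergence the same contraction map is iterated a few more
steps to machine precision so the reported energy breakdown closes to
better than 10⁻⁶ relative.

## The gas-flow basis of the atomizing table

The atomizing fixture prints both a gas flow `Gin` and the composite
variable `AD = FR/Gin`, and the two disagree systematically (e.g.
0.80/18.2 = 4.4×10⁻² vs the printed 3.27×10⁻²).  A first-law screen shows
the printed flows cannot balance the measured outlet temperatures: for the
high-feed rows, `Qin − Qout − Qfeed` is negative or below the network's
convective floor, i.e. the run would have to violate energy conservation.
The flow implied by the AD column (`FR/AD`) is feasible for every row and
agrees with the empty-run aspirator calibration at matching conditions
(e.g. 24.5 vs 23.8 kg/h at the hottest level, 100% aspirator).  The
package therefore carries both: the printed column (`Gin`) defines the
operating-region coordinates, and the AD-consistent flow
(`gin_effective`) feeds the balance and the surrogate features.  The
design-space mesh stays in the printed (indicated-flow) coordinates and
passes the node flow directly to the balance, a conservative convention
that slightly underestimates Tout at a node.

## Design space

The atomizing limits give, per inlet-temperature level, the Gin range and
the maximum feasible FR at each end of it.  The region interpolates these
limits piecewise-linearly in Tin and linearly in Gin between the two
measured anchors (clamped outside them); below the lowest measured level
the FR limits follow ordinary least-squares lines until the feasible FR
interval collapses to the 0.07 kg/h pump minimum — the region apex, at
353.7 K with the packaged limits (extrapolation-method-dependent; read
qualitatively).  A structured (Tin × FR × Gin) lattice is clipped to the
region, with per-axis resolutions calibrated to land within 5% of the
requested node count; the full 22 241-node mesh builds and solves in well
under a minute because the fixed-point iteration is vectorized across
nodes.  Sections: constant-Tin slices return the lattice face; constant-
Tout surfaces interpolate, per (FR, Gin) pair, the Tin at which the model
crosses the requested outlet temperature.

Two sensitivity diagnostics accompany the sections.  The per-unit-flow
leverage |∂Tout/∂FR| / |∂Tout/∂Gin| is 25–30 on constant-Tin faces — the
outlet temperature is governed by the evaporative load, with the gas flow
a weak lever.  The range-normalized comparison against the composite
variable AD, by contrast, does *not* show FR dominance (the AD axis spans
ten-fold on a slice, so its normalized sensitivity is large); the package
reports this fraction as a diagnostic rather than asserting it.  The
iso-Tout trade-off (ΔGin compensating a 0.1 kg/h feed change) computes to
≈2–3 kg/h on the hottest face.

## Synthetic data

The generator emulates the experimental design: conditions drawn inside
the operating region (a configurable fraction without feed, mirroring the
empty runs), ambient temperature and humidity drifting over laboratory
ranges (293–299 K, 22–45%), a named smooth wall-temperature truth
function, and measured Tout = forward balance + Gaussian noise
(default SD 1 K, the stability window of the recorded experiments).  What
it does not emulate: replicate structure, drift between sessions,
instrument quantization, or any wall-temperature physics beyond the truth
function — so passing recovery tests demonstrates that the inversion,
surrogate and solver are consistent with each other, not that the balance
captures every loss path of the real dryer.  With zero noise the label
derivation recovers the truth to 0.01 K at every record; at n = 200 and
1 K outlet noise the held-out outlet-temperature RMSE is ≈1.6 K.

## Validation scale and known limitations

Only 28 of the study's 74 experiments are printed, so all dataset-level
metric reproductions here are scaled-down re-runs: leave-one-out on 28
records gives atomizing MAE/RMSE ≈ 4.5/6.4 K and empty ≈ 5.2/6.2 K, with
near-zero mean bias — the gap to the original fit (1.74/2.15 and
3.34/4.04 K) is surrogate variance from the missing 46 training points,
concentrated at the corners of the design.  The external natural-
convection diagnostic (Churchill–Chu, vertical surface) evaluates to the
same order as radiation at the derived wall temperatures (≈65% of the
modeled wall loss), not a negligible share; with wall temperatures 50–100 K
above ambient no standard correlation makes free convection negligible, so
the model's Qloss decomposition should be read as an effective closure
rather than a complete loss inventory.  Other limitations: pure-water
feed physics only (no crust/falling-rate drying), steady state only, a
single lumped wall temperature, and no humidity output surface.
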