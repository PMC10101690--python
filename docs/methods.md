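# Methods

This note documents the models implemented in `treeflux`, the defaults and
units of the parameters that matter, what the synthetic-data generator does
and does not emulate, the numerical choices, and known limitations.

## Chamber model and flux inversion

A closed chamber whose sample air is replaced by ambient air leaking in
freely is modelled as a well-mixed volume with first-order relaxation:

    dC/dt = F·S·V_mol/V + q·(C_amb − C)

with C in ppm (μmol CO₂ per mol air), F the surface flux
(μmol m⁻² s⁻¹, positive out of the surface), S the exchange or leaf area
(m²), V the chamber volume (l), q the leak rate (s⁻¹) and V_mol the
ideal-gas molar volume of air at chamber temperature (24.055 l mol⁻¹ at
20 °C, 1 atm). The closed form

    C(t) = C_amb + F·k·(1 − e^{−qt})/q + (C₀ − C_amb)·e^{−qt},  k = S·V_mol/V

is used both by the forward simulator (exact solution, verified in the
tests against independent `solve_ivp` integration to 1e-9) and as the
regression model for inversion. The `(1 − e^{−qt})/q` term is evaluated via
`expm1` and degenerates smoothly to `t` as q → 0, so small leak rates are
numerically safe.

Inversion choices:

- **Shared leak rate.** q is physical, not isotopologue-specific, so both
  traces are fitted jointly: for any candidate q the model is linear in the
  per-trace parameters (F and the initial offset), which are solved by
  least squares; q itself is found by bounded 1-D minimization of the
  pooled SSR over log q ∈ [log 1e-8, log 0.5]. This has the same optimum as
  a joint non-linear fit but no multi-start fragility, and an optimum at
  the lower q bound reduces exactly to the linear-slope estimator (flagged
  `q_at_bound`).
- **Ambient concentration is fixed, not fitted.** A single exponential
  trace determines only three quantities (initial value, asymptote, rate);
  with q free, (q, F, C_amb) are not jointly identifiable. C_amb is pinned
  to the sample at closure start, where the trace has not yet evolved. The
  resulting flux error from one noisy sample is q·σ/k — of order 1e-4
  μmol m⁻² s⁻¹ at the default geometries, negligible against fit noise.
- **Fit windows** exclude the pressure transient after closing: shoot
  5–50 s, stem 10–40 s, soil 40–200 s (configurable per chamber).
- **Flags.** `zero_flux` (|F₁₂| below 1e-4 by default → δ undefined),
  `q_at_bound`, `non_convergent` (excluded from aggregation).
- Mass-flow corrections for the soil chamber and xylem-transport/storage
  corrections to stem efflux are deliberately omitted (their contributions
  are reported as insignificant for this chamber class).

δ¹³C of a flux is the flux ratio in δ-notation against V-PDB
(R_std = 0.0111802, the conventional value). Reference-gas calibration maps
measured δ through a two-point (or least-squares) line; the implemented
default pair is −19 and −3.1 ‰. Daily aggregation: closures with PAR <
30 μmol m⁻² s⁻¹ count as nighttime; A_shoot averages daytime closures,
R_stem nighttime, R_soil all; daily δ¹³C is Σ(Fᵢδᵢ)/ΣFᵢ. Days without
usable closures are emitted as missing, never zero. The day boundary is the
calendar day of closure start.

## Synthetic season

The generator emulates one growing season (default 15 Apr – 30 Sep) of a
high-boreal pine stand at half-hourly resolution:

- **Drivers.** Air temperature = seasonal sinusoid + diurnal cycle + AR(1)
  daily anomaly; soil temperature a 7-day-smoothed, damped version; PAR a
  photoperiod half-sine with daily cloudiness (exactly zero at night, with
  a latitude-appropriate day length of ~19 h at solstice); precipitation as
  random events suppressed during a configured dry window; soil moisture
  relaxes toward 0.30 m³ m⁻³ with rain recharge and declines monotonically
  to ~0.10 through the dry window (default 16 Aug – 11 Sep), recovering
  afterwards.
- **True fluxes.** Stem efflux a·e^{bT}·(1 + c_g·g(t)) with a = 0.25,
  b = 0.0693 °C⁻¹ (Q10 = 2) and g(t) the normalized tracheid growth-rate
  truth (coupling c_g = 1); soil efflux a moisture-modulated exponential of
  soil temperature times a root-growth term; shoot influx a saturating
  light response with a seasonal amplitude envelope. Magnitudes fall in the
  0.1–3 μmol m⁻² s⁻¹ range typical of boreal chamber records.
- **δ¹³C truth.** Daily assimilate δ¹³C = −26.5 ‰ base + 1 ‰ seasonal
  drift + 0.6 ‰ 21-day synoptic oscillation + drought enrichment (+2 ‰
  inside the dry window) + AR(1) day-to-day jitter (SD 0.5 ‰, φ = 0.6).
  Stem/soil efflux δ mixes the assimilate signal — delayed by the
  allocation lag (2 d stem, 4 d soil) and offset by the apparent
  respiratory fractionation (4.5 ‰ stem, 1.0 ‰ soil) — with a constant
  storage-pool δ; the mixing weight rises from 0.25 to 0.9 inside
  configured high-demand windows (maximum tracheid production/maturation
  and the dry period for the stem; root pulse periods I and III for soil).
- **Chambers.** Shoot 2.1 l / 0.01 m² leaf area / 60×65 s per day; stem
  2.5 l enclosing 0.1 m² of stem surface, 48×90 s; soil 80 l / 0.4 m²,
  8×840 s. Stem chamber geometry is a design choice (annular cuvettes
  enclose large stem area in little volume); it sets the signal-to-noise of
  stem δ¹³C. Analyzer noise defaults to 0.1 ppm SD on ¹²CO₂ and
  proportionally R_std× that on ¹³CO₂ (the instrument class does not
  publish isotopologue-resolved precision; both SDs are configurable).
- **Growth and NSC.** Five trees draw Gompertz truths (asymptote 40 cells
  per mm of previous ring ± 15% CV, inflection DOY 153 ± 4 d, rate
  0.067 d⁻¹; mature curve delayed 35 d at rate 0.050 d⁻¹, same asymptote —
  every cell matures) sampled weekly with noise of 5% of the asymptote.
  NSC pools follow piecewise-linear seasonal templates: phloem starch
  builds to 72 mg g⁻¹ and is remobilized to 26 mg g⁻¹ across the
  earlywood–latewood transition while sucrose rises; sucrose averages ~34%
  of the WSC sum; starch δ¹³C is buffered relative to sucrose/glucose.
  WSC is constructed per replicate as the exact sum of the sugar pools.
  Root elongation is three Gaussian pulses (6 Jun–12 Jul, 13 Jul–16 Aug,
  17 Aug–30 Sep) with scanner-specific weights mimicking the spatial
  heterogeneity of scanner installations.

What the generator does **not** emulate: instrument drift and pressure
transients (the fit windows exist for them, but the traces are clean inside
the window), autocorrelated analyzer noise, within-day δ¹³C variation of
assimilates, micro-site variability of soil chambers, or any attempt to
statistically match a specific station record. Passing recovery tests
therefore demonstrates correctness of the estimator chain under the stated
noise model, not field accuracy.

## Phenology

The Gompertz curve is fitted in the (A, t₀, κ) parameterization
y = A·exp(−exp(−κ(t − t₀))) — equivalent to the classical A·exp(−β·e^{−κt})
with β = e^{κt₀}, but numerically well scaled (β reaches 1e5 for realistic
mid-season inflections). Initialization: A from the sample maximum, κ and
t₀ from a log-linearized mid-rise regression; up to 7 jittered starts guard
against local minima; failures raise an error carrying best-so-far
diagnostics. Counts are first divided by each tree's previous-year ring
width (trees with missing width are excluded with a warning) and pooled per
date; per-tree normalized values are retained for the mixed models.

The active-phase series is ŷ_total − ŷ_mature clipped at zero (crossings
are warned about); the tracheid growth rate is the day-over-day increment
of the fitted **total** curve — new cells enter the active pool through
enlargement, so this matches the day-over-day increase of the active phases
while being non-negative by construction.

Period rules (all thresholds configurable, defaults in parentheses):
production/maturation = days with fitted rate ≥ f₁ (5%) of its maximum;
"maximum" periods use f₂ (75%); earlywood ends where ŷ_total reaches 60% of
the asymptote and latewood starts at 80%, the transition in between. The
mapping from fitted curves to printed period dates has no canonical
definition; these thresholds are free parameters and period dates should be
read as threshold-relative. Root periods: per-scanner 7-day centered moving
mean, runs above 0.15 mm d⁻¹ merged across gaps < 5 d and across scanners.

## Environmental response and association models

- Exponential temperature fit by non-linear least squares, initialized in
  log space (quartile-ratio fallback when fluxes are non-positive);
  Q10 = e^{10b}. Nightly temperature = mean air T over PAR-defined night
  hours of the calendar day.
- The 1-day lag shift pairs predictor day t with response day t+1 and drops
  the boundary day.
- Soil drivers are removed by additive OLS on soil temperature and
  moisture; near-collinear drivers (|r| > 0.999) produce a warning and a
  pseudo-inverse solution.
- Stand-average associations: OLS with day-of-year included and removed iff
  p ≥ 0.05 (the threshold is configurable); optional interaction terms are
  likewise dropped when non-significant; an exclusion-dates argument
  removes named sampling days (used when starch remobilization makes a
  day's δ¹³C uninterpretable as a substrate signal).
- Repeated measures: random-intercept mixed model (statsmodels `MixedLM`)
  fitted by REML — the default of the R mixed-model packages this class of
  analysis normally uses, and better calibrated than ML at n ≈ 30.
  p-values use a t reference with containment degrees of freedom
  n − p − (g − 1); for the canonical 5-trees × 6-dates design this gives
  30 observations and 23 df. Monte-Carlo calibration (1000 null
  replicates) puts the realized type-I error at ≈ 0.058 — the small
  anticonservatism expected of Wald tests that ignore variance-component
  uncertainty (no Kenward–Roger machinery exists in the Python stack).
  A singular random-effect variance triggers a plain-OLS fallback recorded
  in the result. R² is reported in the marginal/conditional
  variance-partition sense.
- No multiple-testing correction is applied anywhere: the models are
  reported table-style, one predictor at a time, as this analysis class
  conventionally does.

## Wavelet coherence

FFT-based Morlet CWT with ω₀ = 6 (period = 1.033·scale), dyadic scales at
12 voices/octave (defaults: periods 2–48 d), mean removal and zero padding
to the next power of two. Squared coherence uses the standard smoothing
operator — Gaussian of SD = scale in time (kernel truncated at 4σ and never
longer than the series) and a 0.6-octave boxcar across scales — applied to
the scale-normalized (cross-)spectra. Self-coherence is identically 1 by
construction, which the tests assert to 1e-9. The cone of influence is the
e-folding time √2·s. Phase convention: phase = arg S(W_x·W_y*) ∈ (−π, π];
y lagging x by L days at period P gives phase +2πL/P, so phases in (0, π)
mean x leads — the direction treated as physiologically meaningful when x
is the upstream (assimilation) signal.

Significance: surrogate pairs of independent AR(1) processes matched to
each series' lag-1 autocorrelation; null coherence values pooled over time
inside the cone per scale; mask = coherence above the per-scale (1 − α)
quantile, restricted to the cone. Defaults: α = 0.05, 300 surrogates in the
pipeline (1000 in the calibration experiments), seeded. Gaps are linearly
interpolated (ceiling 10% by default; interpolated dates are recorded in a
mask); leading/trailing gaps are trimmed.

Lead/lag summaries stratify by named growth period × period band
(defaults 4–8, 8–16, 16–32 d), reporting the significant fraction of
in-cone cells and, over significant leading cells, the circular-mean phase
and mean implied lag (phase·P/2π per cell).

## Validation experiment sizes

The recovery experiments (in `treeflux.evaluation`, shared by the test
suite and `scripts/acceptance.py`) use: a 45-point noise-free
flux/leak/chamber grid; a 100-day, 40-closures/day season for δ¹³C recovery
(all-day aggregation, so the full 40 closures inform each daily value);
200 simulated trees for Gompertz recovery; 1000 null replicates for LM,
LMM and coherence type-I calibration with 200-replicate sign-recovery runs
(effect sizes configured for ~99% nominal power, mirroring the strong
stand-level associations such designs are built to detect); 192-day series
for the coherence identities; and a full-season pipeline run for the
windowed-coupling check. In that end-to-end run the assimilate δ¹³C
day-to-day SD is set to 2 ‰ — the upper end of natural variability, and
conservative relative to observed seasonal efflux-δ¹³C swings of ~19 ‰ —
because the coupling must remain detectable through the ~1 ‰ day⁻¹
measurement noise that 0.1 ppm analyzer noise induces in daily flux-weighted
δ¹³C.

## Known limitations

- The chamber regression assumes a well-mixed volume and white analyzer
  noise; pressure-pumping transients are handled only by window exclusion.
- C_amb fixed at closure start makes per-closure flux errors from ambient
  drift of order q·ΔC/k; slow ambient drift within a closure is not
  modelled.
- Wald-t inference for the mixed model is mildly anticonservative
  (realized α ≈ 0.058 at the 30-obs design); exact small-sample df
  corrections are not available in the Python ecosystem.
- Wavelet significance assumes AR(1) null structure; strongly nonstationary
  noise (e.g., variance regime shifts) will mis-calibrate the mask.
- Period classification depends on free thresholds; printed period dates
  are not comparable across threshold settings.
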