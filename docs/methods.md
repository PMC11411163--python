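# Methods

## Model

`lysedyn` models a batch culture of engineered bacteria carrying an
inducible lysis circuit.  Three state variables are tracked: the density of
the therapeutic (lysing) strain *x*, the density of non-lysing escape
mutants *y* (both in the same arbitrary density units an OD600 reading
provides), and the per-cell concentration *p* of the toxin inside
therapeutic cells:

    dx/dt = (γ − α) x
    dy/dt = γ y
    dp/dt = β([AHL]) − (γ − α)⁺ p − δ p

with logistic growth γ = γ₀(1 − (x+y)/ρ_s), Hill-type lysis
α = α₀ pⁿ/(Kⁿ + pⁿ), and Hill-type induction β = β₀[AHL]ᵐ/(kᵐ + [AHL]ᵐ).
Assumptions:

* Carrying capacity ρ_s is due to crowding, shared by both strains; the
  core model has no nutrient depletion (see the substrate variant).
* Mutants are fully non-lysing and otherwise identical to the therapeutic
  strain, so the mutant fraction f = y/(x+y) obeys df/dt = α f (1 − f):
  selection for mutants is driven purely by the lysis rate.
* The inducer (AHL) is an external forcing, constant between program
  breakpoints: the strain neither produces nor degrades it.
* Growth dilutes the per-cell toxin; the dilution rate is clamped at zero
  (`(·)⁺`) so that a shrinking population does not concentrate toxin.
* Initial toxin p(0) = 0: cultures are refreshed from uninduced stocks.

### The positive-part ambiguity

The toxin-dilution term admits two readings: −(γ − α)⁺p (net growth of the
therapeutic strain dilutes toxin) and −(γ)⁺p (gross growth dilutes toxin).
The default is `net_growth`: once lysis outpaces growth the dilution stops,
producing a runaway toxin build-up and a sharp lysis crash, which matches
the observed phenomenology better than the `growth` reading (whose crashes
are shallow and self-limiting because falling density restores dilution).
Both readings are available via the `positive_part` argument of
`integrate`, `rhs` and the fitting models.

### Released-payload proxy

The payload delivered by lysis is proportional to the cumulative lysed
biomass.  The default proxy integrates the net loss rate of the therapeutic
strain, ∫(α − γ)⁺ x dt, which is zero while growth outpaces lysis; the
gross-flux alternative ∫α x dt is available via `integrand="lysis"`.  The
proportionality constant is set to 1 — absolute payload units are not
identifiable from growth curves — so only ratios of loads are meaningful,
and all strategy comparisons are reported as ratios.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| γ₀ | exponential-phase growth rate | 1.57 | h⁻¹ |
| ρ_s | carrying capacity | 0.33 | a.u. |
| α₀ | maximum lysis rate | 1.39 | h⁻¹ |
| K | lysis Hill threshold | 3.29 | a.u. toxin |
| n | lysis Hill cooperativity | 4.46 | – |
| β₀ | maximum toxin production | 6.1 | h⁻¹·a.u. |
| k | induction Hill threshold | 19 | nM |
| m | induction Hill cooperativity | 1 | – |
| δ | toxin degradation | 0.1 | h⁻¹ |
| μ | adaptive mutation rate (variant) | 10⁻⁷ | h⁻¹ |
| r_s | substrate utilisation (variant) | 4.17 | h⁻¹ |
| K_s | Monod half-saturation (variant) | 0.1 | normalised |

The growth/lysis block is the mean of fits of the model to plate-reader
growth curves of the reference circuit across inducer concentrations; the
induction Hill comes from an independent promoter calibration; δ is set a
priori in the slow-degradation range (batch experiments are too short to
constrain it).  The cooperativity n ≈ 4.5 reflects the oligomerisation
required for pore formation.  The lysis rate fitted directly from
fraction-vs-induction-time data (α = 2.1 h⁻¹) exceeds α₀ = 1.39 h⁻¹ from
the growth-curve fits; the trade-off and scheduling analyses use 2.1, the
crash-phenomenology simulation uses the growth-curve mean set, mirroring
the provenance of each number.

### Units of the induction threshold

The threshold k is quoted both in instrument arbitrary units and in nM in
the source characterisations; this package identifies the two scales 1:1
(k = 19 nM), so 100 nM of inducer is strongly saturating
(β(100 nM) = 5.13 h⁻¹).  The simulated crash phenomenology is sharply
sensitive to this effective induction level, because the quasi-steady toxin
β/(γ₀ + δ) sits very close to the lysis threshold K:

* at β ≈ 5.1 h⁻¹ (100 nM under the 1:1 identification) toxin crosses K at
  ≈1.2 h while the culture is still dilute — an early, shallow crash
  (peak 2.0 h, depth ≈12%, trough 5.5 h);
* at β ≈ 2.1 h⁻¹ (effective induction ≈10 threshold-units) the threshold
  crossing waits until the culture nears capacity — a deep, delayed crash
  (peak 3.2 h, depth ≈72%, trough 8.9 h), the shape associated with the
  experimentally observed ≈70% collapse.

No published conversion pins the effective scale, so the package keeps the
1:1 identification and exposes the sensitivity rather than calibrating a
hidden factor.  The same sensitivity propagates to the dynamic-vs-static
load ratio: a strongly saturating static reference crashes early from low
density and releases little, making the best pulsed schedule's advantage
over it very large (≈23× under the default sweep), whereas weaker effective
induction brings the ratio down to a few-fold.

## Numerical choices

* Direct forward Euler, default dt = 10⁻³ h, states hard-clamped at zero
  after each step (clamp events are counted on the trajectory).
  `integrate(..., check_convergence=True)` re-runs at dt/2 and warns when
  peak density, peak/trough times or the final mutant fraction move by more
  than 2% (relative).  The method is first-order: trajectory summaries
  carry O(dt) error, e.g. the mutant-fraction curve at dt = 10⁻³ h agrees
  with its quadrature closed form to ≈5×10⁻³ (relative), halving with dt.
* Quadrature for the fraction closed form and the load proxy is trapezoidal
  on the simulation grid, consistent with the integrator's first-order
  accuracy.
* Takeover threshold defaults to f ≥ 0.99 (crossing time linearly
  interpolated); the strategy sweep reports the best-vs-static ratio at
  thresholds {0.9, 0.99, 0.999} alongside, since "takeover" has no unique
  numeric definition.
* Growth-curve fits: bounded trust-region least squares with 16
  Latin-hypercube multi-starts (the objective is multi-modal in (K, n));
  x₀, y₀ are optimised on a log₁₀ scale within [10⁻¹², 1]; uncertainties
  are Gauss–Newton covariances at the optimum; replicates are stacked, not
  averaged.  An optional log-density loss balances the post-crash regime.
* The f(t_ind) law is exactly linear on the logit scale
  (logit f = logit f₀ + αt), so that fit is closed-form OLS with t-based
  intervals.

## Strategy sweep

Square-wave programs start each cycle with the ON segment.  The default
grid spans periods 0.5–24 h and on-durations 0.1–6 h (12 log-spaced values
each; cells with on-duration > period are invalid), amplitude 100 nM,
horizon 200 h.  Loads accumulate until takeover or the horizon, with the
identical truncation rule for the static reference.  The grid maximum is
reported with ties broken toward the shortest on-duration, then the
shortest period.

## Synthetic data

The generator emulates the plate-reader protocol the analysis assumes:
cultures refreshed to total density 0.01 a.u., 10-min sampling over 23 h,
technical triplicates, 8 log-spaced inducer levels (1–1000 nM), and a
measurement model of multiplicative lognormal noise (default CV 3%),
additive Gaussian baseline noise (SD 0.002 a.u.) and a constant blank
offset (0.04 a.u., subtractable).  Passaging series divide the densities by
the dilution factor while carrying the per-cell toxin over unchanged.  The
generator does not emulate: instrument drift, well-position or edge
effects, condensation artefacts, cross-well contamination, or biological
replicate variation in the parameters themselves.  Passing recovery tests
on these data therefore shows the estimators are correct and well-behaved
under the assumed noise structure, not that real plate-reader data meet
those assumptions.

## Variants

The three extensions (Monod substrate consumption, adaptive mutation
μ x flux, chemostat dilution of bacteria and inducer) are reconstructions
of the named model extensions: the Monod factor multiplies growth and
consumption is proportional to growth activity; dilution acts as a
chemostat washout with the inducer as a supplied state.  Each reduces
exactly to the core model in its parameter limit (r_s → 0 or K_s → 0 with
s = 1; μ → 0; d → 0 with fixed inducer), which the tests enforce.
`find_steady_state` integrates with a long horizon (cap 10⁴ h) until the
relative derivative norm max |dz_i|/(1+|z_i|) falls below 10⁻⁸,
distinguishing oscillatory non-convergence from divergence.

## Known limitations

* Deterministic ODEs only: no demographic stochasticity, so de novo mutant
  appearance is a continuous μx flux, not a jump process; extinction of
  sub-cell densities is not modelled.
* The payload proxy is relative; absolute dosing requires an external
  calibration.
* The crash phenomenology and the dynamic-advantage ratio depend strongly
  on the effective induction scale (see above); conclusions drawn at
  100 nM under the 1:1 unit identification should be read with that
  sensitivity in mind.
* Parameter uncertainties are local (Gauss–Newton); for the strongly
  correlated (K, n) pair they understate the true uncertainty.  A
  bootstrap-over-replicates gives a better picture when replicates are
  plentiful.
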