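# Methods

## Measurement model

### Oxygen incubations

Plankton metabolism is measured in four clear and four dark Winkler-type
bottles per campaign, benthic metabolism in four clear and four dark
bell-jars staked into the sediment; incubations last 2–4 h.  The volumetric
rate of each enclosure is the linear O₂ change (end − start)/duration.  Net
community production (NCP) is the mean light rate, aerobic respiration (R)
the magnitude of the mean dark rate, and GPP = NCP + R; the identity holds by
construction for every reported triple.  Replicates are aggregated as the
arithmetic mean of per-enclosure rates (not the rate of mean concentrations),
with the sample sd across enclosures as the dispersion; light and dark
enclosures may have different durations because rates are normalised per hour
before pairing.

Unit chain: volumetric rates are converted to areal rates by depth
integration for plankton (rate × 1000 L m⁻³ × depth, assuming a well-mixed
column — the sites are ≤ 0.5 m deep, so no light-attenuation profile is
applied) and by enclosed volume / basal footprint for the jars.  O₂ is
converted to C at 1:1 molar stoichiometry (×12/32); the photosynthetic and
respiratory quotients are exposed as configuration (`pq`, `rq`, both 1.0 by
default) because direct CO₂ measurements to constrain them are rarely
available.  Diel scaling multiplies GPP by the campaign's daytime length and
R by 24 h (respiration assumed constant over the day).

Degenerate inputs: net O₂ production in the dark (measurement noise) clips R
to 0 with a warning flag; a negative GPP after averaging is retained but
flagged.  When no observed daytime length exists, an astronomical
solar-declination day-length formula (Cooper approximation, no refraction) is
provided; it is undefined poleward of 66.5°.

### Vegetation harvests

Standing stock is the mean over fifteen 0.25 m² quadrats of dry weight per
m², times a plant-type C mass fraction: 0.45 for helophytes (*Phragmites*
type), 0.255 for halophytes (*Salicornia* spp.).  Interval net production is
the stock difference between consecutive campaigns divided by the interval.
Negative differences (senescence) are clipped to 0 by default — harvest
methods estimate production, and winter production in these systems is
essentially nil — but the raw signed value is logged and a `clip_negative`
flag makes the alternative reproducible; with clipping off, production mass
is exactly additive over concatenated intervals.  Uncertainty is propagated
as the sd of the difference of the two date means assuming independence.
Below-ground biomass, litter decomposition and allometric models are out of
scope.

### Core CH₄ fluxes

Intact cores (50 cm × 4 cm methacrylate tubes holding 5–10 cm sediment,
15–25 cm water, and an air headspace) accumulate CH₄ over 2–5 days; twelve
replicates per site and campaign.  The headspace ppm increase converts to
mass by the ideal gas law at the incubation temperature and 1 atm
(mol = ppm·10⁻⁶·PV/RT, ×12.011 g mol⁻¹), then to an areal daily rate by
dividing by the tube footprint and duration.  Dissolved CH₄ in the water
column (Henry's law) is ignored: the measurement is headspace accumulation
only.  Negative accumulation (net methanotrophy) is returned signed with a
warning.

### Response curves

The manipulation experiments are fit with the two families the field data
display: flux = a·e^{bT} in temperature and flux = a·x^b in conductivity.
The model family is an explicit argument, never selected automatically.
Fits are nonlinear least squares initialised from the corresponding
log-space linear regression; non-positive fluxes are excluded from the
log-space initialisation but retained in the refinement, and zero
conductivity points are dropped (power law undefined at 0) with a warning.
Fit strength is reported as the Pearson correlation r between observed and
fitted values — r is NaN when either side is constant — with a two-sided
t-transform p-value on n − 2 degrees of freedom, and asymptotic standard
errors from the curvature of the least-squares problem.  On noiseless
model-class data the fit recovers the generating parameters to ≲10⁻⁶ and
r = 1.

## Budgeting

Annual areal fluxes integrate dated daily rates with a period-weighted
trapezoid over the sampling dates, closing the gap from the last date back
to the first (modulo 365 d) with the mean of the two endpoint values so the
integral always spans a full 365-day year; a single date falls back to flat
extrapolation.  A constant rate therefore integrates exactly, and against a
daily-grid trapezoid of a seasonal sinusoid the bi-monthly estimate agrees
within 5%.  Records spanning two hydrological cycles are split into 365-day
windows anchored at the first sampling date and the per-cycle annual rates
averaged; how the original two-cycle study combined its cycles is not
documented, and this choice treats the cycles symmetrically.

The whole-wetland balance weights each process by the fraction of surface
where it runs:

    B = f_open (R_p + R_b + CH4 − GPP_p − GPP_b) − f_veg P_veg

with negative = net capture.  `open_water_fraction` defaults to
1 − vegetated_fraction.  CH₄ is weighted by the open-water fraction (cores
are taken where the plankton and benthos are measured); a `ch4_coverage`
switch exposes total-surface weighting since the convention is a genuine
judgement call.  Per-date open-water balances (R − GPP, plankton + benthos)
are reported unweighted.

CO₂-equivalents are computed on gas masses: the net CO₂-C exchange
(B − CH₄-C) × 44/12 plus the CH₄-C flux × 16/12 × 28, where 28 is the
100-year mass-based CH₄/CO₂ warming factor.  The mass basis matters: it
reproduces published (C, CO₂-eq) balance pairs for these systems to within
rounding, whereas weighting C masses directly by 28 does not.  The exact
algebraic inverse (`infer_ch4_from_balance_pair`) recovers the annual CH₄-C
flux implied by any such pair; forward∘inverse is an identity to 10⁻¹².

Landscape extrapolation multiplies areal balances by wetland-type surface
(Tn y⁻¹ = g m⁻² y⁻¹ × ha / 100); totals are exact sums and shares are
fractions of the signed C total.  Sediment burial, N₂O and lateral
hydrological C exchange are outside the budget.

## Synthetic data generator

The generator emulates the study conditions: three archetypes along the
salinity gradient (mean conductivities 56.6, 31.3 and 2.0 mS cm⁻¹; depths
0.45, 0.20 and 0.50 m; halophyte belts covering 37% of the two saline sites
and a 50% helophyte belt in the freshwater site), ten bi-monthly campaigns
over two hydrological cycles, sinusoidal water temperature (mean 18 °C,
amplitude 10 °C, peak 1 August), day length from the solar formula at
40.65° N, and unit-mean lognormal replicate noise at CV 0.2 (rates are
positive and right-skewed).

True daily rates follow base·e^{0.10(T−18)} per process, with respiration
and CH₄ additionally damped by (conductivity/site mean)^−0.8 and CH₄ using a
slightly steeper temperature exponent (0.12).  Baselines are calibrated to
the seasonal ranges and orderings reported for the Ebro Delta sites: the
brackish lagoon most productive (plankton GPP base 2500 mg C m⁻² d⁻¹ against
R 1600, reflecting respiration peaks well below the GPP peaks), the salt
marsh least productive with its sink carried by the *Salicornia* belt (peak
standing crop 450 g DW m⁻²), and the freshwater wetland vegetation-dominated
(reed peak 1400 g DW m⁻², within the range of *Phragmites* stands).  CH₄
baselines (4, 30, 40 mg C m⁻² d⁻¹ at 18 °C) put the freshwater site highest
and the salt marsh lowest.  Vegetation biomass follows a logistic green-up
(inflection late June) with linear autumn dieback to a winter minimum.

The generator writes observations by inverting the measurement model —
bottle O₂ end concentrations from true rates through the diel/geometry/
stoichiometry chain, headspace ppm through the ideal-gas model, quadrat
weights from the biomass trajectory — while the pipeline computes the
forward chain from independent code, so with CV = 0 every stage recovers the
truth to ~10⁻⁹ relative as a genuine round-trip test.  Manipulation mode
emits the factorial designs (temperatures 14/20/25/30 °C; salinity factors
1/5×–2× for the saline sites and 1/2×–5× for the freshwater site, acclimated
at 20 °C) with five replicate cores per level.  A single integer seed fixes
every emitted byte (stream keys are CRC32-derived, not `hash()`-derived).

What the generator does **not** emulate: within-site spatial heterogeneity
beyond campaign-level conductivity jitter, trophic-status dynamics (nutrient
pulses driving the observed interannual peaks), tidal forcing, ebullition,
or any site's exact annual numbers — the published landscape figures enter
only as desk-scale reference inputs, never as calibration targets for the
generator.  Passing end-to-end tests therefore demonstrate correctness of
the inference chain under the assumed statistical structure, not agreement
with any particular field dataset.

## Problem sizes and numerics

The default test-and-analysis configuration uses 3 sites × 10 campaigns,
16 bottles/jars + 12 cores + 15 quadrats per site-campaign, and 100
simulated experiments for parameter-recovery statistics; the full suite runs
in seconds.  Identities (GPP = NCP + R, budget conservation, GWP round
trips) are asserted at 10⁻⁹–10⁻¹² relative; curve-fit recovery uses median
error over 100 seeds (10% temperature, 15% salinity) and t-based 95%
intervals for the exponent cover the truth at 88–99% over 100 replicates.
Atomic masses are taken as 12/32 for the O₂→C step (matching the molar
bookkeeping convention of the budget, where 44/12 and 16/12 are exact
ratios) and 12.011 g mol⁻¹ in the ideal-gas CH₄ step.
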