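# Methods

## Scope and data model

`salpflux` assembles a per-cycle carbon budget from five field-style
tables: per-individual net-tow records, per-individual gut pigments,
sediment-trap samples with pellet morphometrics, paired ²³⁴Th/salinity
profiles, and dilution-experiment bottles plus a depth-resolved NPP
profile. One pipeline invocation treats one quasi-Lagrangian cycle
(3–7.5 days of repeat sampling of a tracked water parcel);
multi-cycle salp vs non-salp comparisons consume several cycle
summaries.

## Salp demography

Lengths are pooled into half-open [lo, hi) 5-mm bins spanning 1–136 mm;
individuals outside the range are clipped to the edge bins and logged,
so binning is count-conserving. For a 0–200 m double-oblique tow the
areal abundance is the volumetric concentration times the tow depth
(`count/volume × tow_depth`) — the conventional conversion when the tow
integrates the whole layer. Day and night tows are averaged separately
(unweighted by volume) and then combined; if one period is missing the
other is substituted with a warning so the 14/10-hour grazing weighting
stays defined. Bin midpoints stand in for all size-dependent rates.
Length–carbon coefficients for biomass are deliberately mandatory
configuration — published coefficients vary by region and stage, and a
silent default would be worse than an explicit error. The total-length →
oral–atrial-length correction is likewise a configurable linear factor;
the synthetic generator emits already-corrected lengths.

## Grazing and egestion

Gut pigment (chl a + phaeopigment, ng ind⁻¹) is fit as `Gpig = a·L^b`
by least squares in log-log space; records at or below detection are
dropped, and with fewer than three distinct lengths the fit falls back
to a flagged mean. Gut passage time is `GPT(h) = 2.607·ln(OAL) − 2.6`,
valid only above OAL ≈ 2.71 mm — smaller bins contribute zero grazing
and are logged. Temperature enters through Q10 = 2 factors with
explicit reference temperatures: the GPT relation's native temperature
is not documented, so its default `t_ref` equals the study ambient
(10 °C, factor 1 unless configured); the length-based pellet-production
relation was derived in Antarctic waters, so its default `t_ref` is
0 °C. Pigment-based grazing is converted to carbon with a configurable
C:chl ratio (default 50 g:g) applied to a configurable chl-equivalent
fraction (default 1 — no pigment-destruction correction, and
phaeopigment treated as chl equivalents); the pigment-unit result is
always reported alongside so the carbon conversion never hides the
measurement. Egestion is computed both ways: EE × grazing carbon
(EE = 0.36), and the length-based model
`0.5388·e^(−0.0212·L)` pellets h⁻¹ × `0.055·L^2.0665` µg C, summed over
bins with the same 14/10 day/night weighting.

## Trap fluxes and attenuation

Flux is collected mass over total tube area and deployment days; tubes
are pooled by mass, with a standard error reported when per-tube masses
are available. Attenuation is fit as `Flux(z) = F0·(z/z0)^−b` by
unweighted log-log least squares with `z0` the euphotic depth, so `F0`
is the flux at the euphotic-zone base and interpolation between depths
is geometric. An exponential alternative is provided purely to quantify
functional-form sensitivity; on noiseless power-law points spanning
70–300 m the two forms differ by ~8% at `z0`+100 m (regression-pinned in
the tests, not asserted small). Pellet volume uses a cylinder
`π·(w/2)²·L` by default (salp pellets are elongated; an ellipsoid rule
is available), and carbon follows the log-log C:V relation. Pellet
fractions above 1 are reported with a warning rather than capped.

## ²³⁴Th export

The steady-state balance integrates the salinity-derived ²³⁸U minus
measured total ²³⁴Th from the surface to the integration depth
(trapezoid rule; the shallowest sample extends to 0 m by constant
continuation; linear interpolation to the integration depth), scaled by
λ = 0.02876 d⁻¹ from the 24.1 d half-life. The mixing correction
`−κ·∂²A_Th/∂z²` uses central second differences on the irregular sample
grid with one-sided endpoint closure; κ defaults to 0 because no
study-specific value is available, and a linear profile yields exactly
zero mixing supply. The non-steady-state estimate uses the two-profile
mean deficiency minus the inventory trend `(I₂ − I₁)/Δt` and reduces
continuously to the steady state as the profiles converge. Activity
uncertainties propagate in quadrature through the trapezoid weights.
POC conversion multiplies by the particulate C:²³⁴Th ratio
(µmol C dpm⁻¹) and 12.011 mg mmol⁻¹.

## Dilution rates and the balance

The two-treatment algebra is the standard two-point form: apparent rates
`k = ln(final/initial)/duration`, grazing `g = (k_A − k_B)/(1 − x)` with
x the whole-seawater fraction of the diluted bottle (0.25), nutrient-
amended growth `k_B + g` and in situ growth `k_C + g`. Negative g is
floored at zero with a flag, per conventional practice. The
photoacclimation factor Phi is the biomass-weighted mean log-rate of
change of FL3:FSC over the picoeukaryote and nanoeukaryote populations,
computed and subtracted per depth. NPP is integrated trapezoidally from
the surface (constant-extended) to the euphotic depth. For the
growth–grazing balance, microzooplankton grazing in carbon units is
`mean(g/μ)·NPP` over depths with positive μ — the usual
fraction-of-production scaling; mesozooplankton grazing enters as a
provided areal number (its gut-fluorescence pipeline is out of scope).

## BCP metrics

`Ez = Flux(z_eu)/NPP` with the flux taken from the attenuation fit at
the euphotic depth (power-law interpolation when no trap sits exactly
there); `T100` evaluates the same fit 100 m deeper; their product is the
BCP efficiency. Salp:non-salp flux ratios interpolate each cycle's
power-law fit at shared measured depths — geometric interpolation,
consistent with the flux model — and report per-depth ratios and their
mean; pairs with a missing partner are skipped with a warning.

## Synthetic cycles

The generator emulates the study conditions: a 5-day cycle at 10 °C
with a 70-m euphotic zone and traps at 70/100/300/500 m; a bloom of
~200 blastozooids m⁻² (truncated-normal lengths around 35 mm) and
~20 oozooids m⁻² (around 60 mm); gut pigment `5·L²` ng ind⁻¹, chosen so
cycle-level grazing and egestion land in the observed range (egestion
0.5–2× the 200-m POC flux); trap truth F0 = 210 mg C m⁻² d⁻¹ with
b = 0.39; ²³⁴Th export 1500 dpm m⁻² d⁻¹; μ = 0.6, g = 0.4 d⁻¹; NPP
integrating to 452 mg C m⁻² d⁻¹. Noise models are minimal conventional
choices, all configurable: Poisson tow counts (the field tow-to-tow
variance structure is unknown; Poisson is a stand-in, not an inference),
lognormal σ = 0.2 on gut pigments and on each of the 12 trap tubes'
POC (per-tube noise pooled over the frame), Gaussian σ = 0.05 dpm L⁻¹
on ²³⁴Th activities, lognormal σ = 0.05 per bottle chl measurement. The
day/night abundance contrast is a configurable night:day factor
(default 1). The ²³⁴Th profiles are built with a uniform deficiency
above the euphotic depth sized so the steady-state integral returns the
true export exactly under trapezoidal integration, tapering to
equilibrium at the next sample depth; the pair is held in steady state.
The dilution bottles follow `k(x) = μ − x·g` exactly, with the nutrient
effect and the photoacclimation signal both defaulting to zero.

With noise off (`NoiseConfig.off()`), counts are rounded expectations
and every estimator recovers its ground-truth value to numerical
precision (the ²³⁴Th balance within its ≤5% discretization allowance);
with default noise the median absolute relative error of
(a, b, F0, b_atten, μ, g) over 200 seeds is below 15% (typically
1–10%). What passing these tests shows is that the estimators invert
the generating model faithfully at realistic noise levels; it does not
certify behavior under field pathologies the generator omits —
swimmer-contaminated traps, non-power-law flux profiles, strongly
advective ²³⁴Th fields, nonlinear grazing responses in the dilution
series, or patchy salp distributions beyond Poisson.

## Numerical choices and limitations

Determinism: every generator routine derives an independent child
stream from (seed, table-key), so tables are bit-identical across runs
and the same whether generated singly or via `generate_cycle`. All
log-space fits require positive values and at least two (attenuation)
or three (pigment) support points, with explicit errors otherwise.
Integration is trapezoidal throughout (second-order on smooth
profiles). Problem sizes are deliberately modest — ~10 tows, ≤10 gut
pigments per stage and tow, 4 trap depths × 12 tubes, 10-depth ²³⁴Th
profiles, 6 dilution depths, 200-seed ensembles — matching the scale of
a real cycle's data. Known limitations: no swimmer/blank handling
(trap masses arrive corrected), no β-counting decay corrections
(activities arrive calibrated), no ¹⁴C scintillation chemistry (NPP
arrives in mg C m⁻³ d⁻¹), and no cross-cycle hypothesis testing.
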