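# Methods

`greensim` is a modular dynamic model of a multi-span (Venlo) glasshouse:
solar optics resolved from geometry and glazing physics, two perfectly
stirred moist-air zones with explicit energy and species balances,
pressure-driven airflows, a long-wave radiation network with numerically
computed view factors, surface heat/mass exchange with condensation, and
a tomato crop with transpiration, carbohydrate-based growth and discrete
pruning.  Every parameter is a physical property (a dimension, a material
constant, an equipment datasheet figure) — nothing is calibrated against
indoor measurements.

## Solar optics

**Direct roof transmittance.**  The beam is a vector fixed by the sun
azimuth/zenith (computed by an in-package NOAA/Meeus-type ephemeris,
error well below 0.5°).  In the roof frame the saw-tooth cross-section is
periodic; `tau_r_dir = tau_g · tau_rg · tau_b` where

* `tau_g` is obtained by deterministically tracing a stratified bundle of
  rays (default 96) through the periodic two-slope cross-section.  At
  every pane crossing the ray splits by the unpolarised Fresnel
  two-interface coefficients with Bouguer absorption along the refracted
  path (refraction displacement inside the 4 mm pane is neglected).
  Reflected branches are followed to the third reflection order with a
  10⁻³ weight cutoff: this captures both the underside reflections of the
  shaded slope toward the floor and exterior reflections re-entering the
  opposite slope.  The stochastic Monte-Carlo tracer in the test-suite is
  the independent oracle (agreement ±0.01).
* `tau_rg` (ridges + gutters, running along the ridge axis) and `tau_b`
  (glazing bars, running down-slope) are beam-projected shadow fractions
  of rectangular elements with finite height; the bar term weights the
  two slopes by their beam-projected pane areas.  Default element sizes
  are standard Venlo construction: 4 m span, 22° slope, ridge strip
  0.04 m × 0.05 m, gutter 0.12 m × 0.08 m, bars 0.03 m × 0.02 m at 1.0 m
  pitch, 4 mm glass with refractive index 1.526 and extinction 4 m⁻¹.

**Diffuse roof transmittance** is the radiance-weighted sky-vault average
of the direct transmittance on a 5° × 5° grid (cell-centre evaluation,
no special-casing of the sun-containing cell).  Radiance models: uniform;
CIE standard overcast (Moon–Spencer `(1+2cos γ)/3`); and a continuous
all-sky blend between the overcast gradation and a CIE-clear-type
gradation × circumsolar indicatrix, weighted by a clear-sky index in
[0, 1] derived from the cloud ratio.  The published all-sky radiance
model this emulates is defined by external coefficient tables; only its
interface and limit behaviours (overcast limit, circumsolar maximum) are
reproduced here, which is sufficient because the diffuse transmittance is
a broad average over the vault.  Values are memoised on (geometry,
optics, model, grid) keys; with the study-case roof the standard-overcast
value is ≈ 0.78 and the uniform-sky value ≈ 0.76, and a uniform sky is
exactly rotation-invariant.

**Indoor distribution.**  Entered flux (roof + south-wall gains, split
50/50 PAR/NIR) passes a five-element horizontal stack — shading screen,
thermal screen, canopy, floor — of abstract two-face layers
(independent down/up transmittance/reflectance).  Two layers combine by
the infinite inter-reflection geometric series; a stack is resolved
exactly by a backward effective-reflectance sweep plus forward flux
sweep, conserving energy to machine precision.  Screens deployed over a
fraction `u` are areal mixtures `u·fabric + (1−u)·identity`.  The canopy
layer follows Beer–Lambert extinction diluted by the alleyway share:
`tau = r_cul·exp(−K·LAI) + (1−r_cul)` with K_PAR = 0.7, K_NIR = 0.27;
canopy reflectance is `r_cul·rho_leaf·(1−exp(−K·LAI))`.  Upward
reflections escaping the stack are treated as lost through the cover at
the uniform-sky diffuse transmittance (their secondary return is
neglected).  The south wall is a large vertical window: Fresnel at the
wall incidence for the beam, hemispherical coefficients for the isotropic
sky half-vault and ground albedo (0.2), times a frame/dirt coefficient
(0.9), combined with the curtain through the same layer algebra.

## Air zones

Each zone (MainAir below the screens, TopAir above) is isochoric with
four states: internal energy U and the masses of dry air, water vapour
and CO2.  Temperature follows in closed form because U is affine in T for
the constant-cp ideal-gas mixture (cp 1005 / 1860 / 846 J kg⁻¹ K⁻¹ for
dry air, vapour, CO2; latent reference 2.501 MJ kg⁻¹ at 0 °C; Magnus
saturation law).  CO2 is carried in the mass balance but neglected in the
total pressure.  Writing the balance on U rather than `rho·V·cp·dT/dt`
is what lets the pressure-driven envelope flows close the species
balances exactly (simulated indoor pressure stays within a few Pa of
ambient).  Supersaturation is permitted transiently; only surface
condensation removes it.

## Airflows

Roof vents: buoyancy term `C_f·L_O·[H_O(sin ψ − sin(ψ−δ))]^{3/2}/3 ·
sqrt(g|Δρ|/ρ_ref)` per vent plus wind term `L_O·H_O·G(δ)·U_roof` with the
empirical ventilation functions for alternating Venlo vents
(`G_L = 2.46e-2(1−e^{−δ/14.5})`, `G_W = −1.89e-5 δ² + 2.23e-3 δ`,
extrapolated from their 29° experimental range to the 44° hardware
limit); leeward/windward aggregates (openings per m² floor: 0.0208 each)
superpose in quadrature.  The published rendering of both formulas drops
a radical; the dimensional forms above are implemented, with a config
switch for plain addition.  Closed vents leak through an equivalent
opening height of 6 mm, inverted to an angle by root finding.  Envelope
cracks follow `F = sign(ΔP)·η·|ΔP|^0.65`; the exponent corner at ΔP = 0
is non-Lipschitz, so the simulator evaluates a smoothly regularised
variant (`ε = 0.1 Pa`) — the law is unchanged beyond a fraction of a
pascal but the stiff integrator no longer thrashes (two orders of
magnitude fewer function evaluations).  Leak topology: TopAir↔outdoor,
MainAir↔north/east corridors; the south wall is airtight, the west
compartment neutral.  The two horizontal screens define four deployment
states whose flows superpose with weights `(1−u₁)(1−u₂), …, u₁u₂`
(series fabric conductances when both deployed, a square-root free-
opening law otherwise, plus an always-present edge leak).  Volumetric
flows convert to per-species mass flows through the perfect-gas law
(bilateral for vents/screens, pressure-ordered unilateral for cracks) and
to sensible heat with per-species cp on the Celsius scale; the zone
energy balance uses full enthalpy fluxes so the reference cancels.

## Long-wave radiation

Pairwise net exchange between grey opaque surfaces:
`Q = ε₁ε₂·FF₁₂·A₁·Πτ_x·σ(T₁⁴−T₂⁴) / (1 − ρ₁ρ₂·FF₁₂FF₂₁·Πτ_x²)`.
View factors are computed numerically: surfaces meshed into planar quads,
cell-to-cell factors by the contour double line integral (4-point Gauss
per edge pair; collinear/shared edges use the exact closed form of the
log-kernel double integral; near pairs a subdivided quadrature), with a
centre-ray Möller–Trumbore test against occluder triangles.  Catalog
checks: coaxial parallel unit squares 0.1998, perpendicular adjacent
squares 0.2000, 2-D crossed-strings limit within 2%.  The pipeline runs
this over a parametric reduced scene of the compartment (floor, canopy
slab, roof plane, three walls, three pipe slabs, gutter slab) on a grid
of crop heights × widths, symmetrises by reciprocity, regresses each pair
as a bivariate quadratic in (height, width), and row-normalises at
evaluation so every surface's factors sum to 1.  Screens are not scene
occluders: links crossing the screen plane carry a medium transmissivity
`1 − u(1−τ_lw)` per screen, and each screen is a radiating plane with
effective emissivity `u·ε` that mirrors the roof's view of the hall —
an approximation that preserves exact pairwise antisymmetry (hence
closure) while keeping the factor set crop-size-continuous.  Mixing
ducts and the west wall carry no nodes (their exchange is attributed to
MainAir).  Exterior faces split their view between sky (black body at
the pyrgeometer-derived sky temperature) and outdoor ground (black body
at outdoor air temperature) by the isotropic tilt factors; corridor
walls face a black body at the corridor/outdoor average temperature.

## Surface exchange

Convection goes through a named-correlation registry (all defaults
logged, all overridable): indoor horizontal surfaces `1.7·ΔT^{1/3}`
buoyancy-unstable / `0.8·ΔT^{1/4}` stable; still-air vertical plates
`1.42·(ΔT/L)^{1/4}`; roof exterior wind-linear `2.8 + 1.2·U` (power law
above 4 m s⁻¹); exterior walls TARP-style natural + wind terms; pipes by
the horizontal-cylinder law; curtain cavities by a vertical-cavity law.
Water mass transfer uses the Lewis analogy `k_m = h/(ρ·cp·Le^{2/3})`
(Le = 0.87) with the humidity-ratio difference to saturation at the
surface temperature; evaporation is limited by the per-surface condensate
store (drained over a 10-minute timescale so the ODE stays smooth), and
every kilogram condensed deposits its vapour enthalpy on that surface.
Soil is a five-layer 1-D finite-volume column (geometric thickness
growth 2–32 cm, conductivity 1.2–1.4 W m⁻¹ K⁻¹, fixed 12 °C deep
boundary).  Heating pipes are lumped-capacity nodes driven by the
recorded injected power; their surface temperature adjusts so convective
plus radiative emission balances injection.

## Crop

Transpiration is a Stanghellini-type big-leaf latent flux: `2·LAI ·
ρ·cp/(ΔH·γ·(r_b+r_s)) · (p_sat(T_can) − p_w)` with r_b = 275 s m⁻¹ and a
stomatal resistance `82·f(I)·f(T)·f(CO2)·f(VPD)` s m⁻¹.  Growth is a
reduced carbohydrate-buffer model: gross photosynthesis (light-saturating
with CO2 Michaelis term and Gaussian temperature response, inhibited at a
full buffer) fills the buffer; outflow (turnover ≈ 14 h at 20 °C,
matching the daily assimilation magnitude) partitions 55/28/17% to
fruit/leaf/stem once a 250 °C·day temperature sum switches the plant
generative; fruits mature through 5 development boxes (≈ 55 days at
20 °C) into harvested dry matter and fruit count; maintenance respiration
is Q10 = 2.  LAI = SLA·leaf DM with SLA 0.025 m² g⁻¹.  Pruning is a
discrete event that sets LAI exactly to the event target and reports the
removed biomass; a weekly schedule at 4.5 m² m⁻² can be auto-generated.
Harvested dry matter converts to fresh weight at a constant 5.4% fruit
dry-matter content; the crop water stock is bracketed with 7.5–13.6%
vegetative dry-matter content.  The exact cultivar-adapted growth
parameters of the reference experiment are not public; the defaults here
are literature-typical and the carbon ledger (buffer inflow = pool growth
+ respiration + harvest + pruned biomass) closes to 10⁻⁹ relative
regardless of their values.

## Assembly and numerics

State vector (~45 states): 2 × (U + 3 masses), 13 surface temperatures,
5 soil layers, 7 condensate stores, 8 ledger integrals.  Actuators are
forcing inputs, never controlled.  Integration is operator-split on the
5-min forcing cadence: per step the solar distribution, view-factor
matrix, sky temperature and crop photosynthesis are frozen; the stiff
ODE advances with BDF (rtol 10⁻⁵, per-state-type absolute tolerances);
crop pools and pruning events update at step boundaries.  The measured
indoor CO2 concentration is enforced by a 5-minute relaxation source
whose integral is the implied injection.  Initialisation follows the
first forcing record with a +4/+3 K indoor offset; a 48 h spin-up is
recommended for metrics.  Model variants: C1 removes the south wall; C2
removes all walls, sets r_cul = 1 and a constant cover transmittance of
0.78 — both run at identical injected-heat forcing.

Evaluation metrics are RMSE, RRMSE (= RMSE/mean·100) and MAE, cumulative
and midnight-to-midnight daily.  The water ledger partitions cumulative
transpiration into per-surface condensation, vented vapour, crack-leaked
vapour and air storage (closure 10⁻⁶ relative); the CO2 ledger balances
implied injection against assimilation, venting, leakage and storage.

## Synthetic weather and forcing

The generator emulates a temperate-maritime (Cfb) climate at 47.3° N:
Haurwitz clear-sky irradiance attenuated by `1 − 0.75·Ce`, with the cloud
ratio Ce drawn per daylight sixth-of-day from a Beta distribution whose
mean swings seasonally from 0.72 (January) to 0.35 (July); sinusoidal
seasonal (12 ± 7 °C) and diurnal (3–6 °C, 15 h peak) temperature with
AR(1) noise; humidity anti-correlated with insolation; lognormal daily
wind around 3.5 m s⁻¹; clear-sky net long-wave loss 75 W m⁻² reduced by
cloud.  The forcing generator is a rule-of-thumb controller emulation
(vents proportional to warmth, thermal screen on cold nights, pipe heat
proportional to the heating deficit, day/night CO2 setpoints 750/430 ppm,
mild corridors).  What synthetic runs demonstrate: conservation,
closure, qualitative seasonal behaviour (winter condensation-dominated,
summer venting-dominated water ledgers), stability and determinism.
What they cannot demonstrate: agreement with measured indoor climate,
yield trajectories against harvest records, or real actuator dynamics —
those require the deposited experimental dataset.  Default desk-scale
problem sizes: 1–4 simulated days, 8 m view-factor cells, 96-ray direct
transmittance bundles, 5° sky grids.

## Known limitations

* Perfectly stirred zones: vertical gradients (largest on summer middays)
  are outside the model by construction.
* The reduced radiation scene idealises pipe loops and gutters as
  equivalent-area slabs and merges the 15 crop rows into one slab.
* No spectral resolution beyond PAR/NIR; no condensate optics on glass;
  no wind-direction dependence; no insect screens.
* Screen long-wave treatment is an areal-mix approximation, not a full
  radiosity solution of the partially covering plane.
* Corridor humidity is unrecorded in the reference experiment; the
  corridor air is assumed at MainAir relative humidity (configurable).
* The crop growth defaults are structurally faithful but not
  cultivar-fitted; absolute yield magnitudes carry that uncertainty.
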