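# greensim

A generic, modular, **calibration-free** dynamic model of Venlo-type
greenhouses, written for greenhouse-physics researchers and crop-model
developers who need a physics-based baseline that can be configured from
dimensions, material properties and equipment datasheets alone — no
fitting against indoor measurements.

The library covers the coupled multiphysics of a glasshouse compartment:

* **Solar optics** — direct roof transmittance
  `τ_r,dir(α_s, γ_s) = τ_g · τ_rg · τ_b` resolved by tracing the beam
  through the periodic saw-tooth cross-section (Fresnel + Bouguer at
  every pane, multi-span inter-reflections) and by beam-projected shadows
  of ridges, gutters and glazing bars; diffuse transmittance
  `τ_r,dif = ∫∫ τ_r,dir·L(α,γ) sinγ cosγ dγdα / ∫∫ L sinγ cosγ dγdα`
  over a discretised sky vault with uniform, standard-overcast
  (Moon–Spencer) or continuous all-sky radiance distributions.
* **Indoor short-wave distribution** — exact multilayer algebra
  (infinite inter-reflection series) across shading screen, thermal
  screen, canopy (`τ_can = r_cul·e^{−K·LAI} + (1−r_cul)`) and floor,
  separately for PAR and NIR, plus the south-wall window gain.
* **Moist air** — two perfectly stirred isochoric zones with explicit
  internal-energy and species balances (dry air, vapour, CO2), so that
  pressure-driven envelope flows close the mass balances exactly.
* **Airflows** — buoyancy + wind roof-vent model with empirical
  ventilation functions superposed in quadrature, an equivalent 6 mm
  residual vent opening for closed-vent leakage, `η·|ΔP|^{0.65}` envelope
  cracks, and the four-state superposition of two horizontal screens.
* **Long-wave radiation** — pairwise grey-surface exchange
  `Q = ε₁ε₂·FF₁₂·A₁·Πτ_x·σ(T₁⁴−T₂⁴)/(1−ρ₁ρ₂FF₁₂FF₂₁Πτ_x²)` over view
  factors computed by the contour double line integral with ray-traced
  occlusion, regressed against crop size and row-normalised to 1.
* **Surfaces** — registry-based convection correlations, Lewis-analogy
  condensation/evaporation with per-surface condensate stores, 1-D soil
  conduction, lumped heating-pipe nodes.
* **Crop** — Stanghellini-type big-leaf transpiration and a reduced
  carbohydrate-buffer tomato model (buffer → leaf/stem/fruit pools →
  5 development boxes → harvest) with **discrete pruning events** that
  set the LAI exactly to a target and report the removed biomass; fresh
  yield from dry matter at 5.4% DM content.
* **Simulator** — the assembled two-zone ODE system (≈ 45 states, BDF,
  rtol 10⁻⁵, 5-min output), RMSE/RRMSE/MAE evaluation, water and CO2
  ledgers, and a variant harness (C1: no south wall; C2: quasi-infinite
  greenhouse with constant cover transmittance 0.78).

The default configuration describes a 1037 m² six-span experimental
compartment near Nantes (944 m² cultivated, 22° roof slope, ridge axis
−29° from North, corridors to the north and east, a twin compartment to
the west, only the south gable exposed).

## Worked example

```python
from greensim import (study_case_config, build_system, integrate,
                      synthesize_weather, synthesize_forcing,
                      water_balance, roof_diffuse_transmittance,
                      RadianceModel)

cfg = study_case_config()
print(roof_diffuse_transmittance(cfg.roof, cfg.glazing,
                                 RadianceModel("standard_overcast")))
# 0.7763  — overcast-sky diffuse transmittance of the study roof

w = synthesize_weather(2, seed=3, start="2015-07-10")   # 5-min records
f = synthesize_forcing(w, seed=3)                       # actuator schedules
res = integrate(build_system(cfg), w, f)
print(res.series["T_main"].mean().round(2))             # 24.32  degC
wb = water_balance(res)
print(round(100 * wb["frac_vented"], 1))                # 82.0   % of transpired
print(round(100 * wb["frac_condensed"], 1))             # 0.0    %
print(abs(wb["closure_residual_kg"]))                   # ~6e-10 kg
```

On a summer day nearly all transpired water leaves through the roof
vents; on a winter day (screens closed, vents shut) condensation on the
cold cover dominates instead.  The ledger closes to numerical precision
because the zone balances are written on internal energy and species
masses rather than on temperature.

A thin CLI wraps the same functions:

```bash
greensim weather synth --days 3 --seed 7 --out w.csv
greensim optics diffuse --sky overcast        # tau_r_dif[overcast] = 0.7763
greensim optics direct --date 2014-12-21 --out tau.csv
greensim simulate --days 2 --seed 7 --out run/
greensim variant C1 --days 2 --seed 7
```

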