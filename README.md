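# salpflux

Carbon-export budgets for salp-bloom process studies.

Salps (notably *Salpa thompsoni* in the Southern Ocean) are gelatinous
filter feeders whose dense blooms repackage phytoplankton into large,
fast-sinking fecal pellets. Quantifying how much of net primary
production (NPP) such a bloom exports to depth requires stitching
together several independent rate measurements collected during a
quasi-Lagrangian cycle: net tows (salp abundance and size structure),
gut pigments (grazing), sediment traps (sinking particulate organic
carbon, POC), ²³⁸U:²³⁴Th disequilibrium (export integrated over ~1
month), and dilution experiments (phytoplankton growth μ and
microzooplankton grazing g). `salpflux` implements that whole budget as
a tested pipeline, together with a synthetic-cycle generator with known
ground truth so every estimator can be validated end to end.

## The models

- **Salp demography** — per-individual tow records binned into 5-mm
  oral–atrial length (OAL) classes, areal abundance
  `A = count/volume × tow depth` (ind m⁻²), day/night averaged.
- **Grazing** — gut pigment `Gpig(L) = a·L^b` (log-log least squares)
  over gut passage time `GPT(h) = 2.607·ln(OAL) − 2.6`, Q10 = 2
  temperature scaling; daily rates weight day/night abundance by 14/10 h.
- **Egestion** — pigment route: `E = EE × grazing C` with egestion
  efficiency EE = 0.36; length route: `0.5388·e^(−0.0212·L)` pellets h⁻¹
  of `0.055·L^2.0665` µg C each (Q10-scaled from ~0 °C source waters).
- **Trap fluxes** — `flux = POC mass / (n_tubes·π·(d/2)²·days)` for 7-cm
  tubes; depth attenuation `Flux(z) = F0·(z/z0)^−b` fit in log-log space;
  intact-pellet carbon from morphometrics via
  `C(µg) = 10^(0.634·log10 V + 1.43)`, V a cylinder volume in mm³.
- **²³⁴Th export** — steady state `λ·∫(A_U − A_Th)dz` (λ = 0.02876 d⁻¹,
  `A_U = 0.0786·S − 0.315`), optional mixing term `−κ·∂²A_Th/∂z²`, and a
  non-steady-state variant subtracting the inventory trend between two
  occupations; POC via the C:²³⁴Th ratio.
- **Dilution rates** — two-treatment algebra `g = (k_A − k_B)/(1 − x)`,
  `μ = k + g`, with a flow-cytometric photoacclimation correction
  (μ_corrected = μ − Phi).
- **BCP metrics** — export ratio `Ez = flux(z_eu)/NPP`, flux transmission
  `T100 = Flux(z_eu+100)/Flux(z_eu)`, and their product, the
  biological-carbon-pump (BCP) efficiency.

## Worked example

```sh
salpflux simulate --seed 1 --out data/        # synthetic cycle + truth sidecar
salpflux run --config config.yaml --out out/  # full budget for one cycle
```

with `config.yaml` pointing at the five generated tables
(`--scenario scenario.yaml` customizes the cycle; setting the scenario's
noise block to zeros gives an exact-recovery run). For the default
scenario with noise off, the run command prints:

```
cycle salp-demo: NPP 452 mg C m-2 d-1, flux(z_eu) 210.0, Ez 0.46, T100 0.71
summary written to out/summary.json
```

i.e. 46% of the 452 mg C m⁻² d⁻¹ of primary production leaves the
euphotic zone as sinking particles, and 71% of that survives the next
100 m — a BCP efficiency of ~33%, the signature of a salp-bloom system.
`out/summary.json` holds the full budget: grazing and egestion by stage
and method, fluxes by depth, ²³⁴Th steady/non-steady-state estimates,
per-depth μ and g, and the provenance record of every empirical constant
used. `salpflux compare` takes several cycle summaries plus a
salp/non-salp pairing and reports per-depth flux ratios.

As a library:

```python
from salpflux import CycleScenario, generate_cycle, fit_attenuation, poc_flux, t100

cycle = generate_cycle(CycleScenario(), seed=1)
pts = [(t.depth, poc_flux(t).value) for t in cycle.traps]
fit = fit_attenuation(pts, z0=70.0)
print(fit.f0, fit.b, t100(fit, 70.0))   # ≈ 210, 0.39, 0.71
```

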