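# lakeprod

Productivity and oxygen-metabolism modelling for turbid, highly productive
saline lakes.

Dense cyanobacterial lakes — soda and thalassohaline crater lakes with
hundreds of micrograms of chlorophyll *a* per litre — concentrate all of
their photosynthesis into a thin, brightly lit surface layer. Quantifying
that production takes a chain of small models: a Beer–Lambert underwater
light field anchored to a logged PAR series, a photosynthesis–irradiance
(P–I) curve with photoinhibition fitted to flask incubations, a depth–time
integration of gross production over the photic layer, and an independent
free-water estimate inverted from the diel dissolved-oxygen cycle with
air–water gas exchange. `lakeprod` implements that chain, the physical
conversions underneath it (O₂ solubility, PSS-78 salinity, chlorophyll-*a*
from extract absorbance, O₂→carbon via a photosynthetic quotient), and the
community-level profiling used alongside it (Ward clustering of ionic
composition, Biolog EcoPlate AWCD). A synthetic-data module generates every
input with known ground truth, so each inversion is testable end to end.

It is written for aquatic microbial ecologists and limnologists who want
these standard calculations as tested, composable library calls rather than
spreadsheet arithmetic.

## The models

**Light field.** A discrete PAR profile gives the diffuse attenuation
coefficient K_d by ordinary least squares on ln *I* vs depth *z*; the field
is then *I*(z,t) = *I*(z_ref,t)·exp(−K_d·(z−z_ref)) from a reference-depth
logger series. The 1 % photic depth is ln(100)/K_d.

**P–I curve.** The exponential photoinhibition model

    P(I) = P_s · (1 − e^(−αI/P_s)) · e^(−βI/P_s)

with capacity P_s, initial slope α and photoinhibition slope β ≥ 0, fitted
by bounded nonlinear least squares with data-driven starts and deterministic
multi-start restarts. Derived indices: I_k = P_s/α, the optimum
I_m = (P_s/α)·ln((α+β)/β), the realized maximum
P_s·(α/(α+β))·(β/(α+β))^(β/α), and the half-saturation irradiance.

**Depth–time production.** GPP = ∬ [chl a]·P(I(z,t)) dz dt over the photic
layer between dawn and dusk, by the midpoint rule on a 10-cm × 10-min grid,
with a one-at-a-time sensitivity analysis over (P_s, K_d, α, β).

**Free-water metabolism.** z_mix·dO₂/dt = NEP_t − F with
F = k(T,S)·(O₂ − O₂_sat) and k from a k600 (constant or wind-based) via
Schmidt-number scaling. Night intervals estimate respiration R (assumed
constant over 24 h); day intervals plus the daytime share of R give GPP;
NEP = GPP − R.

## Worked example

Everything below is generated from the synthetic study conditions
(K_d = 6.79 m⁻¹, chl *a* = 612 µg L⁻¹, a 12-h tropical half-sine day,
5-min O₂ logging):

```python
from lakeprod.synthetic import (SimulationSpec, gen_diel_par, gen_par_profile,
                                gen_o2_diel, gen_pi_dataset)
from lakeprod.light import AttenuationModel
from lakeprod.pe_curves import fit_platt
from lakeprod.production import integrate_gpp, IntegrationGrid, net_production
from lakeprod.metabolism import DielMetabolismModel, GasExchangeSpec

spec = SimulationSpec(seed=42)
par = gen_diel_par(spec)
field = AttenuationModel(gen_par_profile(spec)).fit(series=par)
print(field.summary())
```

```
Beer-Lambert attenuation fit
  Kd            6.790 m-1 (SE 0.000)
  1% PAR depth  0.678 m
  R-squared     1.0000
  reference depth 0.3 m, 289 samples
```

The noiseless profile returns the planted attenuation exactly; only the top
~0.7 m of the column sees more than 1 % of subsurface light. Fitting a P–I
curve to noisy flask rates:

```python
res = fit_platt(gen_pi_dataset(noise_sd=8.0, seed=42))
print(res.summary())
```

```
Platt P-I fit (umol O2 mg chla-1 h-1), n = 12
param       estimate     std err
Ps               267       10.49
alpha          3.439      0.3246
beta         0.09888     0.01825
residual SE 8.015
Ik = 77.62  Im = 277.7  realized Pmax = 234.1  half-saturation = 45.85
```

The recovered (P_s, α, β) sit within one standard error of the generating
(271, 3.31, 0.109); photoinhibition caps the realized maximum at 234
µmol O₂ (mg chl a)⁻¹ h⁻¹ near 280 µmol photons m⁻² s⁻¹. Integrating over
depth and daylight and subtracting a dark respiration of 0.6 mg O₂ L⁻¹ h⁻¹
over 0.79 m:

```python
dawn, dusk = par.daylight_window()
gpp = integrate_gpp(612.0, res.curve, field, IntegrationGrid(dawn=dawn, dusk=dusk))
net = net_production(gpp, resp_volumetric=0.6, resp_depth=0.79)
print(f"GPP = {net.gpp:.2f}  R = {net.resp:.2f}  NEP = {net.nep:.2f}")
```

```
GPP = 25.63  R = 11.38  NEP = 14.25
```

in g O₂ m⁻² d⁻¹. The independent free-water route, inverting a forward-
simulated diel O₂ record (truth: GPP 20, R 18, k600 0.5 m d⁻¹):

```python
series, truth = gen_o2_diel(spec)
fw = DielMetabolismModel(series, GasExchangeSpec(k600=spec.k600),
                         dawn=truth["dawn"], dusk=truth["dusk"]).fit()
print(fw.summary())
```

```
Free-water diel metabolism (g O2 m-2 d-1)
         GPP        R      NEP      P/R
day
1      20.00   -18.00     2.00     1.11
```

The inversion recovers the forward model's daily totals to better than
0.1 %.

A `lakeprod` console script exposes the same stages as subcommands
(`fit-kd`, `fit-pi`, `integrate-gpp`, `diel-metab`, `cluster-chem`,
`ecoplate`, `simulate`, `convert`, `run`).

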