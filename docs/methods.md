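# Methods

This note documents the models, the parameter choices, the synthetic-data
generators that the tests invert against, and the numerical decisions taken
where the design was genuinely open.

## Physical conversions

**O₂ solubility.** The default equilibrium concentration is the
Garcia–Gordon combined fit with Benson–Krause coefficients, which yields
µmol kg⁻¹ and is converted to mg L⁻¹ with the EOS-80 one-atmosphere density
at (T, S). The Weiss fit (ml STP L⁻¹ × 1.42905) is available as an
alternative and is coded independently — different functional form, source
data and native units — so the two serve as a mutual cross-check; over
T ∈ [20, 35] °C, S ∈ [0, 55] they agree to within 0.3 %. Inputs are
validated to T ∈ [−2, 40] °C, S ∈ [0, 60]. At 31 °C and 52 psu the default
fit gives 5.59 mg O₂ L⁻¹.

**Salinity.** PSS-78 at zero pressure, from conductivity in mS cm⁻¹
(instrument convention; the input is in-situ conductivity, not
temperature-compensated specific conductance). Above the PSS-78 validity
limit of 42 the value is still returned but flagged as an extrapolation —
routine for hypersaline lakes near 52 psu. Note that the conversion is
sensitive to the assumed temperature (≈ −1 psu per +1 °C at these
conductivities), so salinities quoted without their conversion temperature
can only be checked to a few percent.

**Chlorophyll a.** Ethanol-extract spectrophotometry:
11.904 µg mL⁻¹ per unit of (A₆₆₅ − A₇₅₀) for a 1-cm path, scaled by
extract/filtered volumes to an in-lake µg L⁻¹. Negative absorbance
differences (blank above sample) clamp to zero with a warning rather than
erroring; field blanks can exceed turbid samples.

**Carbon.** O₂ fluxes convert to carbon as flux/32/PQ×12 with the
photosynthetic quotient PQ (default 1). The carbon budget reports the
exponential growth rate µ = ln(1 + P/B) — distinct from the simple turnover
fraction P/B, which is reported separately as a percentage — plus the
annual scaling 365·P and the doubling time ln 2/µ. The log form is the
internally consistent daily compounding rate; ln(1+x) < x guarantees
µ < P/B always.

## Light field

K_d comes from ordinary least squares of ln I on depth (≥3 strictly
positive irradiances required; a non-positive fitted K_d is an error, not a
value). The field I(z,t) anchors to the reference logger depth (default
0.3 m, the typical just-below-surface mooring) and extrapolates upward to
the surface with the same K_d — no separate surface-layer model is
attempted. Time interpolation of the reference series is linear; on the
10-min production grid the choice is numerically immaterial but it is fixed
and documented here. Dawn and dusk are defined operationally as the first
and last times the reference series exceeds 1 µmol photons m⁻² s⁻¹
(configurable).

## P–I fitting

The exponential photoinhibition model is fitted by bounded
(β ≥ 0) Levenberg–Marquardt/trust-region least squares. Starts: α from the
slope of the three lowest-light points, P_s from the maximum observed rate,
β from the log-decline beyond the peak (0 if none); on failure, five
restarts from log-normally jittered starts under a fixed seed. Flask rates
are OLS slopes of O₂ on time normalised to chlorophyll, with the regression
R² as the linearity diagnostic (flagged below 0.95 — curvature signals
substrate exhaustion). Dark-flask respiration is *not* subtracted from
light rates by default; respiration is handled separately at the daily
scale. PAM rETR data reuse the identical machinery under an
"µmol electrons m⁻² s⁻¹" units tag.

With additive noise at 5 % of P_s the median of the recovered parameters
over replicates stays within 1 % of truth; individual estimates of β
scatter more widely (β is the weakly identified parameter — it only enters
through the gentle high-light decline), which is why bias, not per-replicate
error, is the meaningful recovery criterion.

## Production integration

Midpoint rule on cell centres in both z and t, 10-cm × 10-min defaults over
the top 1.5 m; halving both steps changes GPP by < 0.5 %, and a 20× finer
grid by < 1 %. Chlorophyll may be a constant or a depth profile
(interpolated to cell centres); GPP is exactly linear in it. The
respiration integration depth is an explicit argument with deliberately no
default — it is a physically meaningful choice the user must own — and the
CLI refuses to run the bottle route without it.

Sensitivity: each of (P_s, K_d, α, β) is displaced by ±½ SD (scalable) in
the direction that lowers/raises GPP, giving a (low, central, high)
envelope; parameters are ranked by dimensionless elasticity
(∂GPP/GPP per ∂θ/θ, central differences at ±1 %), which orders them
P_s > K_d > α > β under the default conditions. Ranking by SD-scaled
displacement instead depends on the relative SDs supplied and can promote α
(its typical relative uncertainty is ~50 %); both are reported.

A caveat on the photic-layer choice: with the reference-depth irradiance
held fixed, the share of column production *below* the 1 % light depth
grows with K_d (≈ 3.6 % at K_d = 5 m⁻¹, ≈ 9 % at 9 m⁻¹), because the
light-limited tail contributes relatively more as the saturated zone
shrinks. Truncating the integral at the 1 % depth is therefore a ≤ 10 %
approximation across that range, not a fixed small error.

## Free-water metabolism

Each interval contributes areal NEP_t = ΔO₂·z_mix + F·Δt with the gas flux
F = k(T,S)·(O₂ − O₂_sat) evaluated at the interval's left endpoint — the
same forward-Euler convention the synthetic generator uses, so the
noiseless round trip is exact by construction and recovery tests measure
estimation error, not scheme mismatch. R is the negated mean night NEP rate
scaled to 24 h (daytime respiration assumed equal to nighttime — the
standard free-water assumption); GPP is the daytime NEP sum plus the
daytime share of R. Windows with a gap exceeding 5 % of 24 h are rejected.
The piston velocity defaults to a constant k600 with Schmidt-number scaling
(exponent −0.5; Schmidt number from the Wanninkhof O₂ polynomials,
interpolated linearly in salinity between the fresh and S = 35 fits, which
is an extrapolation above 35 and the best available practice for
hypersaline water). A Cole–Caraco wind-based k600 is provided. The mixed-
layer depth is an explicit input with no default. Per-segment volumetric
rates (the linear-regression view of a dark or early-morning stretch) come
with 95 % t-based confidence bands.

## Community profiling

Ward minimal-variance clustering runs on the raw seven-variable ionic
matrix (Na⁺, K⁺, Mg²⁺, Ca²⁺, SO₄²⁻, Cl⁻, total alkalinity, all mg L⁻¹) —
unstandardised by default, because the separation of saline waters is
carried by absolute Na⁺/Cl⁻ levels that z-scoring would erase; a
standardise flag exists. Missing values are an error, never imputed. PCA
defaults to the correlation (standardised) form with a covariance option;
constant variables are dropped with a warning.

EcoPlate profiling blank-corrects each of the 31 substrate wells against
the water well (negatives clamped to 0), averages to AWCD per replicate,
and aggregates replicate-mean corrected ODs into six chemical classes as
percentages of the plate total (they sum to 100 by construction). The
evaluation time defaults to 96 h, the point where colour development is
typically well into its exponential rise. The 31-substrate → 6-class map
(2 amines, 6 amino acids, 9 carbohydrates, 8 carboxylic acids, 2 phenolic
compounds, 4 polymers) ships as an editable CSV; class assignments of a few
substrates (e.g. the phosphorylated sugars, glucosaminic acid) vary between
laboratories, and the map is deliberately user-overridable.

## Synthetic data

The generators define the study conditions the tests run under: a 12-h
tropical half-sine light day with noon PAR 260 µmol photons m⁻² s⁻¹ at the
0.3-m reference depth (a ~2000 µmol surface noon attenuated by
e^(−0.3·K_d) at K_d = 6.79 m⁻¹), chlorophyll 612 µg L⁻¹, P–I truth
(271, 3.31, 0.109), O₂ logging at 5 min in a 1-m mixed layer at 31 °C /
52 psu starting from air saturation, daily GPP/R of 20/18 g O₂ m⁻² d⁻¹ and
k600 = 0.5 m d⁻¹. In the O₂ forward model GPP(t) is distributed
proportionally to instantaneous PAR — not to P(I) of PAR — so the
metabolism inversion test is independent of the P–I module. Noise models:
multiplicative log-normal on light channels, additive Gaussian on rates and
O₂. Every generator is bit-reproducible under its seed.

What the generators do not emulate — sensor drift and fouling, vertical
mixing of the chlorophyll field, cloud structure in the light day,
non-constant respiration, bubble-mediated gas flux — bounds what passing
tests show: they demonstrate correct inversion of the stated forward
models, not robustness to every field artefact.

## Known limitations

* PSS-78 above 42 psu and the Schmidt-number salinity scaling above 35 are
  extrapolations, flagged but not avoidable for thalassohaline systems.
* The P–I β parameter is weakly identified at realistic noise; report its
  standard error, not just the point estimate.
* The free-water method books all night O₂ drawdown as respiration;
  advection or seiching would alias into R and GPP alike.
* Timestamps are local clock hours; no timezone or solar-geometry
  handling.
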