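# Methods

This note records the models implemented in `vwbr`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices that matter for reproducibility.

## Aeration model and k_L estimation

The vessel is surface-aerated (no sparging) and treated as well mixed, so
dissolved oxygen obeys `dC/dt = k_L·a (C_sat − C)` with `C(0) = 0`
(deaeration assumed complete; an incomplete deaeration can be represented
by fitting the intensity span instead, `fit_span=True`). The luminescence
of the ruthenium dye is quenched by oxygen, so the treated intensity
`I_max − I_recorded` follows the same saturating exponential scaled to the
span `I_max − I_min` between the deaerated and saturated plateaus.

Trace treatment mirrors the acquisition chain: dark-spectrum subtraction,
a per-spectrum **linear baseline detrend** anchored on an emission-free
band (default 450–500 nm; the drift is an instrument-temperature artefact
and is wavelength-flat to first order), 30-point moving-average smoothing,
then the maximum inside 608 ± 10 nm. The plateau levels default to the
medians of the first and last 5% of points; they can also be supplied or
profiled out.

k_L·a is found by a **bounded scalar minimisation on log10(k_L·a)** over
[1e−6, 1e−1] s⁻¹ with tolerance 1e−10 — deterministic, no seed, and
invariant to affine intensity rescaling and to time-unit changes. The fit
is flagged when the optimum sits on the bracket. A single k_L·a fitted to
a trace whose true transfer rate varies in time leaves a characteristic
signed-residual pattern (early and late points on opposite sides of the
fit); the test suite asserts this qualitative bias on a constructed
fixture rather than reproducing any instrument plot.

`integrate_aeration` uses the exact integrating factor
`C = C_sat(1 − exp(−∫k_L·a dt))` with 5-point Gauss–Legendre quadrature
per grid interval: exact for constant and piecewise-constant (on-grid
breakpoints) rates, with no ODE-stepper error term.

## Physical properties

* **ν(T)**: Vogel-type correlation `μ = 2.414e−5 · 10^{247.8/(T_K−140)}`
  Pa·s over Kell (1975) density. ν(21 °C) = 9.80e−7 m²/s, 0.25% from the
  9.78e−7 value the rest of the analysis assumes.
* **D_AB(T)**: linear, `c0 + c1·T`, anchored exactly at 2.10e−9 m²/s at
  21 °C with slope 5.0e−11 m²/s/°C (hits the literature 2.30e−9 at 25 °C).
  Both coefficients are configurable (`RunConfig`).
* **C_sat(T, pO2)**: Benson–Krause air-saturation correlation rescaled
  linearly in the oxygen partial pressure (Henry's law). Salinity and
  medium-composition corrections are out of scope; gas-side resistance is
  neglected (oxygen/water: liquid film controls).
* Note the resulting Sc at 21 °C is ≈466. Published Schmidt ranges quoted
  for the same campaign (366–395) imply a different, unrecoverable
  diffusivity fit; the package keeps the anchored values above and does
  not rescale. Synthetic correlation datasets nevertheless sample Sc over
  366–395, the stated fitting window, since the fitted exponents are
  insensitive to the Sc window when β is pinned.

## Correlation fitting and adjustment

`fit_sherwood` minimises `Σ(Sh_obs − Sh_model)²` directly in Sh space
(a log-space option exists for diagnostics) over (log k, α, γ) with β
fixed at 1/3, start (k, α, γ) = (1, 0.5, 1), Levenberg–Marquardt with
tolerances 1e−12. Parameterising log k keeps k positive without bounds.
Identifiability guards reject datasets with fewer records than constants
or with no variation in Re or G. Errors are reported as per-record
absolute percentage errors plus their mean and max.

`adjust_linear_constant` solves the one-dimensional least-squares problem
`min_c Σ(obs − c·pred)²`, which has the closed form
`c = Σ(obs·pred)/Σ(pred²)`. Observations can be compared as Sh or as kL;
a shared linear conversion drops out of the ratio, so the factor is
unit-invariant. The exponents are never touched.

**Wheel diameter.** D is not published for this vessel. The default
0.0414 m is recovered from the endpoints of the fitted geometric-number
range (0.651, 1.08) divided by the specific areas of the 105 mL and 60 mL
volumes (15.7, 26.1 m⁻¹); it is configurable everywhere. Re and Sh use the
impeller convention with this D, which also lands the printed upper Re of
the fitted range (≈3172 near 95.5 rpm at the warm end of the campaign).

**Packaged vessel table.** The 60 mL row of the published area table
rounds area (15.6 cm²) and specific area (26.1 m⁻¹) independently
(15.6/60 = 26.0); the fixture carries both columns verbatim and G-range
computations use the printed specific-area column.

## Turbulence post-processing

Operators act on flat per-cell tables (position, cell volume, nine
gradient components, optional k_sgs and ν_t), never on solver case
directories. Defaults: C_w = 0.325, C_ε = 1.034, Sc_t = 1.34, filter
width Δ = cell_volume^{1/3}; all configurable.

* WALE uses the traceless symmetric part of the squared gradient; the
  0/0 limit (quiescent cells) returns 0. Two algebraic oracles pin the
  implementation: ν_t = 0 for any single-off-diagonal (pure-shear)
  gradient, and ν_t = (C_w Δ)²(2/3)^{1/4}ω for solid-body rotation.
* ε = ε_res + ε_sgs exactly per cell; ε_res = 2ν S̄:S̄,
  ε_sgs = C_ε k_sgs^{3/2}/Δ.
* The printed shear-stress form `(μ+μ_t) S̄:S̄` is dimensionally
  inconsistent (Pa/s); the default implements the magnitude
  `(μ+μ_t)·sqrt(2 S̄:S̄)` and a `literal=True` flag evaluates the plain
  product for comparison. `diagnose_field` converts ν to μ with a fixed
  reference density of 998 kg/m³.
* η = (ν³/ε)^{1/4} maps ε = 0 to +inf (flagged by downstream summaries
  via the finite-volume fraction).
* The KE ratio `k_res/(k_res + k_sgs)` takes mean-removed fluctuation
  samples; the averaging window is whatever the supplied series spans —
  it is an input, not a package choice. Probes under the 0.8
  resolved-energy threshold are flagged.
* Surface k_L: per-face flux `(D_AB + D_ABt)|∂C/∂y|` (reported as
  magnitudes into the liquid, y wall-normal into the bulk), area-weighted
  mean over the driving force `C_sat − ⟨C⟩`; a driving force below
  1e−9·C_sat raises instead of dividing by near-zero.
* Distribution summaries are **volume-weighted** histograms and quantiles
  (cell-count histograms would over-represent refined regions), plus the
  volume fraction with ε > 0.5e−3 m²/s³, a conventional harshness
  threshold for stem-cell culture.

## Synthetic generators

All generators return their ground truth next to the data and are
bit-reproducible per seed (`numpy.random.default_rng`).

* **Traces**: additive Gaussian detector noise (counts) and a linear
  baseline drift; defaults emulate a typical run — k_L·a = 2 h⁻¹, span
  1500 counts on a 200-count floor, σ = 15 counts (≈1% of span), 5 s
  sampling for five time constants. The optional spectral wrapper uses a
  Gaussian emission band (centre 608 nm, σ = 15 nm) on a flat dark floor —
  only the peak position matters to the pipeline, not dye photophysics.
* **Flows**: Taylor–Green vortex (volume-mean ε_res = ν A² κ² in closed
  form), solid rotation and pure shear (closed-form WALE values), and a
  seeded random smooth field for property tests. Taylor–Green gradients
  are computed by 2nd-order central differences of the sampled velocities
  by default, so the dissipation oracle converges at 2nd order under grid
  refinement (≈0.3% at 64³); cell-center sampling of the analytic
  gradients is exact by trigonometric identity and is available via
  `gradients="analytic"`.
* **Sherwood datasets**: log-uniform (Re, Sc, G) over the fitted validity
  ranges (Re 624–3172, Sc 366–395, G 0.651–1.08), multiplicative Gaussian
  scatter on Sh (relative error structure matches correlation residuals,
  unlike additive detector noise).
* **Surface profiles**: film-theory construction, with optional face
  perturbations of zero area-weighted mean so the area-mean flux is
  preserved exactly.

What the generators do **not** emulate: real dye photobleaching and
Stern–Volmer nonlinearity, probe placement effects, genuinely turbulent
LES fields (the analytic flows are laminar patterns with known algebra),
interface deformation, and correlated residual structure across operating
conditions. Passing recovery tests therefore demonstrates estimator
correctness under the assumed noise models, not instrument fidelity.

## Problem sizes and determinism

Default test and acceptance problem sizes — 50-record correlation
datasets, 100–200 replicate seeds for recovery statistics, Taylor–Green
grids of 16³–64³ — were chosen as the smallest sizes at which the
stochastic summaries are stable to well within the asserted tolerances.
Every stochastic path takes an explicit integer seed; fitters are
deterministic by construction (fixed starts, brackets and tolerances).

## Known limitations

* No CFD coupling: quantities that require the original LES runs
  (overprediction magnitudes, slip-coefficient tuning errors) are outside
  the package; the correlation and operators are exercised on synthetic
  inputs with known truth.
* The k_L·a fitter assumes a single dominant transfer coefficient; traces
  from strongly time-varying regimes are fit in a least-squares-average
  sense (see the residual-bias property above).
* Property correlations are for clean water; culture media shift ν, D_AB
  and C_sat by a few percent.
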