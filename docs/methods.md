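# Methods

## Process model and conventions

The package partitions half-hourly NEE into GPP and Reco under the
standard daytime light-response framework, extended with a canopy COS
constraint:

- **Reco** follows the Lloyd–Taylor exponential temperature response
  with fixed T_ref = 15 °C and T₀ = −46.02 °C. `rb` (μmol CO₂ m⁻² s⁻¹)
  is the base respiration at T_ref; `E₀` (°C) the temperature
  sensitivity. The model is undefined at T_air ≤ T₀ and such records
  raise a domain error rather than being clamped.
- **GPP** is a rectangular hyperbola in incident PAR with initial slope
  `α` (μmol CO₂ / μmol photons) and asymptote `β` (μmol CO₂ m⁻² s⁻¹).
- **LRU**, the ratio of COS to CO₂ deposition velocities, is
  light-dependent: LRU = ι·exp(κ/R_PAR), tending to `ι` at high light
  and diverging as light vanishes (COS uptake persists through partly
  open stomata while GPP goes to zero). `κ` has PAR units
  (μmol m⁻² s⁻¹). The exponent is κ/R_PAR — the only reading of the
  relation that is dimensionally consistent with κ's units and with the
  stated low-light/high-light limits.
- **Canopy COS uptake** is GPP·LRU/(χ_CO2/χ_COS), with the
  mole-fraction ratio formed on a common mol/mol scale from native
  units (ppm, ppt). Per-record ambient mole fractions are used (not
  campaign means).

Sign convention: measured fluxes are micrometeorological (negative =
uptake); GPP, Reco and modelled canopy COS uptake are non-negative
magnitudes. Conversions happen explicitly at module boundaries.

## Soil COS correction

Steady-state flow-through chamber fluxes are F = q·(C₂−C₁)/A (q in
mol s⁻¹ from the ideal-gas conversion of the volumetric flow, C in ppt,
A = 0.032 m² by default). A per-site random forest (500 trees, ⅓ of
features per split, minimum leaf 5, out-of-bag scoring; seeded and
therefore bit-reproducible) regresses chamber fluxes on shortwave
radiation at the soil surface, soil temperature and soil moisture, and
predicts the half-hourly soil flux, which is subtracted from the
ecosystem COS flux. Only measurements flagged stable enter the fit; the
stability flag is an input, not detected here. Drivers outside the
training hull produce a warning (forest predictions saturate), never an
error. The hyperparameters are conservative defaults for small-sample
environmental regression and are recorded in the model metadata.

## Calibration

1. **Nighttime E₀.** Records with PAR ≤ 10 μmol m⁻² s⁻¹ are nighttime.
   For fixed E₀ the RMSE-optimal rb is the closed-form least-squares
   amplitude, so (rb, E₀) reduces to a bounded 1-D profile minimisation
   over E₀ ∈ [0, 600] °C, grid-started to avoid local minima. E₀ is
   then held fixed; rb is re-estimated as a daytime parameter.
   Isothermal nights (range < 0.5 °C) raise an unidentifiability error.
2. **Likelihood.** iid Gaussian per data stream with free noise scales
   σ_NEE (and σ_COS for FP+), so the two streams weight themselves; the
   COS stream compares modelled canopy uptake with the negated
   soil-corrected canopy flux. Daytime records only.
3. **Priors.** α, β, rb, κ and the σ's are uniform with generous
   physical bounds (e.g. κ ∈ [0, 500] μmol m⁻² s⁻¹). ι defaults to a
   truncated normal (mean 1.7, sd 1.4, support (0, 10)) reflecting the
   leaf-level literature median 1.7 with wide 95% interval 0.7–6.2; a
   uniform(0, 10) alternative supports prior-sensitivity checks.
4. **Sampler.** Differential-evolution Metropolis (DREAM-style)
   population MCMC: chain i proposes x_i + γ(x_a − x_b) + e with
   γ = 2.38/√(2d), 10% of proposals at γ = 1 (mode jumps), and jitter e
   ~ N(0, (10⁻⁴·prior width)²). Default 2d chains (≥ 8). Convergence is
   checked every 250 iterations on the second half of the chains and
   declared only when all Gelman–Rubin R̂ < 1.1; sampling then continues
   until ≥ 2,950 post-convergence draws exist across chains (the
   reporting convention). Exhausting the budget flags the result
   UNCONVERGED — it is never silently returned as converged.
   Initialisation refines the best of 128 prior draws by Nelder–Mead
   and scatters chains at the mode ± 1% of the prior widths: plain
   DE-MC lacks the outlier-chain rescue of full DREAM (deliberately out
   of scope), and a chain started in a negligible-posterior region can
   otherwise stall indefinitely. This trades some R̂ sensitivity to
   multimodality for robustness; the fitted posteriors here are
   unimodal. A `init="prior"` option retains overdispersed starts.

## Reporting

GPP/Reco series evaluate the process equations over ≤ 500 retained
posterior draws per record; bands are equal-tailed 95% intervals and
GPP is structurally zero at night. The FP vs FP+ comparison statistic
is 100·(ΣGPP_FP+ − ΣGPP_FP)/ΣGPP_FP over the campaign, with a spread
computed as the sd of the same statistic per calendar day (the
sub-period is a package choice; the day is the natural diel unit).
Below-detection flags mark |flux| < 1.96·σ (multiplier configurable);
they annotate, never remove. A nighttime-extrapolation partitioning
variant (whole-campaign E₀/rb, no moving windows) is included as a
clearly-labelled, simplified cross-check only — it omits the windowed
parameter tracking of the standard nighttime method.

## Synthetic campaigns

The generator produces the statistical structure the analysis assumes,
with known truth: half-sine PAR over the daylength (peak at solar noon,
exactly zero at night), air/soil temperature sinusoids lagged 2 h/5 h
after noon, shortwave at the soil surface = transmission·PAR/2.1 (the
2.1 μmol J⁻¹ PAR↔shortwave conversion; only relative magnitudes matter
for the soil model), ±1% diel ripple on mole fractions, a soil COS flux
−baseline + slope·SW_soil (nocturnal uptake, radiation-driven daytime
emission), nocturnal canopy COS uptake at 20% of the mean daytime
uptake (incomplete stomatal closure; configurable), and iid Gaussian
observation noise, default σ_NEE = 1.0 μmol m⁻² s⁻¹ and σ_COS = 3.0
pmol m⁻² s⁻¹. Truth columns carry no noise, so every forward-model
identity holds exactly on them.

The four presets pin ι to the published per-site optima (GRA 1.02,
SAV 2.27, DBF 2.22, CRO 0.89) and choose α, β, rb, E₀, daylength and
soil coefficients so that midday NEE, peak canopy COS uptake
(~40 pmol m⁻² s⁻¹; ~80 at DBF) and the soil-flux sign patterns (daytime
emission at the open-canopy SAV, persistent uptake at DBF) match the
published magnitudes. For CRO the published midday NEE (~−20) and COS
uptake (~40 at ι = 0.89) are not exactly mutually consistent; the
preset favours the site's high productivity (midday NEE ≈ −28, COS
≈ 37). Campaign length defaults to 30 days (campaign durations are not
printed; a month is typical of intensive campaigns).

What the generator does **not** emulate: day-to-day synoptic
variability (every day repeats the same meteorology, so the per-day
spread of the FP vs FP+ difference degenerates to ~0 on synthetic
data), data gaps and QC screening, heteroscedastic or autocorrelated
flux errors (a heteroscedastic option exists behind the observation
model's noise argument but is off by default), canopy radiative
transfer and footprint effects. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data pathologies.

## Validation problem sizes

The recovery study uses the 30-day GRA preset (~870 daytime half
hours): FP+ posterior medians recover α, β, ι within 10% and rb within
15% of truth with all R̂ < 1.1. Band calibration is assessed pooled
over replicate 12-day campaigns of all four presets, because the
credible band covers a whole truth curve at once — any single campaign
yields nearly all-or-nothing pointwise coverage, and only the
replicate average is the calibrated ~95% quantity. Sampler moment
accuracy is checked on an analytic 2-D Gaussian at 50,000 retained
draws (≤ 3% error).

## Known limitations

- E₀ enters as a plug-in estimate; its sampling error propagates into
  daytime parameters (chiefly rb) but is not reflected in the credible
  bands — matching standard practice for this model family, and the
  main driver of occasional under-coverage in short campaigns.
- κ is weakly identified when few low-light records survive the
  daytime threshold (PAR > 10 μmol m⁻² s⁻¹); its posterior can be
  broad, and only its sign is treated as a recovery target.
- The soil random forest cannot extrapolate beyond the chamber
  campaign's driver range (predictions saturate at the hull).
- Whole-campaign fits assume stationary parameters; windowed or
  seasonal fitting is out of scope.
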