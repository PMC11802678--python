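# Methods

## Electrolyte-leakage injury index

The assay reads solution conductivity four times per sample: ultrapure-water
blank and needle solution, each before and after autoclaving (121 °C,
20 min) destroys the membranes. The index

    INX = 100 · (c_fresh − c_blank_fresh) / (c_auto − c_blank_auto)   [%]

is the standard blank-corrected relative-conductivity form; it is invariant
to a common rescaling of all four readings and strictly increasing in the
fresh-solution conductivity. Replicates are computed per replicate and then
averaged (arithmetic mean, sd reported). Small negative values down to
−0.5 % are treated as conductometer noise and clipped to zero with a logged
warning; anything more negative is rejected — a negative numerator beyond
noise means swapped readings or a contaminated blank, not biology. A
non-positive denominator is always an error naming the sample.

## Baseline extrapolation and oxidative stability

Injury grows with cumulative dose approximately exponentially over the
chamber range, so the six-point series is fitted with `INX = a·exp(b·x)` by
ordinary least squares on `ln INX` (equivalent to the usual spreadsheet /
stats-package "exponential trend"). The log-linear route was chosen over
iterative nonlinear least squares deliberately: it is closed-form,
reproduces the study's published baselines most closely of all estimators
tried (the published table is matched exactly in five of seven cells and to
within 0.06 percentage points in the other two — the residual is the
propagation of the inputs' one-decimal rounding), and weights the
small-injury points where the baseline extrapolation lives. `r` and `p`
are the correlation and slope significance of the linear fit.

Oxidative stability converts the injury increase over baseline into a
decimal: `OxS(n) = −(INX(n) − INX(0))/100`, bounded in [−1, 0]. A fitted
baseline slightly above a measured index gives a positive difference,
which is clipped to zero with a warning — injury below the no-ozone
baseline is not meaningful. Reporting precision is one decimal for INX,
two for OxS, one for doses; all computations keep full precision.

## Threshold inversion

OxS is regressed on sumO₃ with a least-squares polynomial. Degree defaults
to 2 (user-configurable): the series has six points, the curvature is
mild, and degrees above 3 are noise-chasing; the degree used for the
study's own figures is unpublished, which is why the inverted doses agree
with the published ones in magnitude (median ~6 %, worst ~25 % for the
species with the most irregular series) rather than exactly. The fit
carries a pointwise 0.95 confidence band (OLS mean-response interval on the
Vandermonde design).

The critical dose is the smallest positive root of `fit(x) = −0.05`,
located by a 4001-point scan of (0, 2·max dose] for a sign change and
polished with Brent's method to 1e−9. The smallest root is the
biologically first dose reaching 5 % injury; roots beyond the observed dose
range are returned but flagged as extrapolation, and a curve that never
crosses raises an error rather than guessing.

## Growing season and exposure metrics

A month belongs to the growing season iff it contains no day whose 24
hourly temperatures all sit below 5 °C; the season is the longest
contiguous run of qualifying months (ties broken toward the run containing
the warmest month), spanning whole months. Month granularity matches how
such seasons are reported; the detector requires complete month coverage
and will not infer across gaps.

sumO₃ is the plain sum of hourly ppb over the season divided by 1000
(ppm); avgO₃ = 1000·sumO₃/hours is its exact inverse. Rounding (e.g. to
tens of ppm for headline figures) is a parameter, never hard-coded. Hours
with missing O₃ are excluded and logged, with a 90 % coverage floor below
which the computation refuses to proceed — reproducibility over silent
gap-filling. AOT40 accumulates `max(0, O₃ − 40 ppb)` over daylight hours,
with daylight defined as global radiation ≥ 50 W m⁻² (configurable).

## Stomatal conductance and POD_Y

The conductance model is the standard multiplicative form

    gsto = gmax · f_phen · f_light · max(fmin, f_temp · f_vpd · f_SWP)

with: `f_temp` the bell curve
`((T−Tmin)/(Topt−Tmin))·((Tmax−T)/(Tmax−Topt))^((Tmax−Topt)/(Topt−Tmin))`,
zero outside (Tmin, Tmax); `f_light = 1 − exp(−a·PPFD)`; `f_vpd` piecewise
linear from 1 at vpd_min to fmin at vpd_max; `f_phen` a trapezoid over the
season window (ramp length in days; the default is 0 — evergreen needles
carry functional foliage through the whole season). Global radiation
converts to PPFD by a single documented constant (2.0 µmol J⁻¹, folding
the PAR fraction and quantum conversion together). Soil water (`f_SWP`) is
an input scalar or series with default 1; no water balance is computed.

Default species parameters are the boreal-conifer convention used in
European flux-risk mapping (gmax 112 mmol O₃ m⁻² PLA s⁻¹, fmin 0.1,
light_a 0.006, Tmin/Topt/Tmax 0/14/35 °C, vpd range 0.8–2.8 kPa), shipped
as named presets with per-species overrides; *P. sylvestris* borrows the
*P. cembra* set and *A. alba* the *P. abies* set, mirroring
parameterisation by related species. Every constant is overridable via a
flat key-value parameter file.

The flux partition is the canonical leaf-level resistance chain:
concentration converts to nmol m⁻³ by the ideal-gas state (measured
pressure when present, standard otherwise), the boundary-layer resistance
is `rb = 1.3·150·√(L/u)` with needle dimension L = 8 mm and a constant
default wind of 2 m s⁻¹, the surface resistance is `rc = 1/(gsto + gext)`
with external (cuticular) conductance 1/2500 m s⁻¹, and
`Fst = c · gsto · rc/(rb+rc)` in nmol m⁻² PLA s⁻¹.

POD_Y accumulates `max(0, Fst − Y)·3600·10⁻⁶` over daylight season hours
(nights contribute nothing anyway, as `f_light` closes the stomata);
POD₀ (Y = 0) is used throughout. For the critical-level projection the
same chain runs with the hourly concentration replaced by the flat
seasonal avgO₃ for all 24 h — night flux self-suppresses, so the choice
between 24 h and daylight-only flat profiles is immaterial; POD₀ is then
exactly linear in the flat concentration, which the tests pin down. With a
daytime-peaking diurnal profile the ambient POD₀ exceeds the flat
same-mean POD₀, because high O₃ coincides with open stomata.

Absolute POD₀ values from this implementation are *not* one-to-one
comparable with the study's published values: those rest on unpublished
station met data and a supplementary parameter table. The pipeline's
claims are structural — linearity, monotonicity in Y, the ratio identities
— plus the published POD₀ pairs re-used as inputs for the utilisation
arithmetic `100·POD₀(ambient)/CL(OxS)`.

## GC–MS composition

Per sample, each identified peak area is divided by the sample's total
identified area (percentages). Classification is formula-driven, not
name-driven: exactly C₁₀H₁₆ → monoterpene, C₁₅H₂₄ → sesquiterpene,
oxygen-bearing with 7–8 carbons → C₇₋₈HₙOₓ oxidation products,
oxygen-bearing with ≥ 20 carbons → C₂₀₊HₙOₓ; everything else is "other"
and stays in the normalising total. An override map handles edge
compounds. The ANOVA is the classical one-way fixed-effects F test
(cross-checked in the tests against an independent sums-of-squares oracle
and `scipy.stats.f_oneway`), reporting group means with t-based 0.95
confidence intervals; zero within-group variance with unequal means is
reported as F = ∞ rather than an exception. The reporting threshold is
p < 0.05.

## Synthetic data

The generators define the study conditions the tests run under:

* **Met years** — seasonal + diurnal temperature harmonics with unit
  Gaussian noise, parameterised per zone (alpine: January mean −8 °C, July
  12 °C; foothill: −4/16 °C). A deterministic all-cold day is inserted
  mid-month in every month outside the target season (spring/autumn cold
  snaps), so the 5 °C rule reproduces the study's seasons exactly —
  June–September alpine, May–September foothill. O₃ is the zone mean
  (52.7 ppb alpine, 27.5 ppb foothill, matching the ambient sums of
  ~154/~101 ppm over the respective seasons) plus a zero-mean diurnal
  harmonic — amplitude 0 for the alpine "flat" profile, 12 ppb
  afternoon-peaking for the foothill. Radiation is a clear-sky arch with
  multiplicative cloud noise; RH noise feeds a Tetens VPD.
* **Dose ladders** — ambient sum plus 150 ppm × {1,3,5,7,10} h, with
  optional lognormal rate jitter (σ = 0.05) per exposure interval.
* **Conductivity tables** — truth `INX(x) = a·exp(b·x)` with
  multiplicative lognormal noise (defaults a = 10 %, b = 0.0008 ppm⁻¹,
  σ = 0.05, three replicates — magnitudes of the study's series), inverted
  into conductivities so the injury stage recovers the noisy index
  exactly. The analytic −0.05 crossing `ln(1 + 5/a)/b` is carried along as
  the recovery target.
* **Peak tables** — Dirichlet class proportions (concentration 150) around
  sesquiterpene-dominated base shares, with a monoterpene-depletion /
  C₇₋₈-accumulation shift per ozonation category; effect 0 gives the
  exchangeable null for type-I calibration.

Each generator call derives its own stream from the single integer seed;
identical seeds give bit-identical outputs. What the generators do *not*
emulate: weather-generator calibration to real climate normals, chamber
fluid dynamics, within-day O₃–met covariance beyond the fixed harmonics,
and compound-level (as opposed to class-level) composition effects —
passing tests therefore certify the pipeline's statistics and algebra, not
the climatology of any real site.

## Numerical and scale choices

Simulation sizes were chosen to keep the whole suite desk-scale: 200
replicates for parameter recovery (median |error| ~2 % at σ = 0.05, well
inside the 10 % requirement), 100 for the noisy inversion, 1000 nulls for
ANOVA calibration (observed type-I ≈ 5 %), one synthetic year per zone for
the flux stages. Degenerate inputs fail loudly (no root, zero denominator,
coverage below floor, incomplete months) rather than returning NaN. The
root finder's 1e−9 tolerance and the 4001-point bracket scan are far below
any scientifically meaningful resolution of the dose axis.

Known limitations: exact reproduction of the published critical doses
would require the study's unrounded injury indices and per-series
polynomial choices; the flux model's absolute level depends on species
parameters only available by convention; and the season detector is
deliberately month-grained, so it cannot express mid-month season starts.
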