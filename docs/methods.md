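# Methods

This note records the models implemented in `plate_smfret`, their
assumptions, the defaults that matter, and the design choices made where
several reasonable options existed. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic photon streams

The generator (`simulate`) emulates diffusion-based confocal smFRET with
pulsed-interleaved excitation at the level the downstream analysis assumes:

- **Bursts.** Molecule arrivals are a Poisson process (`burst_rate`,
  default 1.1/s ≈ 1300 per 20-min well). Transit durations are exponential
  with mean `transit_mean` (default 1 ms, the typical confocal passage
  time); a fixed-duration mode exists because the dynamic-histogram theory
  is exact for a single duration and analytic tests need that limit.
  Emission intensity is flat-top during transit (`brightness`, default
  1×10⁵ detected photons/s across channels) — no Gaussian excitation
  profile, no triplet blinking, no photobleaching.
- **Two-state dynamics.** When `k_open`/`k_close` are nonzero the
  conformational trajectory within each transit is simulated exactly
  (Gillespie); `states[0]` is the open state and the initial state is drawn
  from the equilibrium occupancy `k_open/(k_open+k_close)`. The per-burst
  occupancy fractions, switch counts and time-averaged E are recorded as
  ground truth.
- **Channel intensities.** Per state with efficiency E:
  `r_DD = Λ(1−E)`, `r_AA = f_AA·γ·β·Λ`,
  `r_DA = Λ(γE + α(1−E)) + δ·r_AA`. This makes the detection
  imperfections (α leakage, δ direct excitation, γ detection ratio, β
  excitation ratio) part of the forward model, so the correction pipeline
  can be validated by round trip; with identity corrections it reduces to
  binomial partitioning by E. Because Poisson thinning is used, channel
  counts conditional on the total are exactly binomial. `β` absorbs the PIE
  duty-cycle factor when `f_AA ≠ 1`; the round-trip tests therefore use
  `f_AA = 1`. PIE is modelled at the count level only — nanotimes,
  lifetimes and polarisation are out of scope.
- **Species.** Donor-only molecules emit `r_DD = Λ`, `r_DA = αΛ` (so their
  apparent E is the leakage signature `α/(1+α)`); acceptor-only molecules
  have `r_DD = 0` and `r_DA = δ·r_AA` (apparent S → `δ/(1+δ)`).
- **Background** is Poisson per channel over the full acquisition.
  Timestamps are quantised to a 12.5-ns clock (configurable) and made
  strictly increasing by minimal forward bumps.
- **Plates.** Per-well seeds derive from `(master_seed, CRC32(well_id))`,
  so results are independent of processing order. Titration tables draw
  state assignments as multinomials (`counts/n` fractions, binomial SD with
  a `1/(2n)` floor), matching a counting-statistics error model.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: brightness variation across the focus (real burst
size distributions are broader), acceptor photophysics (blinking inflates
apparent dynamics), spectral crosstalk beyond a single leakage coefficient,
and instrument drift.

## Burst search and per-burst scores

All-photon sliding window: a photon is in-burst when ≥ `min_rate_photons`
photons (itself included) lie within ±`window/2`; consecutive in-burst
photons form candidates; candidates below `min_total_photons` are dropped.
Defaults (window 500 µs, rate 10, total 50) are conventional fallbacks —
real analyses should set them per experiment. Burst duration spans first to
last photon, floored at one clock tick. Background-corrected counts
`b_X = n_X − rate_X·T` are kept when negative so E/S estimators stay
unbiased. Background estimation offers out-of-burst mean rates (default),
an inter-photon-delay tail fit, and whole-trace means (< 100 photons falls
back to the latter with a warning).

Burst-variance analysis (BVA) uses donor-excitation photons only, windows of
n consecutive photons (default 5–8), and flags bursts whose windowed
proximity-ratio SD exceeds the binomial shot-noise limit `sqrt(Ē(1−Ē)/n)`.
Bursts shorter than one window are flagged undefined, never dropped.

## Corrections

Apparent values: `E_app = b_DA/(b_DA+b_DD)`,
`S_app = (b_DD+b_DA)/(b_DD+b_DA+b_AA)`; non-positive denominators give NaN
flags. Corrected values follow the standard chain
`F_AD = b_DA − α·b_DD − δ·b_AA`, `E = F_AD/(γ·b_DD + F_AD)`,
`S = (γ·b_DD + F_AD)/(γ·b_DD + F_AD + b_AA/β)`.

Factor derivation: α from donor-only bursts (`S_app > 0.9`), δ from
acceptor-only bursts (`S_app < 0.2`), γ and β from the two-population
method — after α/δ correction, `1/S = 1 + γβ + (1−γ)β·E` is linear in E, so
a line through two double-labelled populations of distinct E (|ΔE| ≥ 0.1
required) determines both. Population centroids are computed as *ratios of
summed counts* over the sigma-clipped main mode of each population: the
flux-weighted ratio estimator is unbiased at the population level, whereas
the mean of per-burst ratios is not; the sigma clip (a robust Gaussian-mode
fit) supplies the outlier resistance that per-well Gaussian fitting is used
for in practice. The population split is a deterministic 1-D two-means
assignment on E.

## Histogram models

E histograms default to 50 uniform bins over [−0.1, 1.1]. Mixture fits are
Poisson-weighted least squares (weights `1/sqrt(max(model,1))`, refined once
from the first-pass model so empty bins still constrain the fit), via lmfit;
components are reported ordered by mean with fractional amplitudes, 68% CIs
from the parameter covariance. Initial means come from the empirical CDF
quantiles unless supplied.

**Dynamic two-state fits.** The load-bearing constraint is the coupling of
component amplitudes to the exchange rates through the no-switch
probabilities: `A_O = p_O·e^(−k_close·T)`, `A_C = p_C·e^(−k_open·T)`,
`A_B = 1 − A_O − A_C`, with `T` the mean burst duration of the fitted well
(not a global constant). Three bridge parameterisations are implemented:

- `exact` (default): the bridge is the exact occupancy-fraction density of
  the two-state telegraph process (modified-Bessel closed form,
  `occupancy_fraction_density`), mapped onto the E axis and smoothed by the
  occupancy-interpolated static widths. Free parameters: the two rates, two
  static means, two static widths, total count.
- `moments`: a single Gaussian whose mean and width are moment-matched to
  the conditional occupancy distribution (closed-form time-average moments
  of the telegraph process, validated against Monte-Carlo path sampling in
  the tests).
- `free`: a single Gaussian with free mean (bounded strictly between the
  static means) and width.

The Gaussian-bridge variants are the common literature approximation, but on
simulated data with well-separated, shot-noise-narrow static peaks the
conditional occupancy density is strongly non-Gaussian (heavy toward the
static values), and least squares then reassigns bridge mass to the static
components, biasing both rates low by 25–50% in the k·T ≈ 1–3 regime. The
exact-density bridge removes that bias (recovery within ~10% across
k·T ∈ [0.3, 3] in the acceptance tests) at negligible cost, which is why it
is the default; the Gaussian variants remain for comparison with analyses
that use them. When the fitted bridge amplitude is indistinguishable from
zero, rates are flagged as upper bounds.

## Hairpin salt dependence

Opening is linear in salt (weighted least squares). Closing is
pseudo-bimolecular: `k_close(c) = k′_close·[A]`, with the apparent local
concentration `[A] = 1/(N_A·(4/3)πR³)` from the WLC end-to-end distance
`R²  = 2·l_p·l_c − 2·l_p²(1 − e^(−l_c/l_p))` at contour length
`l_c = 14.2 nm` (dT21 loop) and persistence length
`l_p(I) = l_p_∞ + (l_p_0 − l_p_∞)·e^(−I/I_s)` with `l_p_0 = 2.09 nm`,
`l_p_∞ = 0.75 nm`. The decay scale `I_s` (default 0.3 M, the order of the
Debye screening crossover for ssDNA flexibility) and the whole `l_p(I)` form
are pluggable — published parameterisations differ and the choice only
shifts the mid-salt interpolation, not the limits. Ionic strength maps as
`[NaCl] + 0.01 M` buffer contribution (configurable). Rates are carried in
1/ms inside the module, `k′_close` in 1/(s·M) at the boundary.

With these conventions the closing-rate bounds from the two `l_p` limits
evaluate to ≈ 0.33 and ≈ 1.34 ms⁻¹ (`closing_rate_bounds`); the bounds
*ordering* and the monotonicity of `k_close(c)` are contracts tested on
parameter grids. Published analyses of the same system quote different
numeric bounds from a supplementary volume convention that is not fully
specified; this implementation documents its convention (RMS end-to-end
distance as sphere radius) rather than forcing agreement.

Bootstrap sampling-density analysis: subsample n conditions without
replacement, refit the linear opening model, report the SD of the zero-salt
intercept over replicates (seeded, deterministic).

## Equilibrium models

- **LEM**: `f_U = 1/(1+exp(m([D]_1/2 − c)/RT))`, R = 8.314×10⁻³
  kJ·mol⁻¹·K⁻¹, T default 298.15 K. `ΔG_H2O = m·[D]_1/2` by construction.
  When the fraction table carries burst counts, the fit is iteratively
  reweighted with *model-based* binomial SDs: weights estimated from the
  observed fractions are correlated with their own noise and demonstrably
  bias the slope upward.
- **Chain dimensions**: `⟨E⟩ = ∫ P(r|Rg)(1+(r/R0)⁶)⁻¹ dr` with the
  Gaussian-chain end-to-end density (`⟨r²⟩ = 6Rg²`) by default, any
  `P(r|Rg)` pluggable; inverted for Rg by bisection to |ΔE| < 10⁻⁶.
- **Coil–globule**: a single-chain mean-field free energy
  `βf(α) = (3/2N)(α²−1−2lnα) + ((1−φ)/φ)ln(1−φ) + 1 − εφ/2` with
  `φ = φ_Θ/α³`, monomer count N (default 100) and interaction strength
  linear in denaturant activity, `ε(a) = ε₀ + ε₁·a`. The Θ point (α = 1)
  is located numerically; the fit reports `Rg_Θ` and the activity where the
  chain crosses it. The fit multistarts over a deterministic (ε₀, ε₁) grid
  because the minimiser-inside-a-fit objective is multimodal. The
  denaturant activity map is the identity by default (an activity table can
  be supplied); the scaling exponent ν enters only through the caller's
  choice of `Rg_Θ` convention.
- **Speciation** (two SSB binding modes): statistical weights `1`,
  `(S/c_{1/2})^m`, `(S/c_{1/2})^m(S/c*_{1/2})^n`, fractions normalised;
  simultaneous weighted fit of all three curves with half-occupancy
  concentrations in log space (they span pM–µM).
- **Six-state competition**: partition function over
  `{T, TS_m, TS_{m+n}, TR_p, TR_qS_m, TR_rS_{m+n}}` with weights built from
  half-occupancy concentrations (`c_{i,1/2} = K^{1/i}`); the mixed-state
  constants relate to the bare RecA constant through cooperativity factors
  α, β, and thermodynamic-square consistency holds by construction of the
  weights. The configuration enumerator is generic: each subset of the
  optional mixed states defines a scheme, and every subset of its non-DNA
  states containing TS_m is a candidate observable assignment for
  f(E > 0.4) — 36 configurations for the default state sets, each fitted by
  weighted least squares with the SSB-only speciation parameters held
  fixed, ranked by `χ²_r = χ²/(N − n_params)` with ties broken toward fewer
  parameters. Selection is by χ²_r alone (no additional complexity
  penalty), mirroring common practice; the enumerated count is reported so
  alternative enumeration conventions can be compared.
- **Dose–response**: `f(c) = f_min + (f_max−f_min)c^h/(EC50^h + c^h)`,
  EC50 in log space, weighted; concentrations above `exclusion_max` are
  dropped *before* fitting and listed with the reason. A span smaller than
  twice the mean counting SD flags `no_response` with unbounded EC50.

In addition to the covariance-based 68% CIs, every fraction-table fit can be
wrapped in `parametric_bootstrap_ci`: counts are redrawn from the fitted
model (binomial or multinomial per well, seeded), the fit repeated, and
central percentile intervals reported — useful when the counting noise makes
the quadratic covariance approximation doubtful.

## Plate pipeline

Layout CSVs carry `well_id` plus arbitrary condition columns; 48/96/384-well
geometries are validated. The per-well chain (background → burst search →
optional filter → corrections → histogram → configured model) isolates
failures per well, processes wells in sorted order (results independent of
input order), and returns a tidy per-well table plus fit objects and
histograms. An optional plate-level fit (`plate_fit` in the pipeline
config) runs one of the cross-well models — LEM, dose–response, or the
hairpin salt dependence — on the per-well results keyed to a layout
condition column. QC regresses bursts/min on acquisition order (default
row-major A01→H12) and flags significant negative slopes at a configurable
two-sided 0.05 level.

## Problem sizes and numerical choices

The test suite and acceptance script use simulation sizes chosen as the
smallest that make the statistical contracts sharp: ~3000 bursts per
condition for rate recovery (matching the per-well scale of a plate
screen), 96 conditions for titration fits, 2000 bursts/well counting noise
for fraction tables, 100 replicates for selection-consistency, 60–200
random streams for the burst-search oracle. Optimiser settings: lmfit
Levenberg–Marquardt with a single weight refinement pass for histogram
fits; `scipy.optimize.least_squares` with concentrations in log10 for
binding models; bisection/brentq tolerances 10⁻⁶–10⁻⁸. Degenerate inputs
(empty streams, empty filter results, flat dose responses, out-of-range
transitions) warn and flag rather than raise wherever they are legitimate
data rather than usage errors.

## Known limitations

- The generator's flat-top transit intensity makes detected burst sizes
  more uniform than real data; burst-search recall on real streams will be
  lower at the same thresholds.
- The exact-density dynamic fit assumes a single transit duration (the
  well's mean); strongly non-exponential duration mixtures would need the
  empirical-duration integration that is provided but off by default.
- The coil–globule free energy is one member of a family of mean-field
  forms; its parameters (ε₀, ε₁, φ_Θ) are effective and comparable only
  within the same form.
- Correction-factor derivation assumes both calibration populations share
  one γ/β; per-species quantum-yield differences are out of scope.
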