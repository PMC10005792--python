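# Methods

## Relaxation model

The spin-lattice rate measured by fast-field-cycling relaxometry is
modelled as a sum of Lorentzian spectral-density contributions plus a
constant,

R₁(ω) = Σₖ C_k^DD [ τₖ/(1+(ωτₖ)²) + 4τₖ/(1+(2ωτₖ)²) ] + A,

where ω = 2πν is the ¹H Larmor frequency in angular units. Public
interfaces take ν in Hz — the quantity instruments report and figures
plot — and apply the 2π conversion exactly once, internally. Units are
fixed throughout: C^DD in Hz² (≡ s⁻²), τ in s, R₁ and A in s⁻¹; there is
no unit-conversion layer. Between one and four components are supported;
hydrogel data need three (slow ~10⁻⁶ s, intermediate ~10⁻⁷ s, fast
~10⁻⁸ s), and the fourth slot exists so model selection can probe
over-parameterization. Components are stored sorted by strictly
decreasing τ and, for three-component models, labelled slow /
intermediate / fast by rank.

Useful closed forms used as test oracles: the bracket equals 5τ at
ω = 0, so R₁(0) = 5ΣC_kτ_k + A; R₁ is non-increasing in ν; and
R₁(ν) − A ≤ 5ΣC_kτ_k/(ωτ_min)² at high frequency.

## Recovery curves and measurability

Longitudinal magnetization recovers mono-exponentially,
M(t) = M_eq + (M_init − M_eq)e^(−R₁t); the three-parameter form covers
saturation and inversion recovery without a sign constraint. Points
earlier than the field-switching dead time (default 3 ms, configurable)
are discarded; at least 6 points must remain. Fits use
`scipy.optimize.least_squares` with the analytic Jacobian; the reported
1σ on R₁ comes from the Gauss–Newton covariance with the residual scale
floored at 10⁻¹² of the recovery amplitude, so that on noise-free data
the uncertainty degrades monotonically as information is removed instead
of collapsing to numerical noise.

A rate is flagged *unmeasurable* when more than 95% of the recovery is
lost within the dead time, i.e. exp(−R₁·t_dead) < 0.05, giving a maximum
measurable rate of ln 20 / 3 ms ≈ 1.0×10³ s⁻¹ at the defaults. Both the
loss fraction and the dead time are parameters. This convention is
deliberately conservative: the study emulated by the generator measured
rates up to ~4.5×10³ s⁻¹ at its lowest frequencies, so the true
instrument limit sits above this default; see "Synthetic data" below for
how the generator reconciles the two. When only the recovery tail is
observed the fitted rate may be biased; the package flags this situation
(larger uncertainties, measurability flag) but applies no correction.

Mono-exponentiality is checked with two conservative signals: a
Wald–Wolfowitz runs test on the signed residuals (p < 0.01 fails) and a
comparison of the residual RMS against a point-to-point noise estimate
obtained from first-differenced residuals divided by √2 (RMS above 5×
the estimate fails). The thresholds were calibrated so that a clean
single exponential with 1% noise passes in ≥95% of seeds while an
equal-amplitude bi-exponential with rates two decades apart always
fails.

## Profile fitting

Weighted nonlinear least squares over the uncensored points of one or
more profiles. Numerical choices:

- **Parameter space.** C and τ are optimized as log₁₀ values (bounds
  10⁻⁶–10¹⁴ Hz² and 10⁻¹²–10⁻³ s), which enforces positivity and evens
  out scales spanning several decades; A is linear with a lower bound of
  0.
- **Weights.** 1/σ² with σ the supplied uncertainties; when absent,
  relative weighting σᵢ = R₁ᵢ, appropriate for profiles spanning two
  decades in R₁.
- **Initialization.** τ starts on the decades 10⁻⁶/10⁻⁷/10⁻⁸ s; each C
  starts at (max R₁ − min R₁)/(5τk) so the zero-frequency contributions
  split the observed dispersion evenly; A starts at 0.9× the
  high-frequency floor. Five multi-starts, the first unjittered, the
  rest with seeded N(0, 0.3)-decade jitter; a single top-level seed
  threads through all starts and is recorded in the result.
- **Constraints.** A `ConstraintMap` assigns each (profile, parameter)
  slot free, fixed(value) or shared(group); shared groups occupy one
  optimization slot, so members are bit-identical in the output, and
  fixed slots never enter the optimizer. An all-fixed map degenerates to
  evaluate-only mode with a warning; rank deficiency of the Jacobian and
  τ collisions (ratio < 2 between neighbours, suggesting a merged
  component) raise warnings. If the optimizer returns components out of
  τ order they are relabelled by rank, with a warning.
- **Uncertainties.** 1σ from the scaled covariance (J^TJ)⁻¹·χ²/(n−p),
  mapped from log to natural scale by σ_x = x ln10 σ_log. The source
  tables do not state how their uncertainties were computed; the values
  reported here are covariance-based and may differ from published ones
  in detail.
- **Model selection.** AIC = n ln(χ²/n) + 2p over k = 1..k_max; ties
  within 2 AIC units resolve to fewer components.
- **Parsimony search.** Starting from the fully-shared fit of a profile
  set, blocks are freed greedily in the fixed order (C_i, τ_i) → τ_s →
  C_f → C_s → A — the hierarchy observed in temperature studies of
  gelled sweets, where the confined-water contribution responds first —
  and kept only if AIC improves by ≥10 (configurable). Each trial is
  warm-started from the incumbent solution, so freeing a block can never
  increase χ². Censored points are excluded, never imputed.

The published Haribo analysis was a joint description with C_s, C_f and
τ_f common to all jellies and temperatures, τ_s common across
temperature for bear/phantasia and A common across temperature per
jelly; `nmrdfit.study.haribo_constraint_map` reproduces that structure
(sharing A jointly rather than sequentially fixing it at the
lower-temperature estimate — one optimization instead of two passes).
The Vidal rows were fitted per group with the parameters printed without
uncertainties clamped; `vidal_fixed_values` extracts those clamps from
the catalog.

## Fingerprint grouping

Profiles are compared as fingerprints: resampling by log-log linear
interpolation (exact for power laws, no extrapolation beyond the
uncensored span), distance = mean |Δlog₁₀R₁| over a 24-point log-spaced
grid on the intersection of spans, grouping by single-linkage clustering
cut at 0.03. The threshold corresponds to ≈7% relative difference in R₁
and was chosen so that independent 2%-noise realizations of the same
generator co-group (their expected distance is ≈0.01) while distinct
catalog recipes separate. Published overlap judgments are visual; this
quantification is a package convention, not a community standard.

## Synthetic data

The generator emulates an FFC study of jelly candies: 32 log-spaced
frequencies from 10 kHz to 10 MHz, profiles computed from the packaged
parameter catalog, multiplicative Gaussian noise with cv = 0.02 (a
typical FFC instrument specification; the emulated study does not state
its noise level), reported uncertainties σᵢ = cv·R₁ᵢ, and per-profile
noise streams spawned deterministically from a single seed so datasets
reproduce byte-for-byte. Recovery curves default to 48 delay points over
five time constants — a common schedule; at 2% additive noise it
determines R₁ to better than 2% median error, which thinner schedules do
not.

Censoring and the catalog rows: applying the default measurability
cutoff (~10³ s⁻¹) to every generated profile would censor low-frequency
points of rows the real experiment did measure (their R₁(0) reaches
4.5×10³ s⁻¹), because the real instrument limit exceeded the
conservative default. `make_dataset` therefore generates catalog rows
uncensored, matching the data coverage of the study, and applies the
dead-time rule only where the study reports missing data: the Vidal
brand at 298 K. No catalog rows exist there (the experiment could only
reach high and intermediate frequencies); these profiles are emulated —
a synthetic-only convention flagged in the profile metadata — by reusing
the 323 K parameters with all correlation times doubled, which slows the
dynamics enough that the censoring mechanism reproduces the missing
low-frequency region by itself. `make_profile` applies censoring
whenever an explicit dead time is passed, always consistently with the
measurability rule.

The catalog stores the published values verbatim as decimal strings
(bit-exact round-trips through CSV and JSON) with per-parameter fixed
flags defined by "printed without an uncertainty".

## What passing tests show — and what they do not

The test suite and the acceptance script work entirely on synthetic data
with known ground truth. They demonstrate that the implementation is
correct (noise-free round-trips at ≤0.1%, agreement with arithmetic and
grid-search oracles, exact constraint bookkeeping) and that the analysis
design is statistically sound at the emulated noise level (parameter
recovery, component-count selection, parsimony block identification,
fingerprint grouping). They do not validate the noise model against the
real instrument, cover field-switching transients, temperature drift or
multi-exponential recovery, nor establish that the grouping threshold
matches any laboratory's visual judgment.

One documented limit: the slow-dynamics parameters of the Vidal cherry
recipe cannot be recovered to better than ~20% median error from a
single 32-point profile at 2% noise — the Cramér–Rao bound for that
parameter set implies ≈24% (C_s) and ≈18% (τ_s) median error, and the
published table itself quotes 27% and 21% relative uncertainties for
those entries. The corresponding recovery assertion in the acceptance
tests is intentionally strict and fails for exactly those two
parameters, with the fits verified to sit at the statistical efficiency
limit (fit χ² ≤ χ² at the generating values in every seed).

## Problem sizes

Default study sizes used by the tests and the acceptance script: 32
frequency points per profile; 20 seeds for component selection,
parsimony and grouping studies; 50 seeds for parameter-recovery
medians; 100 random models for the evaluation oracle; 200×200 grids for
the optimizer cross-check. These sizes give stable medians and rates
while keeping a full run in the minutes range on one CPU.
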