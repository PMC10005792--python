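# nmrdfit

Decomposition and shared-parameter fitting of ¹H spin-lattice relaxation
dispersion (NMRD) profiles from fast-field-cycling NMR relaxometry, built
around the analysis of water–biopolymer systems such as jelly-candy
hydrogels.

## Who this is for

Fast-field-cycling (FFC) relaxometry measures the spin-lattice relaxation
rate R₁ as a function of ¹H Larmor frequency ν, typically from ~10 kHz to
~10 MHz, probing molecular motion from milliseconds to nanoseconds in a
single experiment. The price is non-trivial data analysis: extracting
correlation times and dipolar relaxation constants requires fitting
multi-component spectral-density models, often jointly over many samples
and temperatures with shared parameters. `nmrdfit` packages that analysis
— model evaluation and decomposition, recovery-curve fitting,
constrained global fitting with a parsimony search, and fingerprint-based
sample grouping — together with a synthetic-data generator so the whole
pipeline is testable at desk scale.

## The model

The dispersion profile is described as a sum of Lorentzian spectral
densities plus a frequency-independent offset:

```
R₁(ω) = Σₖ C_k^DD [ τₖ/(1+(ωτₖ)²) + 4τₖ/(1+(2ωτₖ)²) ] + A ,   ω = 2πν
```

with, for soft hydrogels, three components: *slow* (τ_s ~ 10⁻⁶ s,
macromolecular network dynamics), *intermediate* (τ_i ~ 10⁻⁷ s, water
confined in the matrix) and *fast* (τ_f ~ 10⁻⁸ s, loosely bound water).
Each C_k^DD (in Hz²) scales with the amount of ¹H pairs relaxed by that
process; A collects motions far faster than the probed window.

On top of single fits the package implements the *parsimony strategy*:
profiles measured at two temperatures (or for two products) are fitted
jointly with all parameters shared, and parameter blocks are freed one at
a time — intermediate dynamics (C_i, τ_i) first — keeping a block only if
it improves the AIC by a configurable margin (default 10). The result is
the smallest set of parameters that explains the differences between
profiles. Profile *fingerprints* are compared as the mean |Δlog₁₀R₁| over
a common frequency grid, and samples are grouped by single-linkage
clustering at a 0.03 threshold (≈7% relative difference in R₁).

A parameter catalog replicating the published three-component fits for
six Haribo and six Vidal jelly products (298 K and 323 K) ships with the
package and drives the synthetic-data generator.

## Worked example

Fit a synthetic two-temperature pair of bear-jelly profiles (2% noise)
with the parsimony search:

```python
import nmrdfit as nf

catalog = nf.load_default_catalog()
grid = nf.FrequencyGrid.log_spaced(1e4, 1e7, 32)

pair = [
    nf.make_profile(catalog.model_for("bear", T), grid,
                    nf.NoiseSpec(0.02, seed),
                    sample_id="bear", temperature_k=T)
    for T, seed in ((298, 1), (323, 2))
]

search = nf.ParsimonySearch(delta_aic=10.0, random_state=0).fit(pair)
print("freed blocks:", search.freed_blocks_)
for model, (sid, T) in zip(search.result_.models, search.result_.profile_keys):
    p = model.to_params()
    print(f"{sid} @ {T:g} K: C_i = {p['c_i_dd']:.3g} Hz^2, "
          f"tau_i = {p['tau_i']:.3g} s, A = {p['a']:.1f} 1/s")
```

which prints

```
freed blocks: [('c_i_dd', 'tau_i')]
bear @ 298 K: C_i = 9.8e+08 Hz^2, tau_i = 4.9e-07 s, A = 27.5 1/s
bear @ 323 K: C_i = 7.85e+08 Hz^2, tau_i = 3.49e-07 s, A = 27.5 1/s
```

The search frees exactly the intermediate-dynamics block: heating this
gel changes only the confined-water contribution (its dipolar constant
drops and its correlation time shortens), while the slow and fast
processes and the offset stay shared between the two temperatures — the
generating values were C_i = 1.00×10⁹ / 8.02×10⁸ Hz² and
τ_i = 4.83×10⁻⁷ / 3.49×10⁻⁷ s.

The same pipeline is available from the shell:

```sh
nmrdfit simulate -o out --seed 1            # synthetic dataset from the catalog
nmrdfit fit out/profiles/Haribo_bear_*.csv -o fits --seed 1
nmrdfit compare out/profiles/*_298K.csv -o cmp --threshold 0.03
nmrdfit eval --params fitted_params.json -o eval --decompose
```

## Layout

- `src/nmrdfit/model.py` — model types, evaluation, decomposition
- `src/nmrdfit/recovery.py` — magnetization-recovery fits, measurability
- `src/nmrdfit/profile.py` — NMRD profile container and CSV dialect
- `src/nmrdfit/constraints.py` — shared/fixed/free declarations
- `src/nmrdfit/fitting.py` — single/global fits, parsimony, selection
- `src/nmrdfit/fingerprint.py` — distances and overlap grouping
- `src/nmrdfit/synthetic.py` — parameter catalog and data generator
- `src/nmrdfit/study.py` — published-scenario constraint recipes
- `src/nmrdfit/cli.py` — `nmrdfit` command-line pipeline
- `docs/methods.md` — modelling assumptions and numerical choices
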