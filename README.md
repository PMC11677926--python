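# hdospec

Tools for characterising solute hydration shells — and the interaction of
two solutes' hydration shells — from infrared spectra of semi-heavy water
(HDO), plus the post-processing of quantum-chemical hydration clusters into
O⋯O distance statistics.

## Who this is for

Vibrational spectroscopists studying solute hydration with the HDO
difference-spectra technique: the decoupled OD stretch of dilute HDO in
H₂O reports the hydrogen-bond state of individual water molecules without
the intramolecular coupling that complicates neat H₂O or D₂O spectra.  The
package covers the full analysis chain for binary (solute–water) and
ternary (solute A–solute B–water) systems, with seeded synthetic-data
generators so every stage can be validated by parameter recovery.

## The models

**Two-state affected water.**  Solution water is split into bulk water
(spectrum ε_b, indistinguishable from pure water) and *affected* water
(spectrum ε_a, perturbed by the solute).  At solute molality *m*,

    ε_a = (ε − ε_b) / (N·M·m) + ε_b,

where *N* is the *affected number* (moles of water perturbed per mole of
solute) and *M* the mean molar mass of the water (kg·mol⁻¹, including the
D₂O share).  *N* is fixed by spectral non-negativity: the smallest *N*
keeping ε_a ≥ 0 everywhere, which is sharp when the affected band truly
reaches zero inside the analysis window (`hdospec.affected`).

**Ternary decomposition.**  If two solutes act independently, the mixture's
affected spectrum is the weighted mean
ε_theor = (N_A·ε_A + N_B·ε_B)/(N_A + N_B) and ΔN = N_exp − N_theor ≈ 0.
Deviations are resolved by a seeded stochastic fit

    N_exp·ε_exp ≈ w_A·ε_A + w_B·ε_B + N_changed·ε_changed,

whose non-negative residual is the spectrum of *changed-affected* water —
molecules perturbed by both solutes at once (`hdospec.ternary`).  Negative
ΔN means overlapping shells (shared waters); positive ΔN means extra
perturbed or bridging waters.

**Band geometry.**  Band contours map onto intermolecular O⋯O distance
distributions through the empirical solid-hydrate correlation

    ν_OD/cm⁻¹ = 2727 − exp(16.01 − 3.73·R_OO/Å),
    P(R_OO) = C·ε(ν(R_OO))·dν/dR_OO,

with C normalising ∫P dR = 1 (`hdospec.bands`).  Because the Jacobian
varies across the band, the maximum of P(R) is *not* the image of the band
maximum; the offset vanishes only for narrow bands.

**ATR screen and shell geometry.**  `hdospec.atr` implements the
concentration-difference screen for *direct* solute–solute interactions
(vapor subtraction, water background scaled by C_H₂O/55.33 mol·dm⁻³, molar
conversion, averaged differences).  `hdospec.shells` turns optimised
hydration-cluster coordinates (XYZ/PDB) into first-shell O⋯O distance
lists and rank-normalised interaction curves.

## Worked example

```python
import hdospec as h
from hdospec import synth

grid = synth.make_grid()                      # 2050–2800 cm⁻¹, 1 cm⁻¹ step
bulk = synth.reference_bands(grid)["bulk"]    # stylised bulk-HDO OD band
affected = synth.make_band(2420.0, 55.0, 0.0, 1.0, grid)

series = synth.make_binary_series(bulk, affected, N=6.0,
                                  molalities=[0.1, 0.2, 0.3, 0.4, 0.5],
                                  noise_sd=0.0, noise_mult=0.005, seed=42)
result = h.estimate_affected_number(series, bulk)
print(f"N = {result.N:.2f}")

params = h.band_parameters(bulk, (2200.0, 2750.0))
dist = h.distance_distribution(bulk, (2.58, 3.20))
print(f"bulk: nu_max {params.nu_max:.1f} cm-1, nu_g {params.nu_gravity:.1f} cm-1")
print(f"      R_OOo {dist.r_max:.3f} A, R_OOg {dist.r_gravity:.3f} A")
```

prints

```
N = 5.86
bulk: nu_max 2508.9 cm-1, nu_g 2496.9 cm-1
      R_OOo 2.822 A, R_OOg 2.847 A
```

The recovered affected number matches the generator's N = 6 to within 3 %,
and the synthetic bulk band reproduces the observables of real bulk HDO at
25 °C (band maximum ≈ 2509 cm⁻¹, gravity center ≈ 2497 cm⁻¹, most likely
O⋯O distance ≈ 2.83 Å).  Note R_OOo ≠ R(ν_max) = 2.849 Å: the Jacobian of
the ν↔R correlation shifts the distribution maximum of a broad band.

## Analysis drivers

The `analysis/` scripts run the synthetic study end to end and write their
tables under `results/`:

1. `01_simulate_systems.py` — generate the study bands, molality series and
   ternary mixtures (with ground truth);
2. `02_atr_screen.py` — difference-spectra screen, null and injected-band
   scenarios;
3. `03_affected_water.py` — affected-number recovery benchmark;
4. `04_ternary_decomposition.py` — shares, N_changed and ΔN per molar ratio
   in the excess-perturbation and shell-overlap regimes;
5. `05_distance_distributions.py` — band parameters, P(R_OO) moments, ΔP
   curves;
6. `06_shell_curves.py` — toy hydration-shell interaction curves and the
   bimodality diagnostic.

Each takes `--seed` and `--out-dir`.  A `hdospec` console script exposes
the same stages for manifest-driven use (`hdospec --help`).

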