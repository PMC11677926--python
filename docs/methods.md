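# Methods

This note documents the models implemented in `hdospec`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Two-state affected-water model

Solution water is treated as two additive spectroscopic populations: bulk
water with the molar absorption spectrum ε_b(ν) of pure water, and
*affected* water with spectrum ε_a(ν).  With N moles of affected water per
mole of solute, molality m (mol·kg⁻¹) and mean water molar mass M
(kg·mol⁻¹), the solution spectrum is

    ε(ν; m) = ε_b + N·M·m·(ε_a − ε_b),

linear in m with intercept ε_b.  `affected_spectrum` inverts this
pointwise; `solution_spectrum` is the exact inverse used by the generator,
so the construction/extraction round trip is exact to float precision.

M accounts for the D₂O added to form HDO: for a D₂O:H₂O mass ratio r,
M = (1 + r)/(1/M_H₂O + r/M_D₂O); r defaults to 0.04 (the 4 % w/w
preparation), giving M = 0.018085 kg·mol⁻¹.

### The affected number N

N is not identified by the linear model alone — rescaling N rescales
ε_a − ε_b.  The criterion implemented is **spectral non-negativity**: a
molar absorption coefficient cannot be negative, and since ε_a − ε_b ∝ 1/N,
every wavenumber with a negative deviation slope imposes the lower bound
N ≥ −d(ν)/ε_b(ν), where d(ν) is the per-wavenumber slope of (ε − ε_b)
against m divided by M.  The smallest admissible N — the supremum of that
ratio — is sharp exactly when the true affected spectrum reaches zero
somewhere in the analysed window, which holds for strongly red-shifted
affected bands whose blue wing dies off inside the OD-stretch region.

Numerical estimation (`estimate_affected_number`):

1. The slope d(ν) comes from a per-wavenumber least-squares fit of
   ε − ε_b against m with the intercept fixed at zero (ε_b is measured
   independently), which roughly halves the slope variance of a
   free-intercept fit on a five-point series.  The white-noise level is
   estimated from the high-frequency part of the fit residuals so that
   smooth systematic misfit (a violation of two-state linearity) is
   detected separately and attached as a `ModelViolationWarning`.
2. On effectively noiseless data the pointwise maximum of −d/ε_b is exact
   and is used directly.
3. On noisy data a pointwise maximum is upward-biased (it picks the
   luckiest noise excursion, catastrophically so where ε_b is small and
   the ratio variance explodes).  The estimator instead (a) locates an
   anchor point by ranking a Savitzky–Golay-smoothed ratio minus three
   times its local standard deviation, over candidates that exclude the
   filter edges and points with far-above-typical ratio variance; (b)
   takes all points whose smoothed ratio is statistically consistent with
   the anchor level (within 3σ, but never more than 15 % below it — the
   rising part of ε_a must stay out however noisy the data); and (c)
   returns the inverse-variance-weighted regression of −d on ε_b over that
   region, which averages the noise down without inheriting the selection
   bias of a maximum.

Benchmarked at the study conditions (five molalities 0.1–0.5 mol·kg⁻¹,
0.5 % multiplicative noise, 50 seeds), recovery is within ±10 % of the true
N ∈ {2, 6, 12} in 100 % of seeds with |bias| ≤ 1.5 %; these numbers are
recomputed by `scripts/acceptance.py` and `analysis/03_affected_water.py`.
Under *additive* noise of 0.3 % of the bulk peak the small-N case (N = 2)
is noise-limited: the usable zero-touching wing carries a deviation signal
of roughly 1 % of the bulk intensity there, and the estimate scatters by
about 12 % (unbiased).  This is a property of the measurement conditions,
not of the algorithm; precise small-N work needs higher molalities or
lower noise.

Grid points where ε_b falls below 1 % of its peak are excluded from the
criterion altogether (`floor_frac`), since the bound ratio is unbounded by
noise there.

## Ternary systems

For two independently acting solutes the mixture's affected spectrum is
the affected-number-weighted mean ε_theor = (N_A ε_A + N_B ε_B)/(N_A+N_B),
and ΔN = N_exp − N_theor classifies the shell interaction: |ΔN| < 0.05 is
reported as independent, negative as overlap (shared waters), positive as
excess perturbation (bridging or newly affected waters).  The 0.05 cutoff
is far below the ~0.5-water reproducibility of experimental N values and
only serves to keep the enum stable on synthetic nulls.

### Spectral decomposition

`decompose_ternary` resolves N_exp·ε_exp into w_A·ε_A + w_B·ε_B plus a
residual, the changed-affected spectrum, with N_changed = N_exp − w_A − w_B
(mass balance holds by construction).  The misfit is the mean squared
residual plus an asymmetric penalty (weight 1000 by default) on residual
values below −`noise_tol`.  The penalty is what identifies the weights:
OD-stretch bands of different solutes overlap heavily, so an unpenalised
least-squares fit would absorb a large part of any changed component into
the pure shares.  Because an affected-water spectrum cannot be negative,
pushing the weights past their true values drives the residual negative
wherever the changed component has no intensity, and a quasi-hard penalty
pins the weights there.  A soft penalty of order 10 leaves share inflation
of 0.1–0.2 waters on realistic band overlaps — larger than the 2 %-level
share accuracy targeted here — hence the large default, kept configurable.
For noisy spectra, `noise_tol` of about 3× the spectral noise standard
deviation (times N_exp) keeps the penalty from biting on noise excursions.

The search runs 32 uniform random restarts over the simplex
{w ≥ 0, w_A + w_B ≤ N_exp} (seeded, `numpy.random.default_rng`), each
refined by Nelder–Mead, followed by a deterministic polish of the best
candidate.  The objective is smooth and two-dimensional; restarts guard
against the flat valleys the penalty can create, and independent seeds
agree to well under 1 % in the objective.  If the best fit still has a
negative residual lobe beyond tolerance, a `ConvergenceError` carries the
best decomposition found.

On ideal synthetic mixtures the decomposition returns the construction
weights and a changed share of zero (integrated intensity < 0.01 % of the
total); with an injected changed component (N_changed = 2, distinct band)
it recovers N_changed to ±0.005 noiselessly and the changed spectrum to
0.4 % RMSE of its peak.

## Band geometry and the ν ↔ R_OO transform

Band maxima are refined by quadratic interpolation through the three
points around the discrete peak; gravity centers are trapezoidal first
moments over a window defaulting to 2200–2700 cm⁻¹ (the OD-stretch
region; the experimental papers in this area do not standardise a window,
so it is configurable).  A maximum on the window edge is returned with a
warning rather than an error — monotone segments are legitimate inputs
when scanning difference spectra.

The empirical correlation ν_OD = 2727 − exp(16.01 − 3.73·R_OO), calibrated
on solid hydrates, is strictly increasing in R; its algebraic inverse is
used directly, with ν ≥ 2727 cm⁻¹ a domain error.  The distance
distribution is P(R) = C·ε(ν(R))·dν/dR with dν/dR = 3.73·exp(16.01−3.73R),
evaluated on a uniform R grid (default 2001 points) by linear interpolation
of the spectrum, and normalised by trapezoidal quadrature to ∫P dR = 1.
Spectral values down to −1 % of the peak are clipped to zero with a warning
(baseline noise); anything more negative raises, since the transform
requires ε ≥ 0.  Because the Jacobian grows toward shorter R, the maximum
of P(R) sits below the image of the band maximum for any finite bandwidth;
the offset shrinks monotonically as the band narrows, which is verified
against a dense brute-force transform.

## ATR difference screen

The chain subtracts water-vapor lines (coefficient minimising the sum of
squared second differences of the result over 1300–2000 cm⁻¹ — closed
form, since the roughness is quadratic in the coefficient — iterated twice
with a Savitzky–Golay background model to remove the small bias the smooth
condensed-phase background induces), subtracts the pure-water spectrum
scaled by C_H₂O/55.33 mol·dm⁻³, optionally subtracts a matched co-solute
reference, divides by the solute molarity, and averages the differences of
each molar spectrum against the most dilute one with equal weights.  All
linear (ideal) contributions cancel in the average; only features whose
molar spectrum depends on concentration survive.  The synthetic coupling
fixture therefore injects a complex band with intensity ∝ c²·c_DMSO — any
bilinear (c¹) coupling is itself concentration-independent per mole and
cancels by design, which mirrors why the screen detects only genuinely
saturable direct interactions.

## Shell geometry

First-shell water oxygens are those within 3.5 Å (configurable) of any
solute atom; O⋯O pairs are counted once (i < j) among shell oxygens only
— solute oxygens (e.g. a sulfoxide oxygen or carboxylate oxygens) are
excluded unless explicitly included by flag — and restricted to
2.55–3.00 Å, the strong-to-weak hydrogen-bond range.  Interaction curves
map the sorted distances to ranks i/n so clusters of different size are
comparable on [0, 1]; the "broken-line" diagnostic for two hydrogen-bond
populations is the maximum of the second difference of the sorted
distances.

## Synthetic data

Every generator inverts exactly one analysis stage and its parameters are
the ground truth of the recovery tests.  Band contours are skew-normal
(`scipy.stats.skewnorm`) so the first moment is analytic; the frozen
`reference_bands` parameters were chosen once so that the numerically
evaluated maxima and gravity centers sit at the literature values for bulk
HDO at 25 °C (2509 / 2497 cm⁻¹) and the solute-affected waters of the
peptide–DMSO systems.  Default noise is additive Gaussian at 0.3 % of the
bulk peak (transmission-FTIR scale); multiplicative noise is available and
is the condition of the N-recovery benchmark (0.5 %).  Molalities default
to 0.1–0.5 mol·kg⁻¹ and ternary molar ratios to 1–5, the composition
ladder of the emulated study; in `make_ternary_series` the co-solute share
scales with the molar ratio while the peptide share is fixed, emulating a
constant-peptide series with increasing co-solute.

What the generators do *not* emulate: baseline drift and atmospheric
residuals beyond discrete vapor lines, detector nonlinearity, isotope-
exchange equilibria, temperature dependence of band shapes, and any
correlation structure in the noise.  Passing recovery tests therefore
demonstrates the correctness and noise behaviour of the algorithms under
the stated statistical model, not instrument-grade robustness on real
spectra.

Toy hydration shells place water pairs at exact target O⋯O separations
near a carbon-chain "solute" (pairs mutually separated beyond the
hydrogen-bond range), so the in-range distance multiset equals the target
list verbatim; they are geometric fixtures, not physical water clusters.

## Degenerate inputs and error policy

Duplicate wavenumbers, mixed intensity units, mismatched grids,
extrapolating resamples, non-positive concentrations, water molarity above
55.33 mol·dm⁻³, flat or zero-intensity analysis windows, ν ≥ 2727 cm⁻¹,
empty vapor-reference or distance lists — all raise typed exceptions from
`hdospec.errors` before any computation runs.  A series with no detectable
solute effect (ε = ε_b within noise) raises `EstimationError`, as does a
series whose deviation slope is nowhere negative (the non-negativity
criterion then cannot bound N).

## Known limitations

* The non-negativity criterion for N assumes the true affected spectrum
  reaches (effectively) zero inside the analysed window; for affected
  spectra similar in shape to bulk the criterion returns an upper-shape
  bound below the nominal N.  This mirrors the practical limits of the
  experimental method.
* The ternary decomposition resolves exactly two pure components plus one
  residual; three-solute mixtures and component spectra that are nearly
  collinear are out of scope.
* The ν ↔ R_OO correlation is an empirical solid-hydrate calibration; its
  accuracy for liquid-phase distributions is inherited, not assessed here.
* The XYZ reader accepts the plain `element x y z` dialect only; PDB input
  is delegated to Biopython.
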