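"""Solute-affected HDO spectra and the affected number N.

The two-state model splits solution water into bulk water (spectrum ε_b,
indistinguishable from pure water) and affected water (spectrum ε_a,
perturbed by the solute).  At solute molality m the solution spectrum obeys

    ε(ν; m) = ε_b(ν) + N·M·m·(ε_a(ν) − ε_b(ν)),

where N is the affected number (moles of water perturbed per mole of solute)
and M the mean molar mass of the water (kg·mol⁻¹, including the D₂O share of
the HDO preparation).  Inverting pointwise gives the affected spectrum

    ε_a = (ε − ε_b) / (N·M·m) + ε_b.

N itself is not identified by the linear model alone: rescaling N rescales
ε_a − ε_b.  The criterion used here is spectral non-negativity — a molar
absorption coefficient cannot be negative, and the two-state scaling makes
ε_a − ε_b inversely proportional to N, so the smallest N keeping ε_a ≥ 0
everywhere (within noise tolerance) is sharp whenever the true affected
spectrum actually reaches zero somewhere in the analysed window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import DomainError, EstimationError
from .spectra import Spectrum, SeriesPoint, _check_shared_grid

__all__ = [
    "MOLAR_MASS_H2O",
    "MOLAR_MASS_D2O",
    "mean_molar_mass",
    "affected_spectrum",
    "solution_spectrum",
    "AffectedSettings",
    "AffectedWaterResult",
    "ModelViolationWarning",
    "estimate_affected_number",
]

MOLAR_MASS_H2O = 0.018015  # kg·mol⁻¹
MOLAR_MASS_D2O = 0.020027  # kg·mol⁻¹


class ModelViolationWarning(UserWarning):
    """The series departs from two-state linearity beyond tolerance."""


def mean_molar_mass(d2o_to_h2o_mass_ratio: float) -> float:
    """Mole-fraction mean molar mass of an H₂O/D₂O mixture, kg·mol⁻¹.

    ``d2o_to_h2o_mass_ratio`` is the mass of D₂O added per unit mass of H₂O
    (0.04 for the usual 4 % w/w HDO preparation).  The mean molar mass is
    total mass over total moles:

        M = (1 + r) / (1/M_H2O + r/M_D2O).
    """
    r = d2o_to_h2o_mass_ratio
    if r < 0:
        raise DomainError("D2O/H2O mass ratio must be non-negative")
    if r > 0.1:
        raise DomainError("D2O/H2O mass ratio above 0.1 is outside the HDO regime")
    return (1.0 + r) / (1.0 / MOLAR_MASS_H2O + r / MOLAR_MASS_D2O)


def affected_spectrum(
    solution: Spectrum, bulk: Spectrum, N: float, M: float, m: float
) -> Spectrum:
    """ε_a = (ε − ε_b)/(N·M·m) + ε_b, pointwise on a shared grid."""
    _check_shared_grid([solution, bulk])
    if N * M * m == 0:
        raise DomainError("N·M·m must be non-zero")
    if min(N, M, m) <= 0:
        raise DomainError("N, M and m must all be positive")
    values = (solution.values - bulk.values) / (N * M * m) + bulk.values
    return Spectrum(solution.grid.copy(), values, solution.unit,
                    {"N": N, "M": M, "m": m})


def solution_spectrum(
    affected: Spectrum, bulk: Spectrum, N: float, M: float, m: float
) -> Spectrum:
    """Inverse of :func:`affected_spectrum`: ε = ε_b + N·M·m·(ε_a − ε_b)."""
    _check_shared_grid([affected, bulk])
    if min(N, M) < 0 or m < 0:
        raise DomainError("N, M and m must be non-negative")
    values = bulk.values + N * M * m * (affected.values - bulk.values)
    return Spectrum(affected.grid.copy(), values, affected.unit,
                    {"N": N, "M": M, "m": m})


@dataclass
class AffectedSettings:
    """Tuning knobs for :func:`estimate_affected_number`.

    window:
        Wavenumber window analysed (defaults to the OD-stretch region).
    d2o_to_h2o_mass_ratio:
        Isotopic composition used for the mean molar mass M.
    floor_frac:
        Grid points where the bulk spectrum falls below this fraction of its
        peak are excluded from the non-negativity criterion (the ratio
        −slope/ε_b is unbounded by noise where ε_b ≈ 0).
    zero_frac:
        Relative shortfall from the smoothed ratio maximum still counted as
        part of the zero-touching region.
    noise_sigma_mult:
        Additional noise allowance of the region threshold, in units of the
        smoothed-ratio standard deviation (default 3).
    select_sigma_mult:
        Confidence penalty used when locating the ratio maximum: candidates
        are ranked by ratio − select_sigma_mult·σ_ratio so that
        high-variance points (tiny ε_b under additive noise) cannot win.
    fixed_N:
        Bypass the criterion and extract ε_a at this user-supplied N.
    """

    window: tuple[float, float] = (2200.0, 2750.0)
    d2o_to_h2o_mass_ratio: float = 0.04
    floor_frac: float = 0.01
    zero_frac: float = 0.02
    noise_sigma_mult: float = 3.0
    select_sigma_mult: float = 3.0
    fixed_N: float | None = None


@dataclass
class AffectedWaterResult:
    """Affected spectrum, affected number, and fit diagnostics."""

    epsilon_a: Spectrum
    N: float
    M: float
    m: float  # mean molality of the series
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("affected number must be positive")
        if not 0.018 <= self.M <= 0.0202:
            raise ValueError("mean molar mass outside the H2O–D2O range")


def _slope_through_origin(
    deviations: np.ndarray, molalities: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavenumber LS slope of (ε − ε_b) vs m with intercept fixed at 0.

    The bulk spectrum is measured independently, so the intercept of the
    two-state line is known; fixing it roughly halves the slope variance of
    a free-intercept fit on a short molality series.

    Returns (slope, residual sd per wavenumber).
    """
    mm = float(molalities @ molalities)
    slope = (deviations.T @ molalities) / mm
    resid = deviations - np.outer(molalities, slope)
    dof = max(len(molalities) - 1, 1)
    sd = np.sqrt((resid**2).sum(axis=0) / dof)
    return slope, sd


def _nonnegativity_N(
    d: np.ndarray,
    eb: np.ndarray,
    sigma_d: np.ndarray,
    noise_scale: float,
    dev_rms: float,
    cfg: "AffectedSettings",
) -> float:
    """Smallest N keeping ε_a = ε_b + d/N non-negative (within noise).

    Non-negativity at wavenumber ν requires N ≥ −d(ν)/ε_b(ν) wherever the
    deviation d is negative, so the sharp bound is the supremum of that
    ratio.  On noiseless data the pointwise maximum is exact.  On noisy
    data a pointwise maximum is upward-biased (it picks the luckiest noise
    excursion), so the zero-touching region — where the ratio sits within
    tolerance of its smoothed maximum — is located on a Savitzky–Golay
    smoothed ratio, and N is the inverse-variance weighted regression of
    −d on ε_b over that region, which averages the noise without inheriting
    the selection bias.
    """
    floor = cfg.floor_frac * float(eb.max())
    mask = eb >= floor
    neg = mask & (d < 0)
    if not np.any(neg):
        raise EstimationError(
            "slope spectrum is nowhere negative where the bulk band has "
            "intensity; the non-negativity criterion cannot bound N"
        )
    safe_eb = np.where(eb > 0, eb, np.inf)

    if noise_scale <= 1e-9 * dev_rms:  # effectively exact data
        ratio = np.where(neg, -d / safe_eb, -np.inf)
        N = float(ratio.max())
        if N <= 0:
            raise EstimationError("non-negativity criterion yielded N ≤ 0")
        return N

    n = d.size
    win = min(31, n if n % 2 else n - 1)
    if win < 5:
        win = 5
    d_s = savgol_filter(d, win, 2)
    sigma_s = np.maximum(savgol_filter(sigma_d, win, 2), 1e-300)
    # quadratic SG noise-variance gain for the smoothed ratio
    g = np.sqrt(3.0 * (3 * win**2 - 7) / (4.0 * win * (win**2 - 4)))
    ratio_s = np.where(mask, -d_s / safe_eb, -np.inf)
    sigma_ratio = g * sigma_s / safe_eb
    # anchor: the statistically best zero-touching candidate.  Candidates
    # exclude the filter edges (where the smoothing variance exceeds the
    # interior gain g) and points whose ratio uncertainty is far above
    # typical (tiny ε_b under additive noise); ranking by a
    # lower-confidence score keeps lucky noise excursions from winning.
    sane = mask.copy()
    half = win // 2
    sane[:half] = False
    sane[n - half:] = False
    med_sig = float(np.median(sigma_ratio[mask & np.isfinite(sigma_ratio)]))
    sane &= sigma_ratio <= 3.0 * med_sig
    if not np.any(sane):
        sane = mask
    score = np.where(sane, ratio_s - cfg.select_sigma_mult * sigma_ratio,
                     -np.inf)
    i_star = int(np.argmax(score))
    N_ref = float(ratio_s[i_star])
    if not np.isfinite(N_ref) or N_ref <= 0:
        raise EstimationError("non-negativity criterion yielded N ≤ 0")

    # zero-touching region: points whose smoothed ratio is statistically
    # consistent with the reference level; the relative floor keeps the
    # rising part of ε_a out however large the local noise is
    thr = (1.0 - cfg.zero_frac) * N_ref \
        - cfg.noise_sigma_mult * (sigma_ratio + sigma_ratio[i_star])
    thr = np.maximum(thr, 0.85 * N_ref)
    region = neg & (ratio_s >= thr)
    if region.sum() < 3:
        return N_ref
    # inverse-variance weighted regression of −d on ε_b over the region
    w = 1.0 / np.maximum(sigma_d[region] ** 2, 1e-300)
    num = float(np.sum(w * (-d[region]) * eb[region]))
    den = float(np.sum(w * eb[region] ** 2))
    if den <= 0 or num <= 0:
        return N_ref
    return num / den


def estimate_affected_number(
    series: Sequence[SeriesPoint],
    bulk: Spectrum,
    settings: AffectedSettings | None = None,
) -> AffectedWaterResult:
    """Estimate N and the affected spectrum from a molality series.

    Procedure
    ---------
    1. Per-wavenumber linear fit of ε − ε_b against m (intercept fixed at
       zero since ε_b is measured); the slope spectrum equals
       N·M·(ε_a − ε_b) under the two-state model.  Linearity residuals are
       the model check: systematic residuals beyond 3× the noise level
       attach a :class:`ModelViolationWarning`.
    2. N from the non-negativity criterion: the smallest N for which
       ε_a = ε_b + slope/(N·M) stays above −tolerance everywhere.  The raw
       pointwise bound max(−slope/(M·ε_b)) is exact on noiseless data; with
       noise it is refined by inverse-variance averaging of the same ratio
       over the region where the affected spectrum is indistinguishable
       from zero, which suppresses the upward bias of a pointwise maximum.
    3. ε_a computed at each molality with the chosen N, then averaged.
    """
    cfg = settings or AffectedSettings()
    if len(series) == 0:
        raise EstimationError("empty series")
    spectra = [p.spectrum for p in series]
    _check_shared_grid(list(spectra) + [bulk])
    molalities = np.array([p.molality for p in series], dtype=float)
    if np.any(molalities <= 0):
        raise DomainError("all molalities must be positive")
    M = mean_molar_mass(cfg.d2o_to_h2o_mass_ratio)

    if cfg.fixed_N is None and len(series) < 3:
        raise EstimationError(
            "N estimation needs at least three molalities; "
            "supply settings.fixed_N to extract ε_a at a known N"
        )
    if cfg.fixed_N is None and molalities.max() < 2.0 * molalities.min():
        raise EstimationError("molalities must span at least a two-fold range")

    lo, hi = cfg.window
    win = (bulk.grid >= lo) & (bulk.grid <= hi)
    if win.sum() < 10:
        raise EstimationError("analysis window holds too few grid points")
    grid = bulk.grid[win]
    eb = bulk.values[win]
    dev = np.stack([s.values[win] - eb for s in spectra])  # (n_m, n_nu)

    slope, resid_sd = _slope_through_origin(dev, molalities)
    mm = float(molalities @ molalities)
    sigma_slope = resid_sd / np.sqrt(mm)
    resid = dev - np.outer(molalities, slope)
    # white-noise level from the high-frequency part of the fit residuals:
    # smooth (systematic) misfit barely contributes to adjacent differences
    noise_scale = float(np.std(np.diff(resid, axis=1)) / np.sqrt(2.0))

    # two-state linearity check (only meaningful with ≥3 molalities)
    if len(series) >= 3:
        fit_rms = float(np.sqrt(np.mean(resid**2)))
        dev_rms = float(np.sqrt(np.mean(dev**2)))
        # relative floor keeps float-level residuals of exact data quiet
        if dev_rms > 0 and fit_rms > max(3.0 * noise_scale, 1e-9 * dev_rms):
            warnings.warn(
                "series departs from two-state linearity beyond 3× noise",
                ModelViolationWarning,
            )

    d = slope / M  # = N · (ε_a − ε_b)
    signal = float(np.max(np.abs(slope)))
    if signal == 0 or (noise_scale > 0 and signal < 3.0 * np.median(sigma_slope)):
        raise EstimationError(
            "no detectable solute effect: the series equals bulk within noise"
        )

    if cfg.fixed_N is not None:
        N = float(cfg.fixed_N)
        if N <= 0:
            raise DomainError("fixed_N must be positive")
    else:
        N = _nonnegativity_N(d, eb, sigma_slope / M, noise_scale,
                             float(np.sqrt(np.mean(dev**2))), cfg)

    eps_a_each = np.stack([
        dev[i] / (N * M * molalities[i]) + eb for i in range(len(series))
    ])
    eps_a_mean = eps_a_each.mean(axis=0)
    per_molality_rms = np.sqrt(np.mean((eps_a_each - eps_a_mean) ** 2, axis=1))
    epsilon_a = Spectrum(grid.copy(), eps_a_mean, spectra[0].unit,
                         {"N": N, "M": M})
    return AffectedWaterResult(
        epsilon_a=epsilon_a,
        N=N,
        M=M,
        m=float(molalities.mean()),
        diagnostics={
            "per_molality_rms": per_molality_rms,
            "molalities": molalities,
            "noise_sd": noise_scale,
            "slope_spectrum": Spectrum(grid.copy(), slope, spectra[0].unit),
        },
    )
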