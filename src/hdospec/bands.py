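"""Band parameters and the wavenumber → O⋯O distance transform.

The decoupled OD stretch of HDO reports the hydrogen-bond geometry of the
donating water molecule.  An empirical correlation calibrated on solid
hydrates links the OD wavenumber to the intermolecular oxygen–oxygen
distance R_OO (Å):

    ν_OD/cm⁻¹ = 2727 − exp(16.01 − 3.73·R_OO).

A band contour ε(ν) therefore maps onto a distance distribution

    P(R_OO) = C · ε(ν(R_OO)) · dν/dR_OO,
    dν/dR_OO = 3.73 · exp(16.01 − 3.73·R_OO),

with C fixing ∫P dR = 1.  Because the Jacobian dν/dR varies across the
band, the maximum of P(R) is not the image of the band maximum — the offset
vanishes only in the narrow-band limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SpectralRangeError
from .spectra import Spectrum, resample

__all__ = [
    "NU_LIMIT",
    "CORR_A",
    "CORR_B",
    "distance_to_wavenumber",
    "wavenumber_to_distance",
    "BandParameters",
    "BoundaryMaximumWarning",
    "band_maximum",
    "gravity_center",
    "band_parameters",
    "DistanceDistribution",
    "distance_distribution",
    "distribution_difference",
]

#: Free-OD asymptote of the correlation, cm⁻¹.
NU_LIMIT = 2727.0
#: Exponential parameters of the ν(R_OO) correlation.
CORR_A = 16.01
CORR_B = 3.73

#: Default OD-stretch analysis window, cm⁻¹.
OD_WINDOW = (2200.0, 2700.0)


def distance_to_wavenumber(r):
    """ν(R) = 2727 − exp(16.01 − 3.73·R); strictly increasing in R."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("O⋯O distance must be positive")
    out = NU_LIMIT - np.exp(CORR_A - CORR_B * r)
    return float(out) if out.ndim == 0 else out


def wavenumber_to_distance(nu):
    """Inverse correlation R(ν) = (16.01 − ln(2727 − ν))/3.73 for ν < 2727."""
    nu = np.asarray(nu, dtype=float)
    if np.any(nu >= NU_LIMIT):
        raise DomainError(
            f"correlation undefined for ν ≥ {NU_LIMIT:g} cm⁻¹"
        )
    out = (CORR_A - np.log(NU_LIMIT - nu)) / CORR_B
    return float(out) if out.ndim == 0 else out


def _jacobian(r: np.ndarray) -> np.ndarray:
    """dν/dR = 3.73·exp(16.01 − 3.73·R)."""
    return CORR_B * np.exp(CORR_A - CORR_B * np.asarray(r, dtype=float))


class BoundaryMaximumWarning(UserWarning):
    """The discrete maximum sits on the window edge (monotone segment)."""


@dataclass
class BandParameters:
    """Position at maximum, gravity center, and (optionally) FWHM, cm⁻¹."""

    nu_max: float
    nu_gravity: float
    fwhm: float | None = None

    def __post_init__(self) -> None:
        if self.fwhm is not None and self.fwhm <= 0:
            raise ValueError("fwhm must be positive when present")


def _quadratic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex abscissa of the parabola through points i−1, i, i+1."""
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # not a maximum; fall back to the grid point
        return float(x1)
    return float(-b / (2 * a))


def band_maximum(s: Spectrum, window: tuple[float, float] = OD_WINDOW) -> float:
    """Band position at maximum, refined by local quadratic interpolation.

    A maximum on the window edge (monotone segment) is returned as the edge
    value with a :class:`BoundaryMaximumWarning`; a flat window raises.
    """
    w = s.window(*window)
    if np.ptp(w.values) == 0:
        raise DomainError("flat spectrum in window: maximum is ill-defined")
    i = int(np.argmax(w.values))
    if i == 0 or i == len(w) - 1:
        warnings.warn(
            "band maximum lies on the window boundary", BoundaryMaximumWarning
        )
        return float(w.grid[i])
    return _quadratic_refine(w.grid, w.values, i)


def gravity_center(s: Spectrum, window: tuple[float, float] = OD_WINDOW) -> float:
    """Intensity-weighted mean wavenumber ∫ν·ε dν / ∫ε dν (trapezoidal)."""
    w = s.window(*window)
    denom = float(np.trapezoid(w.values, w.grid))
    if denom == 0:
        raise DomainError("zero integrated intensity in window")
    return float(np.trapezoid(w.grid * w.values, w.grid)) / denom


def _fwhm(grid: np.ndarray, values: np.ndarray) -> float | None:
    peak = values.max()
    half = peak / 2.0
    above = values >= half
    if not above.any() or above.all():
        return None
    idx = np.flatnonzero(above)
    lo_i, hi_i = idx[0], idx[-1]
    if lo_i == 0 or hi_i == len(values) - 1:
        return None  # half level not crossed inside the window

    def cross(i0, i1):
        x0, x1 = grid[i0], grid[i1]
        y0, y1 = values[i0], values[i1]
        return x0 + (half - y0) * (x1 - x0) / (y1 - y0)

    return float(cross(hi_i, hi_i + 1) - cross(lo_i - 1, lo_i))


def band_parameters(
    s: Spectrum, window: tuple[float, float] = OD_WINDOW
) -> BandParameters:
    """Convenience bundle: maximum, gravity center and FWHM in one window."""
    w = s.window(*window)
    return BandParameters(
        nu_max=band_maximum(s, window),
        nu_gravity=gravity_center(s, window),
        fwhm=_fwhm(w.grid, w.values),
    )


@dataclass
class DistanceDistribution:
    """Normalised O⋯O distance distribution P(R_OO) and its moments."""

    r_grid: np.ndarray
    p_values: np.ndarray
    r_max: float
    r_gravity: float
    norm_constant: float

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("distance grid must be strictly ascending")


def distance_distribution(
    s: Spectrum,
    r_range: tuple[float, float] = (2.55, 3.20),
    n_points: int = 2001,
    clip_tol_frac: float = 0.01,
) -> DistanceDistribution:
    """Transform a non-negative band contour into P(R_OO).

    The spectrum is evaluated at ν(R) on a uniform R grid, multiplied by the
    Jacobian dν/dR, and normalised to unit area.  Small negative spectral
    values (down to −``clip_tol_frac`` of the peak, e.g. baseline noise) are
    clipped to zero with a warning; larger ones violate the ε ≥ 0
    requirement of the transform and raise.
    """
    r_lo, r_hi = r_range
    if not 0 < r_lo < r_hi:
        raise DomainError("invalid distance range")
    r = np.linspace(r_lo, r_hi, n_points)
    nu = distance_to_wavenumber(r)
    lo, hi = s.span
    if nu.min() < lo or nu.max() > hi:
        raise SpectralRangeError(
            f"distance range [{r_lo:g}, {r_hi:g}] Å maps to "
            f"[{nu.min():.1f}, {nu.max():.1f}] cm⁻¹, outside the spectrum "
            f"span [{lo:g}, {hi:g}]"
        )
    eps = np.interp(nu, s.grid, s.values)
    peak = float(np.max(np.abs(eps))) or 1.0
    if eps.min() < -clip_tol_frac * peak:
        raise DomainError(
            "spectrum has negative values beyond baseline tolerance; "
            "remove the baseline before the distance transform"
        )
    if eps.min() < 0:
        warnings.warn(
            "clipping small negative spectral values to zero for P(R_OO)",
            UserWarning,
        )
        eps = np.clip(eps, 0.0, None)
    raw = eps * _jacobian(r)
    area = float(np.trapezoid(raw, r))
    if area <= 0:
        raise DomainError("band has no intensity in the mapped window")
    p = raw / area
    i = int(np.argmax(p))
    if 0 < i < n_points - 1:
        r_max = _quadratic_refine(r, p, i)
    else:
        r_max = float(r[i])
    r_gravity = float(np.trapezoid(r * p, r))
    return DistanceDistribution(
        r_grid=r, p_values=p, r_max=r_max, r_gravity=r_gravity,
        norm_constant=1.0 / area,
    )


def distribution_difference(
    p1: DistanceDistribution, p2: DistanceDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """ΔP(R) = p1 − p2 on the overlap of their distance grids.

    Both inputs are normalised densities, so when the grids coincide the
    difference integrates to zero.  Disjoint ranges raise.
    """
    lo = max(p1.r_grid[0], p2.r_grid[0])
    hi = min(p1.r_grid[-1], p2.r_grid[-1])
    if lo >= hi:
        raise SpectralRangeError("distance distributions do not overlap")
    n = max(len(p1.r_grid), len(p2.r_grid))
    r = np.linspace(lo, hi, n)
    d1 = np.interp(r, p1.r_grid, p1.p_values)
    d2 = np.interp(r, p2.r_grid, p2.p_values)
    return r, d1 - d2
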