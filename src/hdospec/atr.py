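"""ATR difference-spectra chain screening for direct solute–solute contacts.

The protocol: remove residual water-vapor lines, subtract the pure-water
background scaled by the actual water molarity of the sample relative to pure
water (55.33 mol·dm⁻³ at 25 °C), divide by the solute molarity to obtain a
molar spectrum, and average the differences of each molar spectrum against
the most dilute one.  Concentration-independent solute bands cancel in the
average; a surviving differential feature (e.g. a shifted S=O component that
appears only in a ternary mixture) marks a direct solute–solute interaction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, DomainError
from .spectra import Spectrum, Unit, _check_shared_grid, linear_combination

__all__ = [
    "PURE_WATER_MOLARITY",
    "vapor_coefficient",
    "subtract_vapor",
    "subtract_water_background",
    "to_molar_spectrum",
    "mean_difference_spectrum",
    "difference_screen",
]

#: Molar concentration of pure water at 25 °C, mol·dm⁻³.
PURE_WATER_MOLARITY = 55.33

#: Wavenumber window dominated by rotational–vibrational vapor lines.
DEFAULT_VAPOR_WINDOW = (1300.0, 2000.0)


def _second_differences(values: np.ndarray) -> np.ndarray:
    return np.diff(values, n=2)


def vapor_coefficient(
    s: Spectrum,
    vapor: Spectrum,
    window: tuple[float, float] = DEFAULT_VAPOR_WINDOW,
    k_bounds: tuple[float, float] = (-2.0, 2.0),
    n_refine: int = 2,
) -> tuple[float, float]:
    """Coefficient k minimising the roughness of ``s − k·vapor``.

    Roughness is the sum of squared second differences inside ``window``,
    which is quadratic in k, so each pass has the closed-form minimiser
    k* = ⟨D²s, D²v⟩ / ‖D²v‖².  The smooth condensed-phase background leaks
    slightly into that correlation, so after the first pass the smooth part
    of the residual (Savitzky–Golay, window wider than a vapor line) is
    removed and k re-estimated on the sharp remainder; two passes suffice
    to push the background bias far below the line amplitude.  The result
    is clipped to ``k_bounds``.

    Returns
    -------
    (k, roughness) where roughness is evaluated at the returned k.
    """
    _check_shared_grid([s, vapor])
    mask = (s.grid >= window[0]) & (s.grid <= window[1])
    if mask.sum() < 8:
        raise ConfigError("vapor window holds too few points for roughness")
    sv = s.values[mask]
    vv = vapor.values[mask]
    dv = _second_differences(vv)
    denom = float(dv @ dv)
    if denom == 0.0:
        ds = _second_differences(sv)
        return 0.0, float(ds @ ds)

    win = min(51, mask.sum() - 1 if mask.sum() % 2 == 0 else mask.sum())
    if win % 2 == 0:
        win -= 1
    background = np.zeros_like(sv)
    k = 0.0
    for _ in range(1 + max(n_refine, 0)):
        ds = _second_differences(sv - background)
        k = float(np.clip(float(ds @ dv) / denom, *k_bounds))
        if win >= 5:
            background = savgol_filter(sv - k * vv, win, 3)
    resid = _second_differences(sv) - k * dv
    return k, float(resid @ resid)


def subtract_vapor(
    s: Spectrum,
    vapor_refs: Sequence[Spectrum],
    window: tuple[float, float] = DEFAULT_VAPOR_WINDOW,
    k_bounds: tuple[float, float] = (-2.0, 2.0),
) -> Spectrum:
    """Remove the best-matching vapor reference from ``s``.

    Each reference is tried; the one whose optimal coefficient leaves the
    smoothest result wins.  The chosen coefficient is recorded in
    ``meta['vapor_k']``.
    """
    if not vapor_refs:
        raise ConfigError("subtract_vapor needs at least one vapor reference")
    best = None
    for i, v in enumerate(vapor_refs):
        k, rough = vapor_coefficient(s, v, window=window, k_bounds=k_bounds)
        if best is None or rough < best[2]:
            best = (i, k, rough)
    i, k, rough = best
    out = linear_combination([s, vapor_refs[i]], [1.0, -k])
    out.meta.update(s.meta)
    out.meta.update(vapor_k=k, vapor_ref_index=i, vapor_roughness=rough)
    return out


def subtract_water_background(
    sample: Spectrum,
    pure_water: Spectrum,
    c_water: float,
    c_water_pure: float = PURE_WATER_MOLARITY,
) -> Spectrum:
    """sample − (c_water / 55.33)·pure_water.

    ``c_water`` is the actual molar concentration of water in the sample; it
    cannot exceed that of pure water.
    """
    if not 0.0 < c_water <= c_water_pure:
        raise DomainError(
            f"water concentration {c_water:g} outside (0, {c_water_pure:g}] mol·dm⁻³"
        )
    coeff = c_water / c_water_pure
    out = linear_combination([sample, pure_water], [1.0, -coeff])
    out.meta.update(sample.meta)
    out.meta["water_subtraction_coeff"] = coeff
    return out


def to_molar_spectrum(s: Spectrum, c_solute: float) -> Spectrum:
    """Divide by the solute molarity; the unit becomes molar absorption."""
    if c_solute <= 0:
        raise DomainError(f"solute concentration must be positive, got {c_solute:g}")
    out = s.copy(values=s.values / c_solute, unit=Unit.MOLAR_ABSORPTION)
    out.meta["c_solute"] = c_solute
    return out


def difference_screen(
    samples: Sequence[Spectrum],
    c_solute: Sequence[float],
    c_water: Sequence[float],
    pure_water: Spectrum,
    vapor_refs: Sequence[Spectrum] = (),
    matched_references: Sequence[Spectrum] | None = None,
) -> Spectrum:
    """Full difference chain: vapor → water → (co-solute) → molar → average.

    ``matched_references`` holds, per sample, the isolated co-solute
    spectrum at its matching concentration (the ternary-series protocol);
    pass ``None`` for a binary series.  Samples must be ordered by
    ascending solute concentration.
    """
    if len(samples) != len(c_solute) or len(samples) != len(c_water):
        raise ValueError("samples, c_solute and c_water lengths must match")
    molar = []
    for i, (s, c, cw) in enumerate(zip(samples, c_solute, c_water)):
        if vapor_refs:
            s = subtract_vapor(s, vapor_refs)
        s = subtract_water_background(s, pure_water, cw)
        if matched_references is not None:
            ref = matched_references[i]
            s = linear_combination([s, ref], [1.0, -1.0])
        molar.append(to_molar_spectrum(s, c))
    return mean_difference_spectrum(molar)


def mean_difference_spectrum(molar_series: Sequence[Spectrum]) -> Spectrum:
    """Mean over i ≥ 2 of (sᵢ − s₁) for a concentration-ordered molar series.

    The most dilute spectrum is subtracted with coefficient 1 from every
    other member; the resulting difference spectra are averaged with equal
    weights.
    """
    if len(molar_series) < 2:
        raise ValueError("a difference series needs at least two spectra")
    _check_shared_grid(molar_series)
    lowest = molar_series[0]
    diffs = [s.values - lowest.values for s in molar_series[1:]]
    mean = np.mean(diffs, axis=0)
    return Spectrum(lowest.grid.copy(), mean, lowest.unit,
                    {"n_differences": len(diffs)})
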