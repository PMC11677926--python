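"""Spectrum container, plain-text I/O, resampling, and linear arithmetic.

A :class:`Spectrum` is a band sampled on a strictly monotone wavenumber grid
(cm⁻¹).  The canonical in-memory order is ascending wavenumber; readers and
the constructor normalise descending input.  Intensities are either raw
absorbance or molar absorption coefficients (dm³·mol⁻¹·cm⁻¹); the unit is
carried as a tag and checked at operation boundaries rather than silently
converted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DuplicateAbscissaError,
    GridMismatchError,
    SpectralRangeError,
    SpectrumParseError,
    UnitMismatchError,
)

__all__ = [
    "Unit",
    "Spectrum",
    "SeriesPoint",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "linear_combination",
]


class Unit(str, enum.Enum):
    ABSORBANCE = "absorbance"
    MOLAR_ABSORPTION = "molar_absorption"


@dataclass
class Spectrum:
    """A sampled band ε(ν) on an ascending wavenumber grid.

    Parameters
    ----------
    grid:
        Wavenumbers in cm⁻¹, strictly monotone, finite and positive,
        length ≥ 2.  Descending input is reversed together with ``values``.
    values:
        Intensity at each grid point.
    unit:
        Either :attr:`Unit.ABSORBANCE` or :attr:`Unit.MOLAR_ABSORPTION`.
    meta:
        Free-form provenance tags (file of origin, subtraction coefficients…).
    """

    grid: np.ndarray
    values: np.ndarray
    unit: Unit = Unit.ABSORBANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or values.ndim != 1:
            raise ValueError("grid and values must be one-dimensional")
        if grid.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if grid.size != values.size:
            raise ValueError(
                f"grid and values lengths differ ({grid.size} vs {values.size})"
            )
        if not np.all(np.isfinite(grid)) or np.any(grid <= 0):
            raise ValueError("grid values must be finite and positive")
        diffs = np.diff(grid)
        if np.all(diffs < 0):  # normalise descending input
            grid = grid[::-1]
            values = values[::-1]
            diffs = -diffs
        if not np.all(diffs > 0):
            raise DuplicateAbscissaError(
                "wavenumber grid is not strictly monotone"
            )
        self.grid = grid
        self.values = values
        self.unit = Unit(self.unit)

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return self.grid.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def copy(self, **updates) -> "Spectrum":
        kwargs = dict(
            grid=self.grid.copy(),
            values=self.values.copy(),
            unit=self.unit,
            meta=dict(self.meta),
        )
        kwargs.update(updates)
        return Spectrum(**kwargs)

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to grid points with lo ≤ ν ≤ hi."""
        mask = (self.grid >= lo) & (self.grid <= hi)
        if mask.sum() < 2:
            raise SpectralRangeError(
                f"window [{lo}, {hi}] cm⁻¹ holds fewer than two grid points"
            )
        return Spectrum(self.grid[mask], self.values[mask], self.unit, dict(self.meta))


@dataclass
class SeriesPoint:
    """One member of a concentration series: a spectrum plus its composition."""

    spectrum: Spectrum
    molality: float  # mol·kg⁻¹
    molarity: float | None = None  # mol·dm⁻³
    density: float | None = None  # g·cm⁻³

    def __post_init__(self) -> None:
        if self.molality < 0:
            raise ValueError("molality must be non-negative")
        if self.molarity is not None and self.molarity < 0:
            raise ValueError("molarity must be non-negative")


# -- I/O -------------------------------------------------------------------

_DELIMS = {"csv": ",", "tsv": "\t", "jcamp_like": None}


def _sniff_delimiter(lines: Sequence[str]) -> str | None:
    for line in lines:
        if "," in line:
            return ","
        if "\t" in line:
            return "\t"
    return None  # whitespace


def read_spectrum(
    path: str | Path,
    dialect: str | None = None,
    unit: Unit = Unit.ABSORBANCE,
) -> Spectrum:
    """Read a two-column (wavenumber, intensity) plain-text spectrum.

    Comment lines start with ``#`` (JCAMP-style ``##`` headers are also
    skipped).  The delimiter is sniffed unless ``dialect`` is one of
    ``csv``, ``tsv`` or ``jcamp_like`` (whitespace).  Rows may come in
    descending wavenumber order; the result is always ascending.  Repeated
    wavenumbers are rejected.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    data_lines: list[tuple[int, str]] = []
    for i, line in enumerate(raw, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        data_lines.append((i, stripped))
    if not data_lines:
        raise SpectrumParseError(f"{path}: no data rows found")
    if dialect is None:
        delim = _sniff_delimiter([l for _, l in data_lines[:20]])
    elif dialect in _DELIMS:
        delim = _DELIMS[dialect]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    nus, eps = [], []
    for lineno, line in data_lines:
        parts = line.split(delim) if delim else line.split()
        parts = [p for p in parts if p != ""]
        if len(parts) < 2:
            raise SpectrumParseError(
                f"{path}:{lineno}: expected two columns, got {line!r}"
            )
        try:
            nus.append(float(parts[0]))
            eps.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(
                f"{path}:{lineno}: non-numeric value in {line!r}"
            ) from exc

    grid = np.asarray(nus)
    order = np.argsort(grid)
    if np.any(np.diff(grid[order]) == 0):
        dup = grid[order][:-1][np.diff(grid[order]) == 0][0]
        raise DuplicateAbscissaError(
            f"{path}: duplicate wavenumber {dup:g} cm⁻¹"
        )
    return Spectrum(
        grid[order],
        np.asarray(eps)[order],
        unit=unit,
        meta={"source": str(path)},
    )


def write_spectrum(s: Spectrum, path: str | Path, dialect: str = "csv") -> None:
    """Write the two-column dialect produced by :func:`read_spectrum`."""
    delim = {"csv": ",", "tsv": "\t", "jcamp_like": " "}[dialect]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# wavenumber/cm-1{delim}{s.unit.value}\n")
        for nu, val in zip(s.grid, s.values):
            fh.write(f"{nu:.6g}{delim}{val:.10g}\n")


# -- resampling and arithmetic ---------------------------------------------


def resample(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate ``s`` onto ``grid`` (no extrapolation)."""
    target = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid,
                        dtype=float)
    lo, hi = s.span
    if target.min() < lo or target.max() > hi:
        raise SpectralRangeError(
            f"target grid [{target.min():g}, {target.max():g}] exceeds the "
            f"source span [{lo:g}, {hi:g}] cm⁻¹"
        )
    values = np.interp(target, s.grid, s.values)
    return Spectrum(target, values, s.unit, dict(s.meta))


def _check_shared_grid(spectra: Sequence[Spectrum]) -> np.ndarray:
    ref = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.size != ref.size or not np.array_equal(s.grid, ref):
            raise GridMismatchError(
                "spectra are not on one common grid; resample first"
            )
    return ref


def linear_combination(
    spectra: Sequence[Spectrum], coefficients: Sequence[float]
) -> Spectrum:
    """Pointwise Σ cᵢ·sᵢ over spectra sharing one grid and one unit."""
    if len(spectra) != len(coefficients):
        raise ValueError("one coefficient per spectrum is required")
    if not spectra:
        raise ValueError("need at least one spectrum")
    units = {s.unit for s in spectra}
    if len(units) > 1:
        raise UnitMismatchError(
            "cannot combine absorbance with molar-absorption spectra"
        )
    grid = _check_shared_grid(spectra)
    total = np.zeros_like(grid)
    for s, c in zip(spectra, coefficients):
        total = total + float(c) * s.values
    return Spectrum(grid.copy(), total, spectra[0].unit)
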