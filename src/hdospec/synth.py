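"""Seeded synthetic fixtures mirroring each analysis stage.

Every generator here is the documented inverse of exactly one analysis
stage, so its parameters are the ground truth for parameter-recovery tests:

* :func:`make_band` — skew-normal OD-stretch contour with analytic moments;
* :func:`make_binary_series` — inverts the two-state affected-water model;
* :func:`make_ternary_series` — inverts the ternary share decomposition;
* :func:`make_toy_shell` — a cluster whose O⋯O distance multiset is known
  exactly by construction.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skewnorm

from .affected import mean_molar_mass, solution_spectrum
from .errors import DomainError, GenerationError
from .spectra import SeriesPoint, Spectrum, Unit, _check_shared_grid
from .shells import ShellModel

__all__ = [
    "make_grid",
    "make_band",
    "reference_bands",
    "make_binary_series",
    "SyntheticTernary",
    "make_ternary_series",
    "AtrFixtures",
    "make_atr_fixtures",
    "make_toy_shell",
]

#: Additive noise default: fraction of the bulk peak, per the transmission
#: signal-to-noise of a purged research FTIR at 128 scans.
DEFAULT_NOISE_FRAC = 0.003


def make_grid(start: float = 2050.0, stop: float = 2800.0, step: float = 1.0) -> np.ndarray:
    """Uniform wavenumber grid, inclusive of ``stop`` when it fits."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def make_band(
    center: float,
    width: float,
    skew: float = 0.0,
    amplitude: float = 1.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Skew-normal band scaled to a given peak amplitude.

    ``center`` and ``width`` are the skew-normal location and scale; the
    analytic first moment ``loc + scale·δ·√(2/π)`` (δ = skew/√(1+skew²)) is
    stored in ``meta['analytic_mean']`` for oracle tests.  Negative skew
    gives the red tail typical of experimental HDO bands (gravity center
    below the maximum).
    """
    if width <= 0:
        raise DomainError("band width must be positive")
    if grid is None:
        grid = make_grid()
    shape = skewnorm.pdf(grid, skew, loc=center, scale=width)
    peak = shape.max()
    values = amplitude * shape / peak if peak > 0 and amplitude != 0 else np.zeros_like(grid)
    return Spectrum(
        grid.copy(), values, Unit.MOLAR_ABSORPTION,
        meta={
            "band": {"center": center, "width": width, "skew": skew,
                     "amplitude": amplitude},
            "analytic_mean": float(skewnorm.mean(skew, loc=center, scale=width)),
        },
    )


def reference_bands(grid: np.ndarray | None = None) -> dict[str, Spectrum]:
    """Stylised OD-stretch bands for the peptide–DMSO system species.

    Skew-normal parameters are frozen so that the numerically evaluated
    band maximum and gravity center sit close to the measured values for
    bulk HDO (2509 / 2497 cm⁻¹) and the solute-affected waters; they are
    emulations of band shape, not reconstructions of the unpublished
    experimental contours.
    """
    if grid is None:
        grid = make_grid()
    params = {
        # name: (loc, scale, skew) -> (target max, target gravity)
        "bulk": (2563.2, 100.0, -1.5),        # 2509, 2497
        "nagma": (2554.4, 93.0, -2.0),        # 2505, 2488
        "dmso": (2565.8, 109.4, -3.0),        # 2514, 2483
        "diglycine": (2574.5, 165.8, -3.0),   # 2496, ~2450
        "changed_strengthened": (2495.0, 150.0, -3.0),  # red-shifted, ~2417
    }
    return {name: make_band(loc, scale, skew, 1.0, grid)
            for name, (loc, scale, skew) in params.items()}


def make_binary_series(
    bulk: Spectrum,
    affected: Spectrum,
    N: float,
    molalities,
    d2o_ratio: float = 0.04,
    noise_sd: float | None = None,
    noise_mult: float = 0.0,
    seed: int = 0,
) -> list[SeriesPoint]:
    """Molality series obeying the two-state model, with seeded noise.

    ε(m) = ε_b + N·M·m·(ε_a − ε_b), then additive Gaussian noise with sd
    ``noise_sd`` (absolute; defaults to 0.3 % of the bulk peak) plus
    optional multiplicative noise ε·(1 + noise_mult·z).  Pass
    ``noise_sd=0`` for a noiseless series.
    """
    _check_shared_grid([bulk, affected])
    if N < 0:
        raise DomainError("affected number must be non-negative")
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_FRAC * float(bulk.values.max())
    M = mean_molar_mass(d2o_ratio)
    rng = np.random.default_rng(seed)
    out = []
    for m in molalities:
        s = solution_spectrum(affected, bulk, N, M, float(m))
        values = s.values
        if noise_mult:
            values = values * (1.0 + noise_mult * rng.standard_normal(values.size))
        if noise_sd:
            values = values + noise_sd * rng.standard_normal(values.size)
        sp = Spectrum(s.grid, values, s.unit,
                      {"true_N": N, "M": M, "m": float(m)})
        out.append(SeriesPoint(spectrum=sp, molality=float(m)))
    return out


@dataclass
class SyntheticTernary:
    """One synthetic ternary mixture with its generating ground truth."""

    molar_ratio: float
    eps_exp: Spectrum
    N_exp: float
    truth: dict = field(default_factory=dict)


def make_ternary_series(
    eps_A: Spectrum,
    eps_B: Spectrum,
    eps_changed: Spectrum | None,
    N_A: float,
    N_B: float,
    N_changed: float,
    molar_ratios=(1.0,),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[SyntheticTernary]:
    """Ternary affected spectra composed of pure and changed contributions.

    For each molar ratio ρ (solute B to solute A) the B share scales with ρ
    while the A share is fixed, emulating a constant-peptide series with
    increasing co-solute:

        ε_exp = (N_A·ε_A + ρ·N_B·ε_B + N_c·ε_c) / (N_A + ρ·N_B + N_c),
        N_exp = N_A + ρ·N_B + N_c.

    With ``N_changed = 0`` this is the ideal mixture (ΔN = 0 against the
    theoretical spectrum); a positive ``N_changed`` injects the
    changed-affected component, giving ΔN = +N_changed by construction.
    """
    spectra = [eps_A, eps_B] + ([eps_changed] if eps_changed is not None else [])
    _check_shared_grid(spectra)
    if min(N_A, N_B, N_changed) < 0:
        raise DomainError("affected numbers must be non-negative")
    if N_A + N_B + N_changed == 0:
        raise DomainError("at least one affected number must be positive")
    if N_changed > 0 and eps_changed is None:
        raise GenerationError("N_changed > 0 requires a changed spectrum")
    rng = np.random.default_rng(seed)
    out = []
    for rho in molar_ratios:
        nb = float(rho) * N_B
        n_exp = N_A + nb + N_changed
        mix = N_A * eps_A.values + nb * eps_B.values
        if eps_changed is not None:
            mix = mix + N_changed * eps_changed.values
        values = mix / n_exp
        if noise_sd:
            values = values + noise_sd * rng.standard_normal(values.size)
        eps_exp = Spectrum(eps_A.grid.copy(), values, eps_A.unit,
                           {"molar_ratio": float(rho)})
        out.append(SyntheticTernary(
            molar_ratio=float(rho), eps_exp=eps_exp, N_exp=n_exp,
            truth={"N_A": N_A, "N_B": nb, "N_changed": N_changed,
                   "noise_sd": noise_sd},
        ))
    return out


def _gauss(grid: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


#: Positions of the synthetic water-vapor rotational–vibrational lines, cm⁻¹.
VAPOR_LINES = (1340.0, 1396.0, 1448.0, 1508.0, 1560.0, 1616.0, 1653.0,
               1700.0, 1772.0, 1845.0, 1918.0)


@dataclass
class AtrFixtures:
    """Synthetic ATR series with the ingredients of the difference screen."""

    grid: np.ndarray
    pure_water: Spectrum
    vapor: Spectrum
    concentrations: list[float]
    c_dmso: float
    binary: list[Spectrum]  # peptide–water samples
    ternary: list[Spectrum]  # peptide–water–DMSO samples
    dmso_reference: Spectrum  # isolated DMSO contribution at c_dmso
    water_molarity_binary: list[float]
    water_molarity_ternary: list[float]
    truth: dict = field(default_factory=dict)


def make_atr_fixtures(
    concentrations=(0.05, 0.12, 0.19, 0.26, 0.33, 0.40),
    c_dmso: float = 0.40,
    coupling: float = 0.0,
    coupling_center: float = 1035.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AtrFixtures:
    """Synthetic ATR dilution series in the fingerprint region (900–2200 cm⁻¹).

    Each sample is water (scaled by its actual molarity) plus the solute's
    molar bands times its concentration, plus water-vapor lines with a
    per-sample coefficient.  Ternary samples add a fixed-concentration DMSO
    contribution.  ``coupling`` > 0 injects a direct solute–solute band at
    ``coupling_center`` with intensity ∝ c²·c_DMSO — a saturable complex
    whose molar spectrum grows with concentration, so it survives the
    difference-spectra chain, unlike every ideal (linear) contribution.
    With ``coupling = 0`` the chain must return a null ternary-vs-binary
    residual: the signature of no direct solute–solute interaction.
    """
    from .atr import PURE_WATER_MOLARITY

    grid = np.arange(900.0, 2201.0)
    water_vals = _gauss(grid, 1640.0, 80.0, 1.0) + 0.05
    vapor_vals = sum(_gauss(grid, c, 1.5, 1.0) for c in VAPOR_LINES)
    peptide_molar = _gauss(grid, 1400.0, 25.0, 2.0) + _gauss(grid, 1550.0, 30.0, 2.5)
    dmso_molar = _gauss(grid, 1045.0, 15.0, 3.0) + _gauss(grid, 1320.0, 10.0, 1.5)

    rng = np.random.default_rng(seed)
    pure_water = Spectrum(grid, water_vals, Unit.ABSORBANCE, {"species": "water"})
    vapor = Spectrum(grid, vapor_vals, Unit.ABSORBANCE, {"species": "vapor"})
    dmso_ref = Spectrum(grid, c_dmso * dmso_molar, Unit.ABSORBANCE,
                        {"species": "dmso", "c": c_dmso})

    binary, ternary, cw_bin, cw_ter = [], [], [], []
    for c in concentrations:
        k_vap = float(rng.uniform(0.1, 0.5))
        cw = PURE_WATER_MOLARITY - 2.0 * c  # solute displaces water
        vals = (c * peptide_molar + (cw / PURE_WATER_MOLARITY) * water_vals
                + k_vap * vapor_vals)
        if noise_sd:
            vals = vals + noise_sd * rng.standard_normal(grid.size)
        binary.append(Spectrum(grid, vals, Unit.ABSORBANCE, {"c": c}))
        cw_bin.append(cw)

        k_vap = float(rng.uniform(0.1, 0.5))
        cw = PURE_WATER_MOLARITY - 2.0 * c - 3.0 * c_dmso
        vals = (c * peptide_molar + c_dmso * dmso_molar
                + (cw / PURE_WATER_MOLARITY) * water_vals
                + k_vap * vapor_vals
                + coupling * c**2 * c_dmso * _gauss(grid, coupling_center, 15.0, 1.0))
        if noise_sd:
            vals = vals + noise_sd * rng.standard_normal(grid.size)
        ternary.append(Spectrum(grid, vals, Unit.ABSORBANCE, {"c": c}))
        cw_ter.append(cw)

    return AtrFixtures(
        grid=grid, pure_water=pure_water, vapor=vapor,
        concentrations=list(concentrations), c_dmso=c_dmso,
        binary=binary, ternary=ternary, dmso_reference=dmso_ref,
        water_molarity_binary=cw_bin, water_molarity_ternary=cw_ter,
        truth={"coupling": coupling, "coupling_center": coupling_center,
               "noise_sd": noise_sd},
    )


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_toy_shell(
    n_waters: int,
    radial_profile: float = 3.0,
    oo_target_distances=None,
    seed: int = 0,
    with_hydrogens: bool = True,
) -> ShellModel:
    """A cluster whose in-range O⋯O distance multiset is known exactly.

    The "solute" is a carbon chain with 10 Å spacing.  Waters are placed in
    pairs: pair k sits near chain atom k, its two oxygens separated by the
    k-th target distance, centred ``radial_profile`` Å from the anchor with
    the pair axis perpendicular to the radial direction (both oxygens then
    sit √(r² + d²/4) Å from the anchor, inside the 3.5 Å first-shell cutoff
    for the default geometry).  Pairs are mutually > 3 Å apart, so only the
    within-pair distances fall in the hydrogen-bond range — the target list
    is recovered verbatim by the O⋯O analysis.  An odd ``n_waters`` adds
    one isolated water contributing no in-range pair.
    """
    if n_waters < 1:
        raise DomainError("need at least one water")
    targets = list(oo_target_distances or [])
    n_pairs = n_waters // 2
    if len(targets) > n_pairs:
        raise GenerationError(
            f"{len(targets)} target distances need {2 * len(targets)} waters, "
            f"got {n_waters}"
        )
    while len(targets) < n_pairs:
        targets.append(2.8)
    for d in targets:
        if not 0.0 < d <= 2.0 * radial_profile:
            raise GenerationError(
                f"target O⋯O distance {d:g} Å infeasible at radial profile "
                f"{radial_profile:g} Å"
            )
    rng = np.random.default_rng(seed)
    elements: list[str] = []
    coords: list[np.ndarray] = []
    n_anchors = n_pairs + (n_waters % 2)
    anchors = np.zeros((max(n_anchors, 1), 3))
    anchors[:, 0] = 10.0 * np.arange(max(n_anchors, 1))
    for a in anchors:
        elements.append("C")
        coords.append(a)
    solute = np.arange(len(coords))

    def add_water(o_xyz: np.ndarray) -> None:
        elements.append("O")
        coords.append(o_xyz)
        if with_hydrogens:
            for u in _random_unit_vectors(rng, 2):
                elements.append("H")
                coords.append(o_xyz + 0.96 * u)

    for k, d in enumerate(targets):
        radial = _random_unit_vectors(rng, 1)[0]
        centre = anchors[k] + radial_profile * radial
        axis = _random_unit_vectors(rng, 1)[0]
        axis = axis - (axis @ radial) * radial  # orthogonalise to the radial
        norm = np.linalg.norm(axis)
        if norm < 1e-9:  # pathological draw: pick any perpendicular
            axis = np.cross(radial, [1.0, 0.0, 0.0])
            if np.linalg.norm(axis) < 1e-9:
                axis = np.cross(radial, [0.0, 1.0, 0.0])
            norm = np.linalg.norm(axis)
        axis = axis / norm
        add_water(centre + 0.5 * d * axis)
        add_water(centre - 0.5 * d * axis)
    if n_waters % 2:
        centre = anchors[n_anchors - 1] + radial_profile * _random_unit_vectors(rng, 1)[0]
        add_water(centre)

    return ShellModel(
        elements=elements,
        coords=np.asarray(coords),
        solute_selection=solute,
        label=f"toy-shell-{n_waters}w-seed{seed}",
    )
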