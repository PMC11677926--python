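"""Ternary-system affected-water analysis.

For two solutes A and B that perturb water independently, the affected
spectrum of the mixture is the affected-number-weighted mean of the pure
affected spectra,

    ε_theor = (N_A·ε_A + N_B·ε_B) / (N_A + N_B),

and the experimental affected number should equal N_theor = N_A + N_B.  The
deviation ΔN = N_exp − N_theor is the first diagnostic of hydration-shell
contact: negative ΔN means the shells share water molecules (overlap),
positive ΔN means extra water is perturbed by the contact (bridging or
newly-affected molecules).

The spectral counterpart is a decomposition of the experimental affected
spectrum into shares of the pure affected spectra plus a residual,

    N_exp·ε_exp = w_A·ε_A + w_B·ε_B + N_changed·ε_changed,

where ε_changed is the spectrum of "changed-affected" water — molecules
perturbed by both solutes at once.  The weights are found by a seeded
stochastic search (random restarts over the simplex w_A + w_B ≤ N_exp,
Nelder–Mead local refinement).  Because an affected-water spectrum cannot be
negative, the misfit strongly penalises negative residual lobes; this is
what pins the weights instead of letting the residual be absorbed into the
overlapping pure-component bands.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ConvergenceError, DomainError
from .spectra import Spectrum, _check_shared_grid

__all__ = [
    "theoretical_affected_spectrum",
    "Interpretation",
    "delta_N",
    "TernarySettings",
    "TernaryDecomposition",
    "decompose_ternary",
]


def theoretical_affected_spectrum(
    eps_A: Spectrum, eps_B: Spectrum, N_A: float, N_B: float
) -> Spectrum:
    """Ideal-mixture affected spectrum (N_A·ε_A + N_B·ε_B)/(N_A + N_B)."""
    _check_shared_grid([eps_A, eps_B])
    if N_A < 0 or N_B < 0:
        raise DomainError("affected numbers must be non-negative")
    total = N_A + N_B
    if total == 0:
        raise DomainError("N_A + N_B must be positive")
    if N_B == 0:  # single-solute limits are exact, not rounded
        values = eps_A.values.copy()
    elif N_A == 0:
        values = eps_B.values.copy()
    else:
        values = (N_A * eps_A.values + N_B * eps_B.values) / total
    return Spectrum(eps_A.grid.copy(), values, eps_A.unit,
                    {"N_A": N_A, "N_B": N_B})


class Interpretation(str, enum.Enum):
    OVERLAP = "overlap"  # negative ΔN: shells share water
    EXCESS_PERTURBATION = "excess_perturbation"  # positive ΔN
    INDEPENDENT = "independent"  # ΔN ≈ 0


def delta_N(
    N_exp: float, N_theor: float, tol: float = 0.05
) -> tuple[float, Interpretation]:
    """ΔN = N_exp − N_theor with its sign interpretation.

    |ΔN| below ``tol`` reads as independent hydration shells; negative ΔN as
    shell overlap (shared waters); positive ΔN as excess perturbation
    (bridging or newly affected waters).
    """
    if N_exp < 0 or N_theor < 0:
        raise DomainError("affected numbers must be non-negative")
    dn = N_exp - N_theor
    if abs(dn) < tol:
        kind = Interpretation.INDEPENDENT
    elif dn < 0:
        kind = Interpretation.OVERLAP
    else:
        kind = Interpretation.EXCESS_PERTURBATION
    return dn, kind


@dataclass
class TernarySettings:
    """Stochastic-search configuration for :func:`decompose_ternary`.

    n_restarts:
        Uniform random starting points on the simplex w_A + w_B ≤ N_exp.
    negativity_weight:
        Multiplier on the squared negative part of the residual.  Large
        values approximate a hard ε_changed ≥ 0 constraint, which is what
        identifies the weights when the changed band overlaps the pure
        bands.
    noise_tol:
        Residual values above −noise_tol are not penalised (set to ≈3× the
        spectral noise sd for noisy data).
    seed:
        Seed for the restart sampler; identical seeds give identical output.
    maxiter:
        Nelder–Mead iteration cap per restart.
    """

    n_restarts: int = 32
    negativity_weight: float = 1000.0
    noise_tol: float = 0.0
    seed: int = 0
    maxiter: int = 400


@dataclass
class TernaryDecomposition:
    """Result of the ternary spectral decomposition.

    ``N_theor`` is the ideal share w_A + w_B recovered by the fit, so
    ``delta_N = N_exp − N_theor = N_changed`` by mass balance.
    """

    share_A: Spectrum
    N_A: float
    share_B: Spectrum
    N_B: float
    changed: Spectrum
    N_changed: float
    N_exp: float
    N_theor: float
    delta_N: float
    objective: float
    seed: int
    diagnostics: dict = field(default_factory=dict)


def _misfit(w: np.ndarray, target: np.ndarray, A: np.ndarray, B: np.ndarray,
            cfg: TernarySettings, scale: float) -> float:
    wa, wb = w
    penalty = 0.0
    if wa < 0:
        penalty += (wa / scale) ** 2 * 1e6
        wa = 0.0
    if wb < 0:
        penalty += (wb / scale) ** 2 * 1e6
        wb = 0.0
    r = target - wa * A - wb * B
    neg = np.minimum(r + cfg.noise_tol, 0.0)
    return float(np.mean(r**2) + cfg.negativity_weight * np.mean(neg**2)) + penalty


def decompose_ternary(
    eps_exp: Spectrum,
    N_exp: float,
    eps_A: Spectrum,
    eps_B: Spectrum,
    settings: TernarySettings | None = None,
) -> TernaryDecomposition:
    """Decompose an experimental ternary affected spectrum.

    Finds non-negative weights (w_A, w_B) minimising the penalised misfit of
    w_A·ε_A + w_B·ε_B against N_exp·ε_exp; the residual, rescaled by
    N_changed = N_exp − w_A − w_B, is the changed-affected spectrum.
    Mass balance N_A + N_B + N_changed = N_exp holds by construction.

    Raises
    ------
    ConvergenceError
        If the best fit still shows negative residual beyond tolerance;
        the best decomposition found is attached as ``.best``.
    """
    cfg = settings or TernarySettings()
    _check_shared_grid([eps_exp, eps_A, eps_B])
    if N_exp <= 0:
        raise DomainError("N_exp must be positive")
    target = N_exp * eps_exp.values
    A = eps_A.values
    B = eps_B.values
    scale = max(float(np.max(np.abs(target))), 1e-30)

    rng = np.random.default_rng(cfg.seed)
    best_w, best_J = None, np.inf
    for _ in range(cfg.n_restarts):
        # uniform over the simplex {w >= 0, w_A + w_B <= N_exp}
        u = rng.random(2)
        if u.sum() > 1.0:
            u = 1.0 - u
        w0 = u * N_exp
        res = minimize(
            _misfit, w0, args=(target, A, B, cfg, scale),
            method="Nelder-Mead",
            options={"maxiter": cfg.maxiter, "xatol": 1e-8 * max(N_exp, 1.0),
                     "fatol": 1e-14 * scale**2},
        )
        if res.fun < best_J:
            best_J, best_w = float(res.fun), np.maximum(res.x, 0.0)

    # deterministic polish from the stochastic winner
    res = minimize(
        _misfit, best_w, args=(target, A, B, cfg, scale),
        method="Nelder-Mead",
        options={"maxiter": 4 * cfg.maxiter, "xatol": 1e-10 * max(N_exp, 1.0),
                 "fatol": 1e-16 * scale**2},
    )
    if res.fun < best_J:
        best_J, best_w = float(res.fun), np.maximum(res.x, 0.0)

    wa, wb = float(best_w[0]), float(best_w[1])
    resid = target - wa * A - wb * B
    n_changed = N_exp - wa - wb

    if n_changed > 1e-6:
        changed_values = resid / n_changed
    else:
        changed_values = resid  # near-ideal mixture: residual ≈ 0 already
    changed = Spectrum(eps_exp.grid.copy(), changed_values, eps_exp.unit,
                       {"N_changed": n_changed})

    n_theor = wa + wb
    decomp = TernaryDecomposition(
        share_A=eps_A.copy(), N_A=wa,
        share_B=eps_B.copy(), N_B=wb,
        changed=changed, N_changed=n_changed,
        N_exp=N_exp, N_theor=n_theor,
        delta_N=N_exp - n_theor,
        objective=best_J, seed=cfg.seed,
        diagnostics={
            "residual_min": float(resid.min()),
            "residual_integral": float(np.trapezoid(resid, eps_exp.grid)),
        },
    )
    floor = -(cfg.noise_tol + 0.02 * scale)
    if float(resid.min()) < floor:
        raise ConvergenceError(
            f"residual has a negative lobe ({resid.min():.3g}) beyond "
            f"tolerance after {cfg.n_restarts} restarts", best=decomp,
        )
    return decomp
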