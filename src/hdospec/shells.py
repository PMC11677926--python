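"""Hydration-cluster geometry: first-shell oxygens, O⋯O distances, curves.

Post-processing of optimised hydration clusters (a central solute plus a
shell of explicit waters).  The first hydration layer is taken as all water
oxygens within a cutoff (default 3.5 Å, the average layer thickness) of any
solute atom; all O⋯O pair distances inside the layer are collected,
restricted to the hydrogen-bond range (default 2.55–3.00 Å), sorted, and
plotted against a rank normalised to 1 — the interaction curve.  The slope
of the curve encodes the distance spread and an inflection marks two
hydrogen-bond sub-populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DomainError, StructureParseError

__all__ = [
    "ShellModel",
    "InteractionCurve",
    "read_structure",
    "write_xyz",
    "first_shell_oxygens",
    "oo_distances",
    "normalized_interaction_curve",
    "curve_inflection",
]

FIRST_SHELL_CUTOFF = 3.5  # Å
OO_RANGE = (2.55, 3.00)  # Å, strong-to-weak hydrogen bonds

_ELEMENTS = {
    "H", "D", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg",
    "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Fe", "Zn", "Br", "I",
}


@dataclass
class ShellModel:
    """Atom records of a hydration cluster.

    ``solute_selection`` indexes the central-molecule atoms; every oxygen
    outside the selection is treated as a water oxygen.
    """

    elements: list[str]
    coords: np.ndarray  # (n, 3) Å
    solute_selection: np.ndarray = field(default_factory=lambda: np.array([], int))
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError("one element symbol per coordinate row required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.solute_selection = np.asarray(self.solute_selection, dtype=int)
        n = len(self.elements)
        if self.solute_selection.size and (
            self.solute_selection.min() < 0 or self.solute_selection.max() >= n
        ):
            raise ValueError("solute selection indices out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def water_oxygen_indices(self, include_solute_oxygens: bool = False) -> np.ndarray:
        """Indices of oxygen atoms, excluding the solute unless asked."""
        solute = set(self.solute_selection.tolist())
        return np.array(
            [i for i, el in enumerate(self.elements)
             if el == "O" and (include_solute_oxygens or i not in solute)],
            dtype=int,
        )


@dataclass
class InteractionCurve:
    """Sorted O⋯O distances against normalised rank (last rank = 1)."""

    sorted_distances: np.ndarray
    normalized_index: np.ndarray
    count: int

    def __post_init__(self) -> None:
        self.sorted_distances = np.asarray(self.sorted_distances, dtype=float)
        self.normalized_index = np.asarray(self.normalized_index, dtype=float)
        if np.any(np.diff(self.sorted_distances) < 0):
            raise ValueError("distances must be sorted ascending")


def _normalize_element(sym: str, lineno: int, path) -> str:
    el = sym.strip().capitalize()
    if el not in _ELEMENTS:
        raise StructureParseError(f"{path}:{lineno}: unknown element {sym!r}")
    return el


def _read_xyz(path: Path) -> tuple[list[str], np.ndarray]:
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise StructureParseError(
            f"{path}:1: expected an atom count, got {lines[0]!r}"
        ) from exc
    body = lines[2:]  # line 2 is the comment line
    elements, coords = [], []
    for off, line in enumerate(body):
        lineno = off + 3
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise StructureParseError(
                f"{path}:{lineno}: expected 'element x y z', got {line!r}"
            )
        elements.append(_normalize_element(parts[0], lineno, path))
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError as exc:
            raise StructureParseError(
                f"{path}:{lineno}: non-numeric coordinate in {line!r}"
            ) from exc
    if len(elements) != n:
        raise StructureParseError(
            f"{path}: header promises {n} atoms, found {len(elements)}"
        )
    return elements, np.asarray(coords)


def _read_pdb(path: Path) -> tuple[list[str], np.ndarray]:
    # Bio.PDB handles the fixed-column records, altlocs and HETATM waters.
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise StructureParseError(f"{path}: PDB parse failed: {exc}") from exc
    elements, coords = [], []
    for atom in structure.get_atoms():
        el = (atom.element or atom.get_name()[:1]).strip().capitalize()
        if el not in _ELEMENTS:
            raise StructureParseError(
                f"{path}: unknown element {atom.element!r} for atom "
                f"{atom.get_full_id()}"
            )
        elements.append(el)
        coords.append(atom.coord)
    if not elements:
        raise StructureParseError(f"{path}: no atom records found")
    return elements, np.asarray(coords, dtype=float)


def read_structure(
    path: str | Path,
    fmt: str | None = None,
    solute_selection: Iterable[int] = (),
    label: str = "",
) -> ShellModel:
    """Read an XYZ or PDB coordinate file into a :class:`ShellModel`.

    ``fmt`` is inferred from the extension when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        elements, coords = _read_xyz(path)
    elif fmt == "pdb":
        elements, coords = _read_pdb(path)
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")
    return ShellModel(
        elements=elements, coords=coords,
        solute_selection=np.asarray(list(solute_selection), dtype=int),
        label=label or path.stem,
    )


def write_xyz(model: ShellModel, path: str | Path, comment: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{model.n_atoms}\n{comment or model.label}\n")
        for el, (x, y, z) in zip(model.elements, model.coords):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def first_shell_oxygens(
    model: ShellModel,
    cutoff: float = FIRST_SHELL_CUTOFF,
    include_solute_oxygens: bool = False,
) -> np.ndarray:
    """Water oxygens whose nearest solute atom lies within ``cutoff`` Å."""
    if cutoff <= 0:
        raise DomainError("cutoff must be positive")
    if model.solute_selection.size == 0:
        return np.array([], dtype=int)
    ox = model.water_oxygen_indices(include_solute_oxygens)
    if ox.size == 0:
        return ox
    solute_xyz = model.coords[model.solute_selection]
    o_xyz = model.coords[ox]
    d = np.linalg.norm(o_xyz[:, None, :] - solute_xyz[None, :, :], axis=2)
    return ox[d.min(axis=1) <= cutoff]


def oo_distances(
    model: ShellModel,
    oxygens: Sequence[int] | np.ndarray,
    r_range: tuple[float, float] = OO_RANGE,
) -> np.ndarray:
    """All pairwise O–O distances (i < j) among ``oxygens``, restricted to
    ``r_range``.  Fewer than two oxygens yield an empty array."""
    idx = np.asarray(list(oxygens), dtype=int)
    if idx.size < 2:
        return np.array([], dtype=float)
    d = pdist(model.coords[idx])
    lo, hi = r_range
    return d[(d >= lo) & (d <= hi)]


def normalized_interaction_curve(distances: Sequence[float]) -> InteractionCurve:
    """Sort distances ascending and map rank i (1…n) to i/n."""
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise DomainError("cannot build an interaction curve from no distances")
    d = np.sort(d)
    n = d.size
    return InteractionCurve(
        sorted_distances=d,
        normalized_index=np.arange(1, n + 1) / n,
        count=int(n),
    )


def curve_inflection(curve: InteractionCurve) -> tuple[float, float]:
    """Locate the strongest inflection of the interaction curve.

    Returns (normalized_index, second_difference) at the rank where the
    second difference of the sorted distances peaks — the diagnostic for a
    "broken" curve separating two hydrogen-bond populations.
    """
    d = curve.sorted_distances
    if d.size < 3:
        raise DomainError("inflection needs at least three distances")
    dd = np.diff(d, n=2)
    i = int(np.argmax(dd))
    return float(curve.normalized_index[i + 1]), float(dd[i])
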