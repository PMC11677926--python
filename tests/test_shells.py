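import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hdospec.errors import DomainError, StructureParseError
from hdospec.shells import (
    ShellModel,
    curve_inflection,
    first_shell_oxygens,
    normalized_interaction_curve,
    oo_distances,
    read_structure,
    write_xyz,
)
from hdospec.synth import make_toy_shell


def brute_force_pairs(coords, lo, hi):
    """Independent double-loop all-pairs oracle."""
    out = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.sqrt(((coords[i] - coords[j]) ** 2).sum()))
            if lo <= d <= hi:
                out.append(d)
    return sorted(out)


class TestStructureIO:
    def test_three_atom_water_xyz(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text("3\nwater\nO 0.0 0.0 0.0\nH 0.96 0.0 0.0\nH 0.0 0.96 0.0\n")
        m = read_structure(p)
        assert m.n_atoms == 3
        assert list(m.water_oxygen_indices()) == [0]

    def test_pdb_hetatm_waters_indexed(self, tmp_path):
        lines = []
        for i, (x, y, z) in enumerate([(0.0, 0.0, 0.0), (2.8, 0.0, 0.0)], 1):
            lines.append(
                f"HETATM{i:5d}  O   HOH A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O"
            )
        lines.append("END")
        p = tmp_path / "w.pdb"
        p.write_text("\n".join(lines) + "\n")
        m = read_structure(p)
        assert m.n_atoms == 2
        assert list(m.water_oxygen_indices()) == [0, 1]

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "e.xyz"
        p.write_text("")
        with pytest.raises(StructureParseError):
            read_structure(p)

    def test_unknown_element_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\n\nXx 0 0 0\n")
        with pytest.raises(StructureParseError, match=":3"):
            read_structure(p)

    def test_xyz_round_trip(self, tmp_path):
        model = make_toy_shell(4, oo_target_distances=[2.7, 2.95], seed=2)
        p = tmp_path / "shell.xyz"
        write_xyz(model, p)
        back = read_structure(p, solute_selection=model.solute_selection)
        assert back.elements == model.elements
        np.testing.assert_allclose(back.coords, model.coords, atol=1e-6)


class TestFirstShell:
    def _model_with_radii(self, radii):
        elements = ["C"] + ["O"] * len(radii)
        coords = [[0.0, 0.0, 0.0]] + [[r, 0.0, 0.0] for r in radii]
        return ShellModel(elements, np.array(coords), solute_selection=[0])

    def test_inclusion_and_exclusion_around_cutoff(self):
        m = self._model_with_radii([3.0, 3.6])
        sel = first_shell_oxygens(m)
        assert list(sel) == [1]

    def test_known_radii_select_exactly_three(self):
        m = self._model_with_radii([2.8, 3.0, 3.4, 3.6, 4.0])
        assert first_shell_oxygens(m).size == 3

    def test_solute_oxygen_excluded_by_default(self):
        m = ShellModel(["O", "O"], np.array([[0.0, 0.0, 0.0], [2.8, 0.0, 0.0]]),
                       solute_selection=[0])
        sel = first_shell_oxygens(m)
        assert list(sel) == [1]
        sel_all = first_shell_oxygens(m, include_solute_oxygens=True)
        assert list(sel_all) == [0, 1]


class TestOODistances:
    def test_single_pair(self):
        m = ShellModel(["O", "O"], np.array([[0, 0, 0], [2.8, 0, 0]], float))
        np.testing.assert_allclose(oo_distances(m, [0, 1]), [2.8])

    def test_equilateral_triangle(self):
        a = 2.9
        coords = np.array([
            [0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0],
        ])
        m = ShellModel(["O"] * 3, coords)
        np.testing.assert_allclose(oo_distances(m, [0, 1, 2]),
                                   [a, a, a], atol=1e-12)

    def test_random_cloud_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        for n in (10, 25, 50):
            coords = rng.uniform(0, 8, size=(n, 3))
            m = ShellModel(["O"] * n, coords)
            got = sorted(oo_distances(m, range(n), (2.0, 4.0)))
            assert got == pytest.approx(brute_force_pairs(coords, 2.0, 4.0))

    def test_rigid_motion_invariance(self):
        model = make_toy_shell(10, oo_target_distances=[2.6, 2.7, 2.8, 2.9, 3.0],
                               seed=9)
        oxy = model.water_oxygen_indices()
        base = np.sort(oo_distances(model, oxy))
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 113.0], degrees=True)
        moved = ShellModel(
            model.elements,
            rot.apply(model.coords) + np.array([5.0, -3.0, 11.0]),
            model.solute_selection,
        )
        np.testing.assert_allclose(np.sort(oo_distances(moved, oxy)), base,
                                   atol=1e-9)


class TestInteractionCurve:
    def test_single_distance_curve(self):
        c = normalized_interaction_curve([2.8])
        assert c.count == 1
        np.testing.assert_allclose(c.normalized_index, [1.0])

    def test_two_distances_sorted_and_ranked(self):
        c = normalized_interaction_curve([2.9, 2.7])
        np.testing.assert_allclose(c.sorted_distances, [2.7, 2.9])
        np.testing.assert_allclose(c.normalized_index, [0.5, 1.0])

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            normalized_interaction_curve([])

    def test_uniform_shift_moves_curve_down(self):
        rng = np.random.default_rng(1)
        d = np.sort(rng.uniform(2.6, 3.0, 40))
        base = normalized_interaction_curve(d)
        shifted = normalized_interaction_curve(d - 0.05)
        assert np.all(shifted.sorted_distances < base.sorted_distances)

    def test_bimodal_distances_show_inflection(self):
        """Two distance populations make the sorted curve 'break'."""
        tight = np.linspace(2.70, 2.78, 20)
        loose = np.linspace(2.88, 3.00, 12)
        curve = normalized_interaction_curve(np.concatenate([tight, loose]))
        pos, mag = curve_inflection(curve)
        assert 0.5 < pos < 0.8  # break sits between the populations
        assert mag > 5 * np.median(np.abs(np.diff(curve.sorted_distances, n=2)))
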