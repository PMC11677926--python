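import numpy as np
import pytest
from scipy.signal import savgol_filter

from hdospec.atr import (
    PURE_WATER_MOLARITY,
    difference_screen,
    mean_difference_spectrum,
    subtract_vapor,
    subtract_water_background,
    to_molar_spectrum,
    vapor_coefficient,
)
from hdospec.bands import band_maximum
from hdospec.errors import ConfigError, DomainError
from hdospec.spectra import Spectrum, Unit
from hdospec.synth import make_atr_fixtures


@pytest.fixture(scope="module")
def atr_grid():
    return np.arange(900.0, 2201.0)


@pytest.fixture(scope="module")
def vapor(atr_grid):
    lines = sum(np.exp(-0.5 * ((atr_grid - c) / 1.5) ** 2)
                for c in (1362.0, 1420.0, 1540.0, 1650.0, 1790.0, 1900.0))
    return Spectrum(atr_grid, lines)


@pytest.fixture(scope="module")
def smooth_band(atr_grid):
    return Spectrum(atr_grid, 0.8 * np.exp(-0.5 * ((atr_grid - 1600.0) / 90.0) ** 2))


class TestVaporSubtraction:
    def test_known_admixture_recovered(self, smooth_band, vapor):
        s = Spectrum(smooth_band.grid, smooth_band.values + 0.3 * vapor.values)
        # oracle: brute-force grid search over k on the synthetic sum
        ks = np.arange(0.0, 1.0, 0.001)
        mask = (s.grid >= 1300) & (s.grid <= 2000)
        rough = [
            float(np.sum(np.diff(s.values[mask] - k * vapor.values[mask], n=2) ** 2))
            for k in ks
        ]
        k_oracle = ks[int(np.argmin(rough))]
        k, _ = vapor_coefficient(s, vapor)
        assert k == pytest.approx(0.3, abs=0.01)
        assert k == pytest.approx(k_oracle, abs=0.01)
        clean = subtract_vapor(s, [vapor])
        assert clean.meta["vapor_k"] == pytest.approx(0.3, abs=0.01)

    def test_vapor_free_sample_gets_zero_coefficient(self, smooth_band, vapor):
        k, _ = vapor_coefficient(smooth_band, vapor)
        assert abs(k) < 0.01

    def test_pure_vapor_fully_removed(self, vapor):
        k, rough = vapor_coefficient(vapor, vapor)
        assert k == pytest.approx(1.0, abs=1e-6)
        assert rough == pytest.approx(0.0, abs=1e-12)

    def test_no_references_is_config_error(self, smooth_band):
        with pytest.raises(ConfigError):
            subtract_vapor(smooth_band, [])


class TestWaterBackground:
    def test_pure_water_self_subtraction(self, smooth_band):
        out = subtract_water_background(smooth_band, smooth_band,
                                        PURE_WATER_MOLARITY)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_half_concentration_halves_subtraction(self, smooth_band):
        out = subtract_water_background(smooth_band, smooth_band,
                                        PURE_WATER_MOLARITY / 2)
        np.testing.assert_allclose(out.values, smooth_band.values / 2, atol=1e-15)

    def test_constructed_solute_band_recovered_exactly(self, atr_grid, smooth_band):
        solute = np.exp(-0.5 * ((atr_grid - 1100.0) / 20.0) ** 2)
        sample = Spectrum(atr_grid, solute + 0.9 * smooth_band.values)
        out = subtract_water_background(sample, smooth_band,
                                        0.9 * PURE_WATER_MOLARITY)
        np.testing.assert_allclose(out.values, solute, atol=1e-12)

    def test_above_pure_water_molarity_rejected(self, smooth_band):
        with pytest.raises(DomainError):
            subtract_water_background(smooth_band, smooth_band, 56.0)


class TestMolarAndDifference:
    def test_molar_conversion_scales_and_relabels(self, smooth_band):
        out = to_molar_spectrum(smooth_band, 0.4)
        assert out.unit == Unit.MOLAR_ABSORPTION
        np.testing.assert_allclose(out.values, smooth_band.values / 0.4)
        half = to_molar_spectrum(smooth_band, 0.8)
        np.testing.assert_allclose(half.values, out.values / 2)

    def test_molar_conversion_requires_positive_concentration(self, smooth_band):
        with pytest.raises(DomainError):
            to_molar_spectrum(smooth_band, 0.0)

    def test_concentration_independent_series_gives_null(self, smooth_band):
        out = mean_difference_spectrum([smooth_band] * 4)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_arithmetic_progression_closed_form(self, atr_grid):
        base = Spectrum(atr_grid, np.exp(-0.5 * ((atr_grid - 1500.0) / 60.0) ** 2))
        d = 0.01 * np.cos(atr_grid / 200.0)
        series = [Spectrum(atr_grid, base.values + i * d) for i in range(5)]
        out = mean_difference_spectrum(series)
        np.testing.assert_allclose(out.values, np.mean([1, 2, 3, 4]) * d,
                                   atol=1e-14)

    def test_two_spectrum_series_is_plain_difference(self, atr_grid, smooth_band):
        other = Spectrum(atr_grid, smooth_band.values * 1.1)
        out = mean_difference_spectrum([smooth_band, other])
        np.testing.assert_allclose(out.values,
                                   other.values - smooth_band.values)

    def test_single_spectrum_rejected(self, smooth_band):
        with pytest.raises(ValueError):
            mean_difference_spectrum([smooth_band])


class TestFullScreen:
    """The concentration-difference chain on synthetic ternary mixtures."""

    @staticmethod
    def _screens(fx):
        binary = difference_screen(
            fx.binary, fx.concentrations, fx.water_molarity_binary,
            fx.pure_water, vapor_refs=[fx.vapor],
        )
        ternary = difference_screen(
            fx.ternary, fx.concentrations, fx.water_molarity_ternary,
            fx.pure_water, vapor_refs=[fx.vapor],
            matched_references=[fx.dmso_reference] * len(fx.ternary),
        )
        return binary, ternary

    @staticmethod
    def _propagated_noise(fx):
        c = np.asarray(fx.concentrations)
        return fx.truth["noise_sd"] * np.sqrt(
            np.sum(1.0 / c[1:] ** 2) / len(c[1:]) ** 2 + 1.0 / c[0] ** 2
        ) * np.sqrt(2.0)

    def test_uncoupled_ternary_matches_binary_screen(self):
        fx = make_atr_fixtures(noise_sd=5e-4, seed=11)
        binary, ternary = self._screens(fx)
        resid = ternary.values - binary.values
        assert np.sqrt(np.mean(resid**2)) < 2.0 * self._propagated_noise(fx)

    def test_injected_coupling_band_located(self):
        fx = make_atr_fixtures(coupling=3.0, coupling_center=1035.0,
                               noise_sd=5e-4, seed=11)
        binary, ternary = self._screens(fx)
        resid = Spectrum(fx.grid,
                         savgol_filter(ternary.values - binary.values, 31, 2))
        assert band_maximum(resid, (950.0, 1150.0)) == pytest.approx(1035.0, abs=2.0)
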