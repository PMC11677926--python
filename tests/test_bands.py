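import numpy as np
import pytest

from hdospec.bands import (
    BoundaryMaximumWarning,
    band_maximum,
    band_parameters,
    distance_distribution,
    distance_to_wavenumber,
    distribution_difference,
    gravity_center,
    wavenumber_to_distance,
)
from hdospec.errors import DomainError, SpectralRangeError
from hdospec.spectra import Spectrum
from hdospec.synth import make_band, make_grid


class TestCorrelation:
    def test_reference_distance_maps_to_known_wavenumber(self):
        # direct evaluation: 2727 − exp(16.01 − 3.73·2.827) = 2490.66
        assert distance_to_wavenumber(2.827) == pytest.approx(2490.7, abs=0.1)

    def test_exponent_zero_point(self):
        r0 = 16.01 / 3.73
        assert distance_to_wavenumber(r0) == pytest.approx(2726.0, abs=1e-9)
        assert wavenumber_to_distance(2726.0) == pytest.approx(r0, abs=1e-9)

    def test_strict_monotonicity(self):
        r = np.linspace(2.3, 3.5, 500)
        nu = distance_to_wavenumber(r)
        assert np.all(np.diff(nu) > 0)

    def test_inverse_pair_on_fine_grid(self):
        r = np.arange(2.3, 3.5 + 5e-4, 1e-3)
        back = wavenumber_to_distance(distance_to_wavenumber(r))
        assert np.abs(back - r).max() < 1e-9

    def test_singular_wavenumber_rejected(self):
        with pytest.raises(DomainError):
            wavenumber_to_distance(2727.0)


class TestBandParameters:
    def test_gaussian_maximum_on_coarse_grid(self):
        g = np.arange(2300.0, 2700.0 + 2, 4.0)  # 4 cm⁻¹ sampling
        s = Spectrum(g, np.exp(-0.5 * ((g - 2496.0) / 60.0) ** 2))
        assert band_maximum(s, (2300.0, 2700.0)) == pytest.approx(2496.0, abs=0.5)

    def test_monotone_segment_flags_boundary(self):
        g = np.arange(2400.0, 2500.0)
        s = Spectrum(g, np.linspace(0.0, 1.0, g.size))
        with pytest.warns(BoundaryMaximumWarning):
            nu = band_maximum(s, (2400.0, 2499.0))
        assert nu == pytest.approx(2499.0)

    def test_flat_window_is_error(self):
        g = np.arange(2400.0, 2500.0)
        with pytest.raises(DomainError):
            band_maximum(Spectrum(g, np.ones(g.size)), (2400.0, 2499.0))

    def test_gravity_center_of_symmetric_band(self, gaussian_spectrum):
        s = gaussian_spectrum(center=2500.0, sigma=40.0, step=0.5)
        assert gravity_center(s, (2200.0, 2800.0)) == pytest.approx(2500.0,
                                                                    abs=1e-6)

    def test_gravity_center_balances_two_equal_peaks(self):
        g = np.arange(2300.0, 2700.0, 0.5)
        v = (np.exp(-0.5 * ((g - 2400.0) / 20.0) ** 2)
             + np.exp(-0.5 * ((g - 2600.0) / 20.0) ** 2))
        assert gravity_center(Spectrum(g, v), (2300.0, 2699.0)) == pytest.approx(
            2500.0, abs=1e-3
        )

    def test_red_tail_pulls_gravity_center_below_maximum(self, grid):
        s = make_band(2500.0, 80.0, -3.0, 1.0, grid)
        # oracle: dense numerical first moment of the same analytic band
        dense = make_band(2500.0, 80.0, -3.0, 1.0,
                          make_grid(2050.0, 2800.0, 0.05))
        dense_g = float(np.trapezoid(dense.grid * dense.values, dense.grid)
                        / np.trapezoid(dense.values, dense.grid))
        params = band_parameters(s, (2100.0, 2800.0))
        assert params.nu_gravity < params.nu_max
        assert params.nu_gravity == pytest.approx(dense_g, abs=0.1)

    def test_zero_intensity_window_is_error(self):
        g = np.arange(2400.0, 2500.0)
        with pytest.raises(DomainError):
            gravity_center(Spectrum(g, np.zeros(g.size)), (2400.0, 2499.0))


class TestDistanceDistribution:
    def test_flat_spectrum_limit_matches_closed_form(self):
        g = make_grid(2050.0, 2800.0, 1.0)
        s = Spectrum(g, np.ones(g.size))
        dist = distance_distribution(s, (2.60, 3.10))
        r = dist.r_grid
        closed = 3.73 * np.exp(16.01 - 3.73 * r)
        closed = closed / np.trapezoid(closed, r)
        np.testing.assert_allclose(dist.p_values, closed, rtol=1e-6)

    def test_unit_normalisation_for_random_bands(self, grid):
        rng = np.random.default_rng(0)
        for _ in range(25):
            s = make_band(rng.uniform(2350, 2550), rng.uniform(30, 90),
                          rng.uniform(-3, 3), 1.0, grid)
            dist = distance_distribution(s, (2.58, 3.15))
            area = float(np.trapezoid(dist.p_values, dist.r_grid))
            assert area == pytest.approx(1.0, abs=1e-6)

    def test_jacobian_offset_shrinks_with_bandwidth(self, grid):
        """r_max(P) is not the image of ν_max, but converges to it."""
        offsets = []
        for width in (40.0, 20.0, 10.0, 5.0):
            s = make_band(2450.0, width, 0.0, 1.0, grid)
            dist = distance_distribution(s, (2.60, 3.05), n_points=8001)
            direct = wavenumber_to_distance(band_maximum(s, (2200.0, 2700.0)))
            offsets.append(abs(dist.r_max - direct))
            # oracle: dense brute-force transform on a 100× finer ν grid
            dense = make_band(2450.0, width, 0.0, 1.0,
                              make_grid(2050.0, 2800.0, 0.01))
            r = np.linspace(2.60, 3.05, 8001)
            p = np.interp(distance_to_wavenumber(r), dense.grid, dense.values) \
                * 3.73 * np.exp(16.01 - 3.73 * r)
            r_max_oracle = r[int(np.argmax(p))]
            assert dist.r_max == pytest.approx(r_max_oracle, abs=1e-3)
        assert offsets[0] > offsets[-1]
        assert all(a > b for a, b in zip(offsets, offsets[1:]))

    def test_red_shift_decreases_both_moments(self, grid):
        a = distance_distribution(make_band(2480.0, 50.0, 0.0, 1.0, grid),
                                  (2.58, 3.10))
        b = distance_distribution(make_band(2430.0, 50.0, 0.0, 1.0, grid),
                                  (2.58, 3.10))
        assert b.r_max < a.r_max
        assert b.r_gravity < a.r_gravity

    def test_window_outside_spectrum_rejected(self, gaussian_spectrum):
        s = gaussian_spectrum(lo=2400.0, hi=2600.0)
        with pytest.raises(SpectralRangeError):
            distance_distribution(s, (2.55, 3.2))

    def test_negative_lobe_beyond_tolerance_rejected(self, grid):
        v = np.exp(-0.5 * ((grid - 2450.0) / 50.0) ** 2) - 0.1
        with pytest.raises(DomainError):
            distance_distribution(Spectrum(grid, v), (2.60, 3.05))


class TestDistributionDifference:
    def test_self_difference_is_zero(self, grid):
        d = distance_distribution(make_band(2450.0, 50.0, 0.0, 1.0, grid),
                                  (2.60, 3.05))
        _, delta = distribution_difference(d, d)
        np.testing.assert_allclose(delta, 0.0, atol=1e-15)

    def test_difference_integrates_to_zero(self, grid):
        d1 = distance_distribution(make_band(2430.0, 45.0, 0.0, 1.0, grid),
                                   (2.60, 3.05))
        d2 = distance_distribution(make_band(2470.0, 55.0, 0.0, 1.0, grid),
                                   (2.60, 3.05))
        r, delta = distribution_difference(d1, d2)
        assert abs(np.trapezoid(delta, r)) < 1e-6

    def test_strengthening_signature_sign_pattern(self, grid):
        """Shift to shorter R: ΔP > 0 below the crossing, < 0 above."""
        shifted = distance_distribution(make_band(2430.0, 50.0, 0.0, 1.0, grid),
                                        (2.60, 3.05))
        ref = distance_distribution(make_band(2470.0, 50.0, 0.0, 1.0, grid),
                                    (2.60, 3.05))
        r, delta = distribution_difference(shifted, ref)
        sign_changes = np.flatnonzero(np.diff(np.sign(
            delta[np.abs(delta) > 1e-4]
        )))
        # single crossing: positive lobe at short R, negative at long R
        big = np.abs(delta) > 0.05 * np.abs(delta).max()
        first, last = np.flatnonzero(big)[[0, -1]]
        assert delta[first] > 0 and delta[last] < 0
        assert sign_changes.size == 1
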