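"""Forward model: Beer-Lambert, 2f lineshape, bulk attenuation, acquisitions."""

import math

import numpy as np
import pytest

from gasmasim.environment import Environment
from gasmasim.forward import (
    DEFAULT_H2O_LINE,
    DEFAULT_O2_LINE,
    GasLineModel,
    OpticalProperties,
    beer_lambert_transmission,
    bulk_transmission,
    default_detuning_grid,
    second_harmonic_lineshape,
    simulate_acquisition,
)
from gasmasim.geometry import CapillaryArray


class TestBeerLambert:
    def test_no_absorber_full_transmission(self):
        assert beer_lambert_transmission(5.0, 0.0, 1.0) == 1.0

    def test_half_transmission_closed_form(self):
        assert beer_lambert_transmission(math.log(2), 1.0, 1.0) == pytest.approx(
            0.5, rel=1e-12
        )

    def test_monotone_in_each_argument(self):
        base = beer_lambert_transmission(1.0, 0.1, 0.01)
        assert beer_lambert_transmission(2.0, 0.1, 0.01) < base
        assert beer_lambert_transmission(1.0, 0.2, 0.01) < base
        assert beer_lambert_transmission(1.0, 0.1, 0.02) < base

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            beer_lambert_transmission(-1.0, 0.1, 0.01)


class TestLineshape:
    def test_even_in_detuning(self):
        grid = default_detuning_grid(DEFAULT_O2_LINE)
        profile = second_harmonic_lineshape(DEFAULT_O2_LINE, grid)
        assert profile == pytest.approx(profile[::-1], abs=1e-12)

    def test_normalized_with_positive_centre(self):
        grid = default_detuning_grid(DEFAULT_O2_LINE)
        profile = second_harmonic_lineshape(DEFAULT_O2_LINE, grid)
        assert np.max(np.abs(profile)) == pytest.approx(1.0, abs=1e-9)
        assert profile[len(grid) // 2] == pytest.approx(1.0, abs=1e-9)

    def test_vanishes_in_far_wings(self):
        far = np.array([-200.0, 200.0])
        profile = second_harmonic_lineshape(DEFAULT_O2_LINE, far)
        assert np.all(np.abs(profile) < 1e-3)

    def test_quadrature_matches_brute_force_riemann_sum(self):
        """Fixed-order Gauss-Legendre vs 1e5-point midpoint rule."""
        line = DEFAULT_O2_LINE
        nu = np.linspace(-4.0, 4.0, 9)
        theta = (np.arange(100_000) + 0.5) * math.pi / 100_000
        shift = line.modulation_index * line.halfwidth * np.cos(theta)
        x = nu[:, None] + shift
        lorentz = line.halfwidth**2 / (x**2 + line.halfwidth**2)
        riemann = (2.0 / math.pi) * np.sum(
            lorentz * np.cos(2 * theta), axis=1
        ) * (math.pi / 100_000)
        from gasmasim.forward import _profile_scale, _raw_second_harmonic

        raw = _raw_second_harmonic(nu, line.halfwidth, line.modulation_index)
        assert raw == pytest.approx(riemann, abs=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            second_harmonic_lineshape(DEFAULT_O2_LINE, np.array([]))


class TestBulkTransmission:
    def test_no_crossings_unity(self):
        assert bulk_transmission(0, OpticalProperties(), 1e-3) == 1.0

    def test_effective_attenuation_value(self):
        # sqrt(3 * 0.5 * 5.9) = 2.9748949561287037 1/cm, direct arithmetic
        props = OpticalProperties(mu_a=0.5, mu_s_prime=5.4)
        assert props.mu_eff_per_m == pytest.approx(297.48949561287037, rel=1e-12)

    def test_strictly_decreasing_in_crossings(self):
        props = OpticalProperties()
        values = [bulk_transmission(n, props, 1e-3) for n in range(5)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSimulateAcquisition:
    def test_deterministic_given_seed(self, default_array, default_beam, nominal_env):
        a = simulate_acquisition(default_array, default_beam, nominal_env, seed=17)
        b = simulate_acquisition(default_array, default_beam, nominal_env, seed=17)
        for gas in ("O2", "H2O"):
            assert np.array_equal(a[gas].amplitude, b[gas].amplitude)

    def test_all_filled_no_interstitial_gives_null_trace(
        self, default_beam, nominal_env
    ):
        arr = CapillaryArray(fill_state=[True] * 229)
        scans = simulate_acquisition(
            arr, default_beam, nominal_env, include_interstitial=False, seed=0
        )
        assert np.all(scans["O2"].amplitude == 0.0)
        assert scans["O2"].true_gas_path == 0.0

    def test_noiseless_peak_linear_in_path(
        self, default_array, default_beam, nominal_env
    ):
        """Peak amplitude proportional to absorbance over three decades."""
        peaks = []
        for scale in (0.01, 0.1, 1.0, 10.0):
            scans = simulate_acquisition(
                default_array,
                default_beam,
                nominal_env,
                noise_sd=0.0,
                path_enhancement=scale,
                seed=0,
            )
            peaks.append(np.max(np.abs(scans["O2"].amplitude)) / scale)
        assert np.ptp(peaks) / peaks[0] < 1e-9

    def test_doubling_path_doubles_peak(self, default_array, default_beam, nominal_env):
        one = simulate_acquisition(
            default_array, default_beam, nominal_env, noise_sd=0.0, seed=0
        )
        two = simulate_acquisition(
            default_array, default_beam, nominal_env, noise_sd=0.0,
            path_enhancement=2.0, seed=0,
        )
        assert np.max(two["O2"].amplitude) == pytest.approx(
            2 * np.max(one["O2"].amplitude), rel=1e-12
        )

    def test_transmission_decreases_with_filled_count(
        self, default_beam, nominal_env
    ):
        last = 1.1
        for n_filled in (0, 50, 100, 200):
            arr = CapillaryArray(
                fill_state=[True] * n_filled + [False] * (229 - n_filled)
            )
            scans = simulate_acquisition(arr, default_beam, nominal_env, seed=0)
            assert scans["O2"].transmission < last
            last = scans["O2"].transmission

    def test_invalid_inputs_rejected(self, default_array, default_beam, nominal_env):
        with pytest.raises(ValueError):
            simulate_acquisition(
                default_array, default_beam, nominal_env, o2_true=1.5
            )
        with pytest.raises(ValueError):
            simulate_acquisition(
                default_array, default_beam, nominal_env, noise_sd=-0.1
            )
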