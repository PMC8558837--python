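"""Phantom geometry: volume bookkeeping, test-set construction, ray paths."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gasmasim.geometry import (
    BeamFootprint,
    CapillaryArray,
    DesignError,
    GeometryError,
    beam_average_path,
    config_air_volume,
    generate_test_set,
    geometric_max_path,
    grid_layout,
    interstitial_air_volume,
    ray_gas_path,
    sampled_capillary_air_volume,
    sampling_volume,
)

PER_CAPILLARY = math.pi * (0.25e-3) ** 2 * 0.01  # bore volume, default geometry


class TestVolumes:
    def test_per_capillary_matches_reference(self, default_array, default_beam):
        vol = sampled_capillary_air_volume(default_array, default_beam)
        assert vol == pytest.approx(1.96e-9, rel=5e-3)

    def test_per_capillary_quadratic_in_radius(self, default_beam):
        doubled = CapillaryArray(inner_radius=0.5e-3, outer_radius=0.625e-3)
        base = CapillaryArray()
        assert sampled_capillary_air_volume(doubled, default_beam) == pytest.approx(
            4 * sampled_capillary_air_volume(base, default_beam), rel=1e-12
        )

    @pytest.mark.parametrize(
        "dims, expected",
        [((0.01, 0.014, 0.025), 3.5e-6), ((1.0, 1.0, 1.0), 1.0)],
    )
    def test_sampling_volume(self, dims, expected):
        w, d, l = dims
        beam = BeamFootprint(width=w, depth=d, array_path_length=l)
        assert sampling_volume(beam) == pytest.approx(expected, rel=1e-9)

    def test_sampling_volume_linear_in_each_dimension(self, default_beam):
        half = BeamFootprint(width=default_beam.width / 2)
        assert sampling_volume(half) == pytest.approx(
            sampling_volume(default_beam) / 2, rel=1e-12
        )

    def test_interstitial_matches_reference(self, default_array, default_beam):
        assert interstitial_air_volume(default_array, default_beam) == pytest.approx(
            6.89e-7, rel=5e-3
        )

    def test_interstitial_empty_array_is_full_volume(self, default_beam):
        empty = CapillaryArray(n_capillaries=0, fill_state=())
        assert interstitial_air_volume(empty, default_beam) == pytest.approx(
            sampling_volume(default_beam), rel=1e-12
        )

    def test_interstitial_envelope_overflow_raises(self, default_beam):
        fat = CapillaryArray(inner_radius=0.25e-3, outer_radius=2e-3)
        with pytest.raises(GeometryError, match="envelope"):
            interstitial_air_volume(fat, default_beam)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(GeometryError):
            BeamFootprint(width=0.0)
        with pytest.raises(GeometryError):
            CapillaryArray(inner_radius=-1e-3)

    @pytest.mark.parametrize(
        "n_filled, expected_table",
        [(0, 1.14), (229, 0.69), (29, 1.08)],  # all-air, all-filled, 200 air
    )
    def test_config_air_volume_reference_rows(
        self, default_beam, n_filled, expected_table
    ):
        arr = CapillaryArray(fill_state=[True] * n_filled + [False] * (229 - n_filled))
        assert config_air_volume(arr, default_beam).in_table_units() == expected_table

    @given(n_filled=st.integers(min_value=0, max_value=229))
    def test_volume_conservation(self, n_filled):
        """Air + liquid-filled bores + glass envelope == sampling volume."""
        beam = BeamFootprint()
        arr = CapillaryArray(fill_state=[True] * n_filled + [False] * (229 - n_filled))
        budget = config_air_volume(arr, beam)
        glass = 229 * math.pi * (arr.outer_radius**2 - arr.inner_radius**2) * 0.01
        total = budget.total_air_volume + n_filled * PER_CAPILLARY + glass
        assert total == pytest.approx(sampling_volume(beam), rel=1e-12)

    def test_monotone_decrease_in_exact_steps(self, default_beam):
        arrays = generate_test_set("decreasing_air", seed=7)
        volumes = [config_air_volume(a, default_beam).total_air_volume for a in arrays]
        steps = -np.diff(volumes)
        assert np.all(steps > 0)
        assert steps == pytest.approx([20 * PER_CAPILLARY] * 10, rel=1e-12)


class TestTestSets:
    def test_decreasing_air_filled_counts(self):
        arrays = generate_test_set("decreasing_air", seed=1)
        assert [a.n_filled for a in arrays] == list(range(0, 201, 20))

    def test_increasing_air_counts(self):
        arrays = generate_test_set("increasing_air", seed=1)
        assert [a.n_air for a in arrays] == list(range(0, 201, 20))

    def test_zero_steps_single_configuration(self):
        arrays = generate_test_set("increasing_air", n_steps=0, seed=3)
        assert len(arrays) == 1 and arrays[0].n_filled == 229

    def test_steps_are_nested(self):
        arrays = generate_test_set("decreasing_air", seed=11)
        for prev, nxt in zip(arrays, arrays[1:]):
            converted = {i for i, f in enumerate(prev.fill_state) if f}
            assert converted <= {i for i, f in enumerate(nxt.fill_state) if f}

    def test_same_seed_reproducible(self):
        a = generate_test_set("decreasing_air", seed=42)
        b = generate_test_set("decreasing_air", seed=42)
        assert all(x.fill_state == y.fill_state for x, y in zip(a, b))

    def test_overconversion_rejected(self):
        with pytest.raises(DesignError):
            generate_test_set("decreasing_air", step=30, n_steps=10, seed=0)


class TestGrid:
    def test_default_layout_occupancy(self, default_array):
        layout = grid_layout(default_array)
        assert len(layout) == 229
        cells = set(layout.values())
        assert len(cells) == 229  # bijective
        vacant = {(c, r) for r in range(12) for c in range(20)} - cells
        assert len(vacant) == 11
        # vacancies are the trailing row-major cells
        assert vacant == {(c, 11) for c in range(9, 20)}

    def test_single_capillary_at_origin(self):
        arr = CapillaryArray(n_capillaries=1, fill_state=(False,))
        assert grid_layout(arr)[0] == (0, 0)


class TestRayPath:
    def test_expected_all_air_row_bore_path(self, default_array, default_beam):
        # closed form: 20 cells x hit probability x mean chord
        gas, crossed, _ = ray_gas_path(default_array, default_beam, row=0)
        expected = 20 * 0.4 * (math.pi / 2) * 0.25e-3
        assert gas == pytest.approx(expected, rel=1e-12)
        assert crossed == 0

    def test_all_filled_row(self, default_beam):
        arr = CapillaryArray(fill_state=[True] * 229)
        gas, crossed, _ = ray_gas_path(arr, default_beam, row=0)
        assert gas == 0.0
        assert crossed == pytest.approx(20.0)

    def test_row_out_of_range(self, default_array, default_beam):
        with pytest.raises(GeometryError):
            ray_gas_path(default_array, default_beam, row=12)

    def test_sampled_mode_reproducible(self, default_array, default_beam):
        a = ray_gas_path(default_array, default_beam, 0, mode="sampled", seed=5)
        b = ray_gas_path(default_array, default_beam, 0, mode="sampled", seed=5)
        assert a == b

    def test_monte_carlo_matches_expected_within_one_percent(
        self, default_array, default_beam
    ):
        """Mean of 1e5 sampled rays converges to the analytic expectation."""
        rng = np.random.default_rng(2024)
        offsets = rng.random(100_000)
        gas_sum = inter_sum = 0.0
        for u in offsets:
            gas, _, inter = ray_gas_path(
                default_array, default_beam, 0, offset=float(u), mode="sampled"
            )
            gas_sum += gas
            inter_sum += inter
        exp_gas, _, exp_inter = ray_gas_path(default_array, default_beam, 0)
        assert gas_sum / len(offsets) == pytest.approx(exp_gas, rel=0.01)
        assert inter_sum / len(offsets) == pytest.approx(exp_inter, rel=0.01)

    def test_beam_average_below_geometric_maximum(self, default_array, default_beam):
        path, _ = beam_average_path(default_array, default_beam)
        assert 0 < path <= geometric_max_path(default_array, default_beam)
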