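"""Capillary-array phantom geometry and air-volume bookkeeping.

The phantom is a gridded array of glass capillaries inside a resin holder.
A subset of the capillaries is filled with a liquid tissue-mimicking phantom
(scattering + absorption); the rest hold air and play the role of inflated
alveoli.  The beam samples a rectangular sub-volume of the array; every air
volume reported by this module refers to that sampled region only.

Conventions
-----------
* All lengths in metres, all volumes in cubic metres.
* The capillary grid is row-major: capillary ``i`` sits at column
  ``i % n_columns`` and row ``i // n_columns``; vacant holder cells (the grid
  has more cells than capillaries) are the trailing cells in row-major order.
* Column pitch along the beam is ``array_path_length / n_columns``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "GeometryError",
    "DesignError",
    "CapillaryArray",
    "BeamFootprint",
    "VolumeBudget",
    "sampled_capillary_air_volume",
    "sampling_volume",
    "interstitial_air_volume",
    "config_air_volume",
    "generate_test_set",
    "grid_layout",
    "ray_gas_path",
    "beam_average_path",
    "geometric_max_path",
]


class GeometryError(ValueError):
    """Raised when phantom dimensions are inconsistent or non-physical."""


class DesignError(ValueError):
    """Raised when a test-set design cannot be realised by the array."""


@dataclass(frozen=True)
class CapillaryArray:
    """The gridded capillary phantom and its fill state.

    ``fill_state[i]`` is True when capillary ``i`` is filled with liquid
    phantom and False when it holds air.  Defaults reproduce the physical
    build: 229 capillaries of 0.25 mm bore and 0.625 mm outer radius in a
    20 x 12 grid.
    """

    n_capillaries: int = 229
    inner_radius: float = 0.25e-3
    outer_radius: float = 0.625e-3
    capillary_length: float = 125e-3
    n_columns_along_beam: int = 20
    n_rows: int = 12
    fill_state: tuple[bool, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fill_state is None:
            object.__setattr__(
                self, "fill_state", (False,) * self.n_capillaries
            )
        else:
            object.__setattr__(self, "fill_state", tuple(bool(b) for b in self.fill_state))
        if not (self.outer_radius > self.inner_radius > 0):
            raise GeometryError(
                "require outer_radius > inner_radius > 0, got "
                f"outer={self.outer_radius}, inner={self.inner_radius}"
            )
        if self.capillary_length <= 0:
            raise GeometryError("capillary_length must be positive")
        if self.n_capillaries > self.n_columns_along_beam * self.n_rows:
            raise GeometryError(
                f"{self.n_capillaries} capillaries do not fit a "
                f"{self.n_columns_along_beam} x {self.n_rows} grid"
            )
        if len(self.fill_state) != self.n_capillaries:
            raise GeometryError(
                f"fill_state has {len(self.fill_state)} entries for "
                f"{self.n_capillaries} capillaries"
            )

    @property
    def n_filled(self) -> int:
        return sum(self.fill_state)

    @property
    def n_air(self) -> int:
        return self.n_capillaries - self.n_filled

    def with_fill(self, fill_state) -> "CapillaryArray":
        return replace(self, fill_state=tuple(bool(b) for b in fill_state))


@dataclass(frozen=True)
class BeamFootprint:
    """Beam-sampled region: source/detector footprint and array span.

    width x depth is the cross-section set by the source and detector
    apertures; ``array_path_length`` is the array extent along the beam and
    ``sampled_capillary_length`` the portion of each capillary inside the
    footprint.
    """

    width: float = 0.01
    depth: float = 0.014
    array_path_length: float = 0.025
    sampled_capillary_length: float = 0.01

    def __post_init__(self) -> None:
        for name in ("width", "depth", "array_path_length", "sampled_capillary_length"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"beam footprint field {name!r} must be positive")

    def pitch(self, array: CapillaryArray) -> float:
        """Column pitch along the beam (m)."""
        return self.array_path_length / array.n_columns_along_beam


@dataclass(frozen=True)
class VolumeBudget:
    """Air-volume decomposition of the sampled region."""

    sampling_volume: float
    interstitial_air_volume: float
    per_capillary_air_volume: float
    total_air_volume: float
    n_air_capillaries: int
    n_filled_capillaries: int

    def __post_init__(self) -> None:
        expected = (
            self.interstitial_air_volume
            + self.n_air_capillaries * self.per_capillary_air_volume
        )
        if not math.isclose(self.total_air_volume, expected, rel_tol=1e-12):
            raise GeometryError("air-volume budget does not close")
        if self.total_air_volume > self.sampling_volume * (1 + 1e-12):
            raise GeometryError("total air volume exceeds sampling volume")

    def in_table_units(self) -> float:
        """Total air volume in 1e-6 m3, round-half-even to 2 decimals."""
        return round_table_units(self.total_air_volume)


def round_table_units(volume_m3: float) -> float:
    """Rescale a volume to 1e-6 m3 and round-half-even to two decimals."""
    scaled = volume_m3 * 1e6
    # numpy.round is round-half-even, matching the presentation convention
    return float(np.round(scaled, 2))


def sampled_capillary_air_volume(array: CapillaryArray, beam: BeamFootprint) -> float:
    """Air volume of one capillary bore inside the beam footprint (m3)."""
    if beam.sampled_capillary_length > array.capillary_length:
        raise GeometryError("sampled length exceeds capillary length")
    return math.pi * array.inner_radius**2 * beam.sampled_capillary_length


def sampling_volume(beam: BeamFootprint) -> float:
    """Total sampled volume: beam cross-section times array span (m3)."""
    return beam.width * beam.depth * beam.array_path_length


def interstitial_air_volume(array: CapillaryArray, beam: BeamFootprint) -> float:
    """Air between the capillary envelopes inside the sampled volume (m3).

    Computed as the sampling volume minus the envelope volume of all
    capillaries (outer radius, sampled length); constant across fill states.
    """
    envelope = (
        array.n_capillaries
        * math.pi
        * array.outer_radius**2
        * beam.sampled_capillary_length
    )
    total = sampling_volume(beam)
    if envelope > total * (1 + 1e-12):
        raise GeometryError(
            f"capillary envelope volume {envelope:.3e} m3 exceeds "
            f"sampling volume {total:.3e} m3"
        )
    return total - envelope


def config_air_volume(array: CapillaryArray, beam: BeamFootprint) -> VolumeBudget:
    """Full air-volume budget for one fill configuration."""
    per_cap = sampled_capillary_air_volume(array, beam)
    inter = interstitial_air_volume(array, beam)
    n_air = array.n_air
    return VolumeBudget(
        sampling_volume=sampling_volume(beam),
        interstitial_air_volume=inter,
        per_capillary_air_volume=per_cap,
        total_air_volume=inter + n_air * per_cap,
        n_air_capillaries=n_air,
        n_filled_capillaries=array.n_filled,
    )


Direction = Literal["decreasing_air", "increasing_air"]


def generate_test_set(
    direction: Direction,
    step: int = 20,
    n_steps: int = 10,
    seed: int = 0,
    base: CapillaryArray | None = None,
) -> list[CapillaryArray]:
    """Build the nested fill configurations of one measurement set.

    ``decreasing_air`` starts with every capillary holding air and converts
    ``step`` randomly chosen capillaries to liquid phantom at each step;
    ``increasing_air`` starts all-filled and empties them instead.  Steps are
    cumulative (previously converted capillaries stay converted), mirroring
    the by-hand replacement procedure.  Returns ``n_steps + 1`` arrays.
    """
    if direction not in ("decreasing_air", "increasing_air"):
        raise DesignError(f"unknown direction {direction!r}")
    base = base if base is not None else CapillaryArray(rng_seed=seed)
    if step < 0 or n_steps < 0:
        raise DesignError("step and n_steps must be non-negative")
    if step * n_steps > base.n_capillaries:
        raise DesignError(
            f"cannot convert {step * n_steps} of {base.n_capillaries} capillaries"
        )
    start_filled = direction == "increasing_air"
    fill = np.full(base.n_capillaries, start_filled, dtype=bool)
    rng = np.random.default_rng(seed)
    order = rng.permutation(base.n_capillaries)
    configs = [base.with_fill(fill)]
    for k in range(n_steps):
        converted = order[k * step : (k + 1) * step]
        fill[converted] = not start_filled
        configs.append(base.with_fill(fill))
    return configs


def grid_layout(array: CapillaryArray) -> dict[int, tuple[int, int]]:
    """Deterministic row-major placement: capillary index -> (column, row)."""
    ncols = array.n_columns_along_beam
    return {i: (i % ncols, i // ncols) for i in range(array.n_capillaries)}


def _row_members(array: CapillaryArray, row: int) -> tuple[list[int], int]:
    """Capillary indices occupying ``row`` and the count of vacant cells."""
    ncols = array.n_columns_along_beam
    lo, hi = row * ncols, (row + 1) * ncols
    members = [i for i in range(lo, min(hi, array.n_capillaries))]
    return members, hi - lo - len(members)


def _mean_chord(radius: float, pitch: float) -> float:
    """Mean chord of a circle of ``radius`` over a uniform lateral offset
    spanning one pitch (accounts for rays that miss the circle)."""
    if radius <= 0:
        return 0.0
    a = min(radius, pitch / 2.0)
    area = 2.0 * (a * math.sqrt(max(radius**2 - a**2, 0.0)) + radius**2 * math.asin(a / radius))
    return area / pitch


def ray_gas_path(
    array: CapillaryArray,
    beam: BeamFootprint,
    row: int,
    offset: float | None = None,
    mode: Literal["expected", "sampled"] = "expected",
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Gas path of a straight ray crossing every column cell of one row.

    Returns ``(gas_path_in_air_capillaries, n_filled_crossed,
    interstitial_path)`` in metres (crossings are an expected value, hence a
    float, in ``expected`` mode).  A ray through an air bore accumulates a
    chord ``2 * sqrt(r_in**2 - y**2)`` for lateral offset ``y`` from the
    capillary axis; ``expected`` mode replaces the sampled chord by its
    analytic mean over uniform offsets (mean chord ``(pi/2) r`` times hit
    probability ``2 r / pitch``).  Interstitial path per cell is the pitch
    minus the (expected or sampled) envelope chord; vacant holder cells count
    entirely as interstitial air.
    """
    if not 0 <= row < array.n_rows:
        raise GeometryError(f"row {row} outside grid of {array.n_rows} rows")
    pitch = beam.pitch(array)
    members, n_vacant = _row_members(array, row)
    n_air = sum(1 for i in members if not array.fill_state[i])
    n_filled = len(members) - n_air

    if mode == "expected":
        bore = _mean_chord(array.inner_radius, pitch)
        envelope = _mean_chord(array.outer_radius, pitch)
        p_hit_out = min(1.0, 2.0 * array.outer_radius / pitch)
        gas = n_air * bore
        interstitial = len(members) * (pitch - envelope) + n_vacant * pitch
        crossed = n_filled * p_hit_out
        return gas, crossed, interstitial

    if mode != "sampled":
        raise GeometryError(f"unknown ray mode {mode!r}")
    if offset is None:
        rng = np.random.default_rng(seed)
        offset = float(rng.random())
    if not 0.0 <= offset < 1.0:
        raise GeometryError("offset must lie in [0, 1)")
    y = (offset - 0.5) * pitch
    bore = 2.0 * math.sqrt(array.inner_radius**2 - y**2) if abs(y) < array.inner_radius else 0.0
    env = 2.0 * math.sqrt(array.outer_radius**2 - y**2) if abs(y) < array.outer_radius else 0.0
    gas = n_air * bore
    interstitial = len(members) * (pitch - env) + n_vacant * pitch
    crossed = float(n_filled) if abs(y) < array.outer_radius else 0.0
    return gas, crossed, interstitial


def beam_average_path(
    array: CapillaryArray,
    beam: BeamFootprint,
    include_interstitial: bool = True,
    path_enhancement: float = 1.0,
) -> tuple[float, float]:
    """Beam-averaged gas path and filled-capillary crossings.

    Averages the expected-mode ray over all grid rows.  ``path_enhancement``
    is a single multiplicative stand-in for the scattering-induced path
    lengthening of diffuse light (default 1: straight rays).
    """
    gas_tot = cross_tot = 0.0
    for row in range(array.n_rows):
        gas, crossed, inter = ray_gas_path(array, beam, row, mode="expected")
        gas_tot += gas + (inter if include_interstitial else 0.0)
        cross_tot += crossed
    n = array.n_rows
    return path_enhancement * gas_tot / n, cross_tot / n


def geometric_max_path(array: CapillaryArray, beam: BeamFootprint) -> float:
    """Upper bound on the gas path of any single ray through the array.

    Columns times the maximal bore chord (a ray through every capillary
    centre) plus the maximal interstitial path along the beam.  Inferred
    paths above this bound are physically impossible for the geometry.
    """
    pitch = beam.pitch(array)
    ncols = array.n_columns_along_beam
    max_interstitial = ncols * max(0.0, pitch - 2.0 * array.outer_radius)
    return ncols * 2.0 * array.inner_radius + max_interstitial
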