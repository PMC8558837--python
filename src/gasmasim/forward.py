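"""Synthetic wavelength-modulation-spectroscopy forward model.

Stands in for the bench-top dual O2/H2O instrument: for one capillary
configuration and chamber environment it produces, per gas, a second-harmonic
(2f) amplitude trace over a detuning grid, plus the bulk optical transmission
of the turbid phantom.

Model summary
-------------
* Gas absorbance follows Beer-Lambert, ``A = eps * c * l``, with ``l`` the
  beam-averaged gas path through air-filled bores and interstitial space.
* The 2f trace is the small-absorbance linearisation ``gain * A`` shaped by
  the normalized second Fourier coefficient of a Lorentzian line under
  sinusoidal wavelength modulation (``A << 1`` in every simulated regime, so
  the 2f amplitude is proportional to absorbance).
* Bulk attenuation by phantom-filled capillaries uses the diffusion-theory
  effective attenuation coefficient ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))``.
* Noise is additive zero-mean Gaussian on the trace, scaled to its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np

from .environment import Environment, h2o_volume_fraction
from .geometry import BeamFootprint, CapillaryArray, beam_average_path

__all__ = [
    "GasLineModel",
    "OpticalProperties",
    "WMSScan",
    "beer_lambert_transmission",
    "second_harmonic_lineshape",
    "bulk_transmission",
    "simulate_acquisition",
    "default_detuning_grid",
    "DEFAULT_O2_LINE",
    "DEFAULT_H2O_LINE",
]

#: Detuning grid convention: symmetric, in units of the Lorentzian halfwidth.
GRID_POINTS = 201
GRID_SPAN_HALFWIDTHS = 6.0

_QUAD_ORDER = 64
_NORM_GRID_POINTS = 2001


@dataclass(frozen=True)
class GasLineModel:
    """One gas line as seen by the instrument.

    ``effective_absorptivity`` plays the role of the molar absorptivity folded
    with line strength and pressure broadening: absorbance per unit
    concentration fraction per metre of gas path.  ``wms_gain`` is the
    instrument calibration constant mapping absorbance to 2f amplitude in
    instrument units; forward and inverse modules share the same line model,
    so parameter recovery tests self-consistency, not absolute spectroscopy.
    """

    gas: Literal["O2", "H2O"]
    effective_absorptivity: float
    halfwidth: float = 1.0
    line_center_detuning: float = 0.0
    modulation_index: float = 2.2
    wms_gain: float = 1000.0

    def __post_init__(self) -> None:
        if self.effective_absorptivity <= 0:
            raise ValueError("effective_absorptivity must be positive")
        if self.halfwidth <= 0 or self.wms_gain <= 0 or self.modulation_index <= 0:
            raise ValueError("halfwidth, wms_gain and modulation_index must be positive")


#: Order-of-magnitude placeholder lines (the real instrument calibration is
#: proprietary); chosen so both gases sit at comparable, small absorbances.
DEFAULT_O2_LINE = GasLineModel(gas="O2", effective_absorptivity=1.0)
DEFAULT_H2O_LINE = GasLineModel(gas="H2O", effective_absorptivity=4.0)


@dataclass(frozen=True)
class OpticalProperties:
    """Turbid-phantom optics at the working wavelength (cgs units, 1/cm)."""

    mu_a: float = 0.50
    mu_s_prime: float = 5.4
    g: float = 0.6

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_prime < 0:
            raise ValueError("mu_a and mu_s_prime must be non-negative")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy g must lie in [0, 1)")

    @property
    def mu_eff_per_m(self) -> float:
        """Diffusion-theory effective attenuation, converted to 1/m."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime)) * 100.0


@dataclass(frozen=True)
class WMSScan:
    """One simulated 2f acquisition for one gas."""

    gas: str
    detuning_grid: np.ndarray
    amplitude: np.ndarray
    transmission: float
    environment_used: Environment
    true_gas_path: float  # m; ground truth carried for testing only

    def __post_init__(self) -> None:
        if len(self.detuning_grid) != len(self.amplitude):
            raise ValueError("detuning grid and amplitude trace differ in length")
        if not 0.0 < self.transmission <= 1.0:
            raise ValueError("transmission must lie in (0, 1]")


def beer_lambert_transmission(absorptivity: float, concentration: float, path: float) -> float:
    """Intensity ratio I/I0 = exp(-eps * c * l)."""
    if absorptivity < 0 or concentration < 0 or path < 0:
        raise ValueError("Beer-Lambert arguments must be non-negative")
    return math.exp(-absorptivity * concentration * path)


def default_detuning_grid(line: GasLineModel, n: int = GRID_POINTS) -> np.ndarray:
    """Symmetric detuning grid spanning +/- 6 halfwidths around line centre."""
    half = GRID_SPAN_HALFWIDTHS * line.halfwidth
    return line.line_center_detuning + np.linspace(-half, half, n)


@lru_cache(maxsize=32)
def _gauss_legendre_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(order)
    # map [-1, 1] -> [0, pi]
    return (x + 1.0) * (math.pi / 2.0), w * (math.pi / 2.0)


def _raw_second_harmonic(
    nu: np.ndarray, halfwidth: float, modulation_index: float, order: int = _QUAD_ORDER
) -> np.ndarray:
    """Unnormalized 2nd Fourier coefficient of the peak-normalized Lorentzian
    under sinusoidal modulation, by fixed-order Gauss-Legendre quadrature:
    ``(2/pi) * integral_0^pi L(nu + m*g*cos(theta)) cos(2 theta) d theta``.
    """
    theta, w = _gauss_legendre_nodes(order)
    shift = modulation_index * halfwidth * np.cos(theta)
    x = np.asarray(nu, dtype=float)[..., None] + shift
    lorentz = halfwidth**2 / (x**2 + halfwidth**2)
    return (2.0 / math.pi) * np.sum(lorentz * np.cos(2.0 * theta) * w, axis=-1)


@lru_cache(maxsize=64)
def _profile_scale(halfwidth: float, modulation_index: float, center: float) -> float:
    """Normalization constant: max |2f profile| over a dense detuning grid.

    The raw 2f coefficient is negative at line centre (the absorbance dip is
    concave there); the profile is flipped so the centre lobe is positive,
    matching how instruments display 2f signals.
    """
    half = GRID_SPAN_HALFWIDTHS * halfwidth
    dense = center + np.linspace(-half, half, _NORM_GRID_POINTS)
    raw = _raw_second_harmonic(dense - center, halfwidth, modulation_index)
    return float(np.max(np.abs(raw)))


def second_harmonic_lineshape(line: GasLineModel, detuning_grid: np.ndarray) -> np.ndarray:
    """Normalized 2f lineshape on ``detuning_grid`` (max |value| = 1, centre
    lobe positive)."""
    grid = np.asarray(detuning_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("detuning grid is empty")
    raw = _raw_second_harmonic(
        grid - line.line_center_detuning, line.halfwidth, line.modulation_index
    )
    scale = _profile_scale(line.halfwidth, line.modulation_index, line.line_center_detuning)
    return -raw / scale


def bulk_transmission(
    n_filled_crossed: float, props: OpticalProperties, chord: float
) -> float:
    """Diffuse transmission factor after crossing phantom-filled capillaries.

    ``exp(-mu_eff * n * chord)`` with ``n`` the (possibly fractional,
    beam-averaged) number of filled capillaries crossed and ``chord`` the
    mean chord per crossing.
    """
    if n_filled_crossed < 0:
        raise ValueError("n_filled_crossed must be non-negative")
    if chord < 0:
        raise ValueError("chord must be non-negative")
    return math.exp(-props.mu_eff_per_m * n_filled_crossed * chord)


def simulate_acquisition(
    array: CapillaryArray,
    beam: BeamFootprint,
    env: Environment,
    lines: tuple[GasLineModel, GasLineModel] = (DEFAULT_O2_LINE, DEFAULT_H2O_LINE),
    props: OpticalProperties = OpticalProperties(),
    noise_sd: float = 0.03,
    o2_true: float = 0.209,
    seed: int = 0,
    include_interstitial: bool = True,
    path_enhancement: float = 1.0,
) -> dict[str, WMSScan]:
    """Simulate one dual-gas acquisition; returns ``{"O2": scan, "H2O": scan}``.

    The true gas path is the beam average of the expected-mode ray over all
    grid rows (air bores plus, by default, interstitial space).  Per gas the
    noiseless trace is ``wms_gain * eps * c * l`` times the normalized 2f
    profile; zero-mean Gaussian noise with sd ``noise_sd`` times the trace
    maximum is added.  Bulk transmission uses the beam-averaged count of
    phantom-filled capillaries crossed and the mean envelope chord.
    """
    if not 0.0 <= o2_true <= 1.0:
        raise ValueError("o2_true must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    path, crossings = beam_average_path(
        array, beam, include_interstitial=include_interstitial,
        path_enhancement=path_enhancement,
    )
    mean_envelope_chord = (math.pi / 2.0) * array.outer_radius
    transmission = bulk_transmission(crossings, props, mean_envelope_chord)

    concentrations = {"O2": o2_true, "H2O": h2o_volume_fraction(env)}
    rng = np.random.default_rng(seed)
    scans: dict[str, WMSScan] = {}
    for line in lines:
        c = concentrations[line.gas]
        grid = default_detuning_grid(line)
        profile = second_harmonic_lineshape(line, grid)
        clean = line.wms_gain * line.effective_absorptivity * c * path * profile
        peak = float(np.max(np.abs(clean)))
        noise = rng.normal(0.0, noise_sd * peak, size=grid.size) if noise_sd > 0 and peak > 0 else 0.0
        scans[line.gas] = WMSScan(
            gas=line.gas,
            detuning_grid=grid,
            amplitude=clean + noise,
            transmission=transmission,
            environment_used=env,
            true_gas_path=path,
        )
    return scans
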