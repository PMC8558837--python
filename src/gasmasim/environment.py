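"""Chamber environment: water-vapor psychrometrics and drift.

Water vapor serves as the reference gas of the two-wavelength measurement:
its concentration in the sampled air follows from temperature, relative
humidity and pressure alone.  Saturation pressure uses the Arden Buck
equation with its pressure enhancement factor; the mole (volume) fraction
then follows from the ideal gas law as partial pressure over total pressure.

Units are fixed across the module: temperature in degrees Celsius, pressure
in hectopascal, relative humidity in percent.  Conversions happen at the
boundary, never inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Environment",
    "DriftModel",
    "InvalidEnvironmentError",
    "buck_saturation_pressure",
    "h2o_volume_fraction",
    "h2o_number_density",
    "sample_environment",
]

#: Pole of the Buck exponent denominator (deg C); the formula is undefined at
#: and below this temperature.
BUCK_POLE_C = -240.97

#: Boltzmann constant, J/K (CODATA exact).
K_BOLTZMANN = 1.380649e-23

STANDARD_PRESSURE_HPA = 1013.25


class InvalidEnvironmentError(ValueError):
    """Raised for environments outside the model's domain."""


@dataclass(frozen=True)
class Environment:
    """Chamber state: temperature (deg C), relative humidity (%), pressure (hPa)."""

    temperature: float = 37.0
    relative_humidity: float = 92.0
    pressure: float = STANDARD_PRESSURE_HPA

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise InvalidEnvironmentError(
                f"relative_humidity must be in [0, 100] %, got {self.relative_humidity}"
            )
        if self.pressure <= 0:
            raise InvalidEnvironmentError(f"pressure must be positive, got {self.pressure}")
        if self.temperature <= BUCK_POLE_C:
            raise InvalidEnvironmentError(
                f"temperature must exceed {BUCK_POLE_C} degC, got {self.temperature}"
            )


@dataclass(frozen=True)
class DriftModel:
    """Uniform, independent per-acquisition wander of chamber T and RH.

    Defaults reproduce the instability observed in the chamber during the
    air-reduction measurement set: RH oscillating between 90% and 94% due to
    condensation, dragging temperature between 36 and 39 deg C.
    """

    temperature_range: tuple[float, float] = (36.0, 39.0)
    rh_range: tuple[float, float] = (90.0, 94.0)
    enabled: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        tlo, thi = self.temperature_range
        rlo, rhi = self.rh_range
        if tlo > thi or rlo > rhi:
            raise InvalidEnvironmentError("drift ranges must be ordered (lo <= hi)")
        # both endpoints must themselves be valid environments
        Environment(temperature=tlo, relative_humidity=rlo)
        Environment(temperature=thi, relative_humidity=rhi)


def buck_saturation_pressure(env: Environment) -> float:
    """Saturation partial pressure of water vapor in moist air, hPa.

    Arden Buck form with the weak total-pressure enhancement factor:
    ``[1.0007 + 3.46e-6 P] * 6.1121 * exp(17.502 T / (240.97 + T))`` with T
    in deg C and P in hPa.  At 37 deg C and 1 atm this gives ~63.1 hPa
    (~62.8 hPa without the enhancement factor).
    """
    t, p = env.temperature, env.pressure
    if t <= BUCK_POLE_C:
        raise InvalidEnvironmentError(f"temperature {t} degC at or below Buck pole")
    enhancement = 1.0007 + 3.46e-6 * p
    return enhancement * 6.1121 * math.exp(17.502 * t / (240.97 + t))


def h2o_volume_fraction(env: Environment) -> float:
    """Mole/volume fraction of water vapor in the sampled air (dimensionless).

    Ideal-gas ratio of the vapor partial pressure (RH times saturation
    pressure) to total pressure.
    """
    return (env.relative_humidity / 100.0) * buck_saturation_pressure(env) / env.pressure


def h2o_number_density(env: Environment) -> float:
    """Water-vapor number density, molecules per m3 (ideal gas law)."""
    partial_pa = (env.relative_humidity / 100.0) * buck_saturation_pressure(env) * 100.0
    t_kelvin = env.temperature + 273.15
    return partial_pa / (K_BOLTZMANN * t_kelvin)


def sample_environment(
    drift: DriftModel, nominal: Environment, acquisition_index: int
) -> Environment:
    """Environment actually present during one acquisition.

    With drift disabled the nominal environment is returned unchanged.  With
    drift enabled, temperature and RH are drawn independently and uniformly
    over the configured ranges, seeded by ``rng_seed + acquisition_index`` so
    each acquisition is reproducible in isolation.
    """
    if not drift.enabled:
        return nominal
    rng = np.random.default_rng(drift.rng_seed + acquisition_index)
    t = rng.uniform(*drift.temperature_range)
    rh = rng.uniform(*drift.rh_range)
    return Environment(temperature=float(t), relative_humidity=float(rh), pressure=nominal.pressure)
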