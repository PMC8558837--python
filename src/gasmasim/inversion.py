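"""Two-wavelength Beer-Lambert inversion and physical-consistency QC.

The inference chain mirrors how gas-in-scattering-media measurements are
evaluated: water vapor, whose concentration is known from chamber
temperature, humidity and pressure, serves as the reference gas.  The H2O
peak fixes the gas absorption path length ``l``; that path, assumed equal at
the spectrally close O2 wavelength, converts the O2 peak into an O2
concentration.  A record whose inferred path exceeds what the geometry can
possibly provide is flagged and excluded from summaries — the same rule under
which an anomalously absorbing configuration was dropped from the bench
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .environment import Environment, h2o_volume_fraction
from .forward import GasLineModel, WMSScan
from .geometry import BeamFootprint, CapillaryArray, geometric_max_path

__all__ = [
    "AcquisitionRecord",
    "UnrecoverablePathError",
    "InconsistentSignalError",
    "QC_OK",
    "QC_PATH_EXCEEDS_GEOMETRY",
    "peak_amplitude",
    "infer_path_length",
    "infer_o2",
    "qc_check",
    "invert_acquisition",
]

QC_OK = "ok"
QC_PATH_EXCEEDS_GEOMETRY = "path_exceeds_geometry"


class UnrecoverablePathError(ValueError):
    """Path length cannot be inferred: the reference-gas concentration is
    zero (dry air) — humidity is what makes the method work."""


class InconsistentSignalError(ValueError):
    """Nonzero gas signal with zero inferred path: physically inconsistent."""


@dataclass(frozen=True)
class AcquisitionRecord:
    """Per-acquisition inversion result."""

    config_id: tuple[str, int]  # (set label, n_filled)
    replicate: int
    peak_o2: float
    peak_h2o: float
    transmission: float
    inferred_path: float  # m
    inferred_o2: float  # fraction
    qc_flag: str = QC_OK
    true_path: float = float("nan")
    true_o2: float = float("nan")

    def __post_init__(self) -> None:
        if self.inferred_path < 0 or self.inferred_o2 < 0:
            raise ValueError("inferred path and concentration must be non-negative")
        if self.qc_flag not in (QC_OK, QC_PATH_EXCEEDS_GEOMETRY):
            raise ValueError(f"unknown qc_flag {self.qc_flag!r}")


def peak_amplitude(scan: WMSScan) -> float:
    """Maximum absolute 2f amplitude over the detuning grid."""
    amp = np.asarray(scan.amplitude, dtype=float)
    if amp.size == 0:
        raise ValueError("empty amplitude trace")
    return float(np.max(np.abs(amp)))


def infer_path_length(peak_h2o: float, line_h2o: GasLineModel, env: Environment) -> float:
    """Gas absorption path length (m) from the H2O 2f peak.

    Linearized Beer-Lambert inversion: ``l = peak / (gain * eps * c_H2O)``
    with the water concentration computed from the *assumed* environment —
    a mismatch between assumed and actual chamber state propagates
    reciprocally into the path, which is the intended error mechanism of the
    drift emulation.
    """
    if peak_h2o < 0:
        raise ValueError("peak amplitude must be non-negative")
    c = h2o_volume_fraction(env)
    if c <= 0:
        raise UnrecoverablePathError(
            "H2O concentration is zero (RH=0): path length unrecoverable; "
            "the method requires high humidity"
        )
    return peak_h2o / (line_h2o.wms_gain * line_h2o.effective_absorptivity * c)


def infer_o2(peak_o2: float, line_o2: GasLineModel, path: float) -> float:
    """O2 volume fraction from its 2f peak and the inferred path (m)."""
    if peak_o2 < 0:
        raise ValueError("peak amplitude must be non-negative")
    if path == 0:
        if peak_o2 > 0:
            raise InconsistentSignalError("nonzero O2 signal with zero gas path")
        return 0.0
    if path < 0:
        raise ValueError("path must be non-negative")
    return peak_o2 / (line_o2.wms_gain * line_o2.effective_absorptivity * path)


def qc_check(
    record: AcquisitionRecord,
    array: CapillaryArray,
    beam: BeamFootprint,
    multiplier: float = 1.0,
) -> AcquisitionRecord:
    """Flag records whose inferred path exceeds the geometric maximum.

    ``multiplier`` scales the threshold (default 1: no safety margin).
    Flagged records stay in the output but are excluded from summaries.
    """
    limit = multiplier * geometric_max_path(array, beam)
    flag = QC_PATH_EXCEEDS_GEOMETRY if record.inferred_path > limit else QC_OK
    return replace(record, qc_flag=flag)


def invert_acquisition(
    scans: dict[str, WMSScan],
    line_o2: GasLineModel,
    line_h2o: GasLineModel,
    assumed_env: Environment,
    array: CapillaryArray,
    beam: BeamFootprint,
    config_id: tuple[str, int],
    replicate: int = 0,
    qc_multiplier: float = 1.0,
    o2_true: float = float("nan"),
) -> AcquisitionRecord:
    """Full inversion of one dual-gas acquisition, including QC."""
    p_o2 = peak_amplitude(scans["O2"])
    p_h2o = peak_amplitude(scans["H2O"])
    path = infer_path_length(p_h2o, line_h2o, assumed_env)
    conc = infer_o2(p_o2, line_o2, path)
    record = AcquisitionRecord(
        config_id=config_id,
        replicate=replicate,
        peak_o2=p_o2,
        peak_h2o=p_h2o,
        transmission=scans["O2"].transmission,
        inferred_path=path,
        inferred_o2=conc,
        true_path=scans["O2"].true_gas_path,
        true_o2=o2_true,
    )
    return qc_check(record, array, beam, multiplier=qc_multiplier)
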