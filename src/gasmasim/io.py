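"""Deterministic CSV writers/readers shared by the CLI subcommands.

Every output starts with ``#``-prefixed header comments carrying the config
hash and master seed, so any table can be traced back to the run that
produced it.  Floats are written at 6 significant digits; row and column
order are fixed, so identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .environment import Environment
from .forward import WMSScan
from .inversion import AcquisitionRecord
from .experiment import records_to_frame

__all__ = [
    "write_table",
    "write_records",
    "write_summary",
    "write_scans",
    "write_manifest",
    "read_manifest",
    "read_scans",
]

_FLOAT_FMT = "%.6g"


def _format_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: _FLOAT_FMT % v)
    return out


def write_table(
    frame: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> Path:
    """Write a DataFrame as CSV with ``# key=value`` header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        with path.open("w", newline="") as fh:
            for key, value in (meta or {}).items():
                fh.write(f"# {key}={value}\n")
            _format_frame(frame).to_csv(fh, index=False)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc
    return path


def write_records(
    records: Sequence[AcquisitionRecord],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> Path:
    """Acquisition records as CSV, one row per acquisition, fixed columns."""
    return write_table(records_to_frame(list(records)), path, meta)


def write_summary(
    summary: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> Path:
    return write_table(summary, path, meta)


def write_scans(
    scans: Mapping[str, WMSScan], path: str | Path, meta: Mapping[str, object] | None = None
) -> Path:
    """One acquisition's 2f traces: columns gas, detuning, amplitude."""
    frames = [
        pd.DataFrame(
            {"gas": scan.gas, "detuning": scan.detuning_grid, "amplitude": scan.amplitude}
        )
        for scan in scans.values()
    ]
    return write_table(pd.concat(frames, ignore_index=True), path, meta)


def write_manifest(rows: Sequence[Mapping[str, object]], path: str | Path,
                   meta: Mapping[str, object] | None = None) -> Path:
    """Acquisition manifest: one row per acquisition with its provenance."""
    columns = [
        "acquisition_id", "test_set", "n_filled", "replicate", "seed",
        "temperature_c", "rh_percent", "transmission", "true_path_m", "scan_file",
    ]
    frame = pd.DataFrame(list(rows))[columns]
    return write_table(frame, path, meta)


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_manifest(path: str | Path) -> pd.DataFrame:
    return _read_csv(path)


def read_scans(scan_path: str | Path, manifest_row: Mapping[str, object]) -> dict[str, WMSScan]:
    """Rebuild the per-gas scans of one acquisition from its CSV + manifest."""
    frame = _read_csv(scan_path)
    env = Environment(
        temperature=float(manifest_row["temperature_c"]),
        relative_humidity=float(manifest_row["rh_percent"]),
    )
    scans: dict[str, WMSScan] = {}
    for gas, sub in frame.groupby("gas", sort=True):
        scans[str(gas)] = WMSScan(
            gas=str(gas),
            detuning_grid=sub["detuning"].to_numpy(),
            amplitude=sub["amplitude"].to_numpy(),
            transmission=float(manifest_row["transmission"]),
            environment_used=env,
            true_gas_path=float(manifest_row["true_path_m"]),
        )
    return scans
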