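"""CSV/JSON readers and writers for the documented file dialects.

Waveform CSV: columns ``time_ms`` plus exactly one of ``voltage_mV``,
``current_pA`` or ``ca_uM``; header mandatory, decimal point, no
thousands separators.  Sweeps CSV (noise analysis): ``time_ms`` plus
``sweep_001``, ``sweep_002``, ...  Every command of the CLI writes a
JSON provenance record alongside its outputs.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError
from .qmatrix import Waveform
from .variance import EnsembleSweeps

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "write_provenance",
    "load_json_config",
]

_VALUE_COLUMNS = {"voltage_mV": "voltage", "current_pA": "current", "ca_uM": "calcium"}


def read_waveform_csv(path: str | Path) -> Waveform:
    """Read a waveform table; the value column determines the quantity."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as CSV ({exc})") from exc
    if "time_ms" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_ms'")
    value_cols = [c for c in df.columns if c in _VALUE_COLUMNS]
    if len(value_cols) != 1:
        extra = [c for c in df.columns if c != "time_ms"]
        raise FormatError(
            f"{path}: expected exactly one of {sorted(_VALUE_COLUMNS)} beside "
            f"'time_ms', found {extra}"
        )
    col = value_cols[0]
    t = df["time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: 'time_ms' must be strictly increasing (no duplicates)")
    return Waveform(t, df[col].to_numpy(dtype=float), _VALUE_COLUMNS[col])


def write_waveform_csv(wf: Waveform, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_ms": wf.t, wf.column_name: wf.y}).to_csv(path, index=False, float_format="%.17g")
    return path


def read_sweeps_csv(path: str | Path) -> EnsembleSweeps:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_ms" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_ms'")
    sweep_cols = [c for c in df.columns if c.startswith("sweep_")]
    if len(sweep_cols) < 2:
        raise FormatError(f"{path}: need >= 2 'sweep_###' columns, found {len(sweep_cols)}")
    t = df["time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: 'time_ms' must be strictly increasing")
    return EnsembleSweeps(t, df[sweep_cols].to_numpy(dtype=float))


def write_sweeps_csv(s: EnsembleSweeps, path: str | Path) -> Path:
    path = Path(path)
    cols = {"time_ms": s.t}
    for j in range(s.n_sweeps):
        cols[f"sweep_{j + 1:03d}"] = s.sweeps[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


def load_json_config(path: str | Path, required: tuple[str, ...] = ()) -> dict:
    """Load a JSON configuration object, checking required top-level keys."""
    path = Path(path)
    try:
        cfg = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top-level JSON value must be an object")
    missing = [k for k in required if k not in cfg]
    if missing:
        raise FormatError(f"{path}: missing required key(s) {missing}")
    return cfg


def write_provenance(
    path: str | Path, command: str, inputs: dict, parameters: dict, seed: int | None
) -> Path:
    """Write the JSON provenance record every CLI run emits."""
    record = {
        "command": command,
        "package": "bksensor",
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "inputs": inputs,
        "parameters": parameters,
    }
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, default=_jsonable) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
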