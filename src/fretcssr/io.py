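"""Reading traces, writing machines, and configuration round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DataFormatError
from .machine import CausalStateMachine, Trace
from .pipeline import PipelineConfig

__all__ = [
    "read_trace",
    "write_machine",
    "read_machine",
    "save_config",
    "load_config",
]

_TIME_JITTER_TOL = 0.01  # relative jitter allowed in a time column


def read_trace(path: str | Path, dt: float | None = None) -> Trace:
    """Read a delimited text trace.

    One column: values only, ``dt`` required.  Two columns: ``(time, value)``
    pairs with ``dt`` inferred from the (uniform) time steps; more than 1%
    step jitter is rejected.  Lines starting with ``#`` are comments; blank
    lines are skipped.  Whitespace and commas both delimit.
    """
    path = Path(path)
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.replace(",", " ").split()
        try:
            row = [float(x) for x in parts]
        except ValueError:
            raise DataFormatError(f"{path}:{lineno}: non-numeric row {line!r}") from None
        if len(row) not in (1, 2):
            raise DataFormatError(
                f"{path}:{lineno}: expected 1 or 2 columns, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise DataFormatError(f"{path}: no data rows")
    ncol = {len(r) for r in rows}
    if len(ncol) != 1:
        raise DataFormatError(f"{path}: mixed column counts {sorted(ncol)}")
    arr = np.asarray(rows)
    if arr.shape[1] == 1:
        if dt is None:
            raise ConfigurationError(
                f"{path}: single-column trace needs an explicit dt"
            )
        return Trace(arr[:, 0], dt=dt)
    times, values = arr[:, 0], arr[:, 1]
    steps = np.diff(times)
    if len(steps) == 0:
        raise DataFormatError(f"{path}: need at least two rows to infer dt")
    mean_step = float(steps.mean())
    if mean_step <= 0:
        raise DataFormatError(f"{path}: time column is not increasing")
    if np.max(np.abs(steps - mean_step)) > _TIME_JITTER_TOL * mean_step:
        raise DataFormatError(
            f"{path}: non-uniform time steps (jitter beyond "
            f"{100 * _TIME_JITTER_TOL:.0f}% of the mean step {mean_step:.4g})"
        )
    if dt is not None and abs(dt - mean_step) > _TIME_JITTER_TOL * mean_step:
        raise ConfigurationError(
            f"{path}: explicit dt={dt} disagrees with time column step {mean_step:.4g}"
        )
    return Trace(values, dt=mean_step)


def write_machine(machine: CausalStateMachine, path: str | Path, format: str = "json") -> None:
    """Write a machine as JSON (lossless) or GraphViz DOT (for figures)."""
    path = Path(path)
    if format == "json":
        path.write_text(machine.to_json() + "\n")
    elif format == "dot":
        path.write_text(machine.to_dot())
    else:
        raise ConfigurationError(f"unknown machine format {format!r}")


def read_machine(path: str | Path) -> CausalStateMachine:
    try:
        return CausalStateMachine.from_json(Path(path).read_text())
    except (json.JSONDecodeError, KeyError) as exc:
        raise DataFormatError(f"{path}: not a valid machine JSON ({exc})") from exc


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise DataFormatError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig.from_dict(d)
    except TypeError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
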