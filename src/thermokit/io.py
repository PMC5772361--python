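"""Delimited-text trace formats with YAML metadata sidecars.

Each trace is a tab-separated file whose header names carry the units
(``time_s``, ``current_nA``, ``voltage_mV``, ``temp_C``, ``F_au``,
``position_cm``), accompanied by a ``<name>.meta.yaml`` sidecar holding the
trace kind and the non-columnar metadata (sample rate, construct or
genotype, chamber length, generator seed).  Plain text keeps recordings
inspectable and diff-able; converters from binary electrophysiology formats
are a plausible extension, not core.

Writing uses a fixed number format so that read -> write round-trips are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import PositionTrace
from .calcium import FluorescenceTrace
from .biophysics import SolutionComposition
from .tevc import TEVCTrace

__all__ = [
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "read_solutions",
    "write_solutions",
]

_FLOAT_FMT = "%.10g"

_COLUMNS = {
    "tevc": ["time_s", "current_nA", "voltage_mV", "temp_C"],
    "calcium": ["time_s", "F_au", "temp_C"],
    "position": ["time_s", "position_cm", "temp_C"],
}


class TraceFormatError(ValueError):
    """A trace file violates the format contract (named with line numbers)."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.yaml") if path.suffix else path.with_name(path.name + ".meta.yaml")


def _check_monotone_time(time: np.ndarray, path: Path) -> None:
    bad = np.flatnonzero(np.diff(time) <= 0)
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        row = int(bad[0]) + 2 + 1
        raise TraceFormatError(
            f"{path}: time reverses or repeats at data row {row} "
            f"(t={time[bad[0] + 1]!r} after t={time[bad[0]]!r})"
        )


def write_trace(trace, path: str | Path) -> Path:
    """Write a typed trace and its metadata sidecar; returns the data path."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if isinstance(trace, TEVCTrace):
        kind = "tevc"
        frame = pd.DataFrame(
            {
                "time_s": trace.time_s,
                "current_nA": trace.current_nA,
                "voltage_mV": trace.voltage_mV,
                "temp_C": trace.temperature_C,
            }
        )
        meta = {"kind": kind, "sample_rate_hz": trace.sample_rate_hz, **trace.metadata}
    elif isinstance(trace, FluorescenceTrace):
        kind = "calcium"
        frame = pd.DataFrame(
            {"time_s": trace.time_s, "F_au": trace.fluorescence, "temp_C": trace.temperature_C}
        )
        meta = {
            "kind": kind,
            "frame_interval_s": trace.frame_interval_s,
            "roi_id": trace.roi_id,
            "genotype": trace.genotype,
            **trace.metadata,
        }
    elif isinstance(trace, PositionTrace):
        kind = "position"
        frame = pd.DataFrame(
            {"time_s": trace.time_s, "position_cm": trace.position_cm, "temp_C": trace.temperature_C}
        )
        meta = {
            "kind": kind,
            "fly_id": trace.fly_id,
            "genotype": trace.genotype,
            "chamber_length_cm": trace.chamber_length_cm,
            **trace.metadata,
        }
    else:
        raise TraceFormatError(f"unsupported trace type {type(trace).__name__}")

    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_trace(path: str | Path, kind: str | None = None):
    """Read a trace file back into its typed container.

    ``kind`` ("tevc" | "calcium" | "position") is taken from the sidecar
    when omitted.  Missing columns, unit-mismatched headers, and
    non-monotone time raise :class:`TraceFormatError` naming the offending
    column or row.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"{path}: no such file")
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    if kind is None:
        kind = meta.get("kind")
    if kind not in _COLUMNS:
        raise TraceFormatError(
            f"{path}: unknown or missing trace kind {kind!r}; expected one of "
            f"{sorted(_COLUMNS)}"
        )

    frame = pd.read_csv(path, sep="\t")
    expected = _COLUMNS[kind]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise TraceFormatError(
            f"{path}: header is missing required columns {missing} "
            f"(units are enforced through the header names; found "
            f"{list(frame.columns)})"
        )
    time = frame["time_s"].to_numpy(dtype=float)
    _check_monotone_time(time, path)

    if kind == "tevc":
        sample_rate = meta.get("sample_rate_hz")
        if sample_rate is None:
            dt = np.median(np.diff(time)) if time.size > 1 else 1.0
            sample_rate = 1.0 / dt
        extra = {k: v for k, v in meta.items() if k not in ("kind", "sample_rate_hz")}
        return TEVCTrace(
            time,
            frame["current_nA"].to_numpy(dtype=float),
            frame["voltage_mV"].to_numpy(dtype=float),
            frame["temp_C"].to_numpy(dtype=float),
            float(sample_rate),
            metadata=extra,
        )
    if kind == "calcium":
        frame_interval = meta.get("frame_interval_s")
        if frame_interval is None:
            frame_interval = float(np.median(np.diff(time))) if time.size > 1 else 1.0
        extra = {
            k: v
            for k, v in meta.items()
            if k not in ("kind", "frame_interval_s", "roi_id", "genotype")
        }
        return FluorescenceTrace(
            time,
            frame["F_au"].to_numpy(dtype=float),
            frame["temp_C"].to_numpy(dtype=float),
            float(frame_interval),
            roi_id=str(meta.get("roi_id", "roi0")),
            genotype=str(meta.get("genotype", "control")),
            metadata=extra,
        )
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("kind", "fly_id", "genotype", "chamber_length_cm")
    }
    return PositionTrace(
        time,
        frame["position_cm"].to_numpy(dtype=float),
        frame["temp_C"].to_numpy(dtype=float),
        fly_id=str(meta.get("fly_id", "fly0")),
        genotype=str(meta.get("genotype", "control")),
        chamber_length_cm=float(meta.get("chamber_length_cm", 3.4)),
        metadata=extra,
    )


def write_solutions(solutions: dict[str, SolutionComposition], path: str | Path) -> Path:
    """Serialize solution compositions as a structured YAML block."""
    path = Path(path)
    payload = {
        name: {
            "concentrations_mM": dict(sol.concentrations_mM),
            "temperature_C": sol.temperature_C,
        }
        for name, sol in solutions.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_solutions(path: str | Path) -> dict[str, SolutionComposition]:
    path = Path(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    out = {}
    for name, block in payload.items():
        try:
            out[name] = SolutionComposition(
                name,
                {str(i): float(c) for i, c in block["concentrations_mM"].items()},
                float(block.get("temperature_C", 22.0)),
            )
        except (KeyError, TypeError) as exc:
            raise TraceFormatError(f"{path}: malformed solution block {name!r}") from exc
    return out
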