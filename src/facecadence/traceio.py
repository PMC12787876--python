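"""Trace-file dialect: versioned CSV for landmark time series.

Layout: UTF-8, comma-delimited, dot decimals. Two leading comment lines
carry the format version and metadata::

    # facetrace v1
    # sample_rate=30 config=<hash>
    frame_index,time_s,nose_y,yaw_deg,tracked
    0,0.000000,1.234,-2.5,1

``yaw_deg`` and ``tracked`` are optional columns; a missing ``yaw_deg``
means the recording has no orientation channel, a missing ``tracked``
means every frame was tracked. Malformed files are rejected with the
offending line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .trace import LandmarkTrace

__all__ = ["read_trace", "write_trace", "TraceFormatError"]

_MAGIC = "# facetrace v1"


class TraceFormatError(ValueError):
    """A trace file violates the dialect; the message names the line."""


def write_trace(
    trace: LandmarkTrace,
    path: str | Path,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> None:
    """Serialize a trace in the versioned CSV dialect."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "frame_index": trace.frame_index,
        "time_s": trace.time,
        "nose_y": trace.nose_y,
    }
    if trace.yaw is not None:
        cols["yaw_deg"] = trace.yaw
    if not trace.tracked.all():
        cols["tracked"] = trace.tracked.astype(int)
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(
            f"# sample_rate={trace.sample_rate:g} config={config.config_hash()} "
            f"id={trace.trace_id}\n"
        )
        df.to_csv(fh, index=False, float_format="%.17g")


def _parse_header_meta(line: str, path: Path) -> tuple[float, str]:
    meta = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    if "sample_rate" not in meta:
        raise TraceFormatError(f"{path}:2: header missing sample_rate")
    try:
        rate = float(meta["sample_rate"])
    except ValueError as exc:
        raise TraceFormatError(f"{path}:2: bad sample_rate {meta['sample_rate']!r}") from exc
    return rate, meta.get("id", path.stem)


def read_trace(path: str | Path) -> LandmarkTrace:
    """Parse a trace file, validating version, columns and monotonicity."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise TraceFormatError(f"{path}:1: not a facetrace v1 file")
        second = fh.readline().rstrip("\n")
        if not second.startswith("#"):
            raise TraceFormatError(f"{path}:2: missing metadata comment line")
        sample_rate, trace_id = _parse_header_meta(second, path)
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except Exception as exc:
            raise TraceFormatError(f"{path}: malformed CSV body: {exc}") from exc

    required = {"frame_index", "time_s", "nose_y"}
    missing = required - set(df.columns)
    if missing:
        raise TraceFormatError(
            f"{path}:3: header row missing mandatory column(s) {sorted(missing)}"
        )
    # data rows start at physical line 4 (magic, meta, header row)
    idx = df["frame_index"].to_numpy()
    expected = np.arange(len(df))
    bad = np.nonzero(idx != expected)[0]
    if bad.size:
        line_no = int(bad[0]) + 4
        raise TraceFormatError(
            f"{path}:{line_no}: frame_index must increase strictly from 0 "
            f"(got {idx[bad[0]]}, expected {expected[bad[0]]})"
        )
    nose = df["nose_y"].to_numpy(dtype=float)
    tracked = (
        df["tracked"].to_numpy(dtype=bool)
        if "tracked" in df.columns
        else np.ones(len(df), dtype=bool)
    )
    nonfinite = np.nonzero(~np.isfinite(nose) & tracked)[0]
    if nonfinite.size:
        raise TraceFormatError(
            f"{path}:{int(nonfinite[0]) + 4}: non-finite nose_y on a tracked frame"
        )
    yaw = df["yaw_deg"].to_numpy(dtype=float) if "yaw_deg" in df.columns else None
    return LandmarkTrace(
        sample_rate=sample_rate,
        nose_y=nose,
        yaw=yaw,
        tracked=tracked,
        trace_id=trace_id,
    )
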