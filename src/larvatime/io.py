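"""Readers/writers for the pipeline's CSV/PNG/JSON artifacts.

CSV dialect: comma-separated, header required, UTF-8, '.' decimal.  Times
are hours as floats everywhere; episode durations alone are in minutes.
Every run log records the parameters, the seed and SHA-256 hashes of the
inputs so outputs are traceable to their configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .profiles import ActivityTrace
from .pumping import PumpingRaster

__all__ = [
    "load_image",
    "save_image",
    "read_traces_csv",
    "write_traces_csv",
    "read_boundaries_csv",
    "read_raster_csv",
    "write_raster_csv",
    "read_morphometry_csv",
    "write_run_log",
]


def load_image(path) -> np.ndarray:
    """Load an image as a 2-D grayscale uint8 array (0=black, 255=white)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def save_image(binary: np.ndarray, path) -> None:
    """Save a binary ink mask (1=ink) as a black-on-white PNG."""
    arr = (255 * (1 - np.asarray(binary, dtype=np.uint8))).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_traces_csv(path, boundaries: dict | None = None) -> list[ActivityTrace]:
    """Read activity traces (individual_id, time_h, activity)."""
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "time_h", "activity"], path)
    traces = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.sort_values("time_h")
        traces.append(
            ActivityTrace(
                individual_id=str(ind),
                times=sub["time_h"].to_numpy(float),
                activity=sub["activity"].to_numpy(float),
                stage_boundaries=dict(boundaries.get(str(ind), {})) if boundaries else {},
            )
        )
    return traces


def write_traces_csv(traces: list[ActivityTrace], path) -> None:
    frames = [
        pd.DataFrame({"individual_id": t.individual_id, "time_h": t.times, "activity": t.activity})
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_boundaries_csv(path) -> dict[str, dict[str, tuple[float, float]]]:
    """Read stage boundaries (individual_id, stage, entry_h, exit_h)."""
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "stage", "entry_h", "exit_h"], path)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for rec in df.itertuples():
        out.setdefault(str(rec.individual_id), {})[str(rec.stage)] = (float(rec.entry_h), float(rec.exit_h))
    return out


def read_raster_csv(path) -> list[PumpingRaster]:
    """Read pumping rasters (individual_id, time_h, pumping, [l4], [group]).

    Malformed rows are reported with their CSV line numbers; each
    individual's grid must have a fixed sampling interval.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "time_h", "pumping"], path)
    bad = ~df["pumping"].isin((0, 1))
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-binary pumping value(s) at line(s) {lines}")
    if "l4" in df.columns:
        bad = ~df["l4"].isin((0, 1))
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad]]
            raise ValueError(f"{path}: non-binary l4 value(s) at line(s) {lines}")
    rasters = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(float)
        if len(times) > 1:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-4):
                raise ValueError(f"{path}: individual {ind!r}: fixed interval required")
        rasters.append(
            PumpingRaster(
                individual_id=str(ind),
                times=times,
                pumping=sub["pumping"].to_numpy(np.int64),
                l4=sub["l4"].to_numpy(np.int64) if "l4" in sub.columns else None,
                group=str(sub["group"].iloc[0]) if "group" in sub.columns else "control",
            )
        )
    return rasters


def write_raster_csv(rasters: list[PumpingRaster], path) -> None:
    frames = []
    for r in rasters:
        frame = pd.DataFrame(
            {"individual_id": r.individual_id, "time_h": r.times, "pumping": r.pumping, "group": r.group}
        )
        if r.l4 is not None:
            frame["l4"] = r.l4
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_morphometry_csv(path) -> pd.DataFrame:
    """Read a morphometry table (individual_id, time_h, group, length_um, width_um)."""
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "time_h", "group", "length_um", "width_um"], path)
    if (df["length_um"] <= 0).any() or (df["width_um"] <= 0).any():
        raise ValueError(f"{path}: lengths and widths must be positive")
    return df


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_log(path, params: dict, inputs: list | None = None) -> None:
    """Write a JSON run log: parameters, seed and input-file hashes."""
    log = {
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in (inputs or []) if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
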