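"""File-format plumbing: multi-page TIFF images, CSV tables, JSON configs.

CSV dialect: comma-separated, UTF-8, header row, '.' decimal, floats written
to 15 significant digits so reader/writer round-trips are lossless at double
precision for practical purposes.  Concentrations are always plain floats in
nM.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .quantify import CalciumTrace

FLOAT_FORMAT = "%.15g"


# ---- images ---------------------------------------------------------------


def write_channels_tiff(path: str | Path, channels: Sequence[np.ndarray]) -> None:
    """Write one image channel per TIFF page (float32)."""
    pages = np.stack([np.asarray(ch, dtype=np.float32) for ch in channels])
    tifffile.imwrite(str(path), pages)


def write_stack_tiff(path: str | Path, stack: np.ndarray) -> None:
    """Write a time-lapse stack, one frame per TIFF page (float32)."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return np.asarray(arr)


def read_channels_tiff(path: str | Path, n_channels: int = 2) -> list[np.ndarray]:
    arr = read_tiff(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != n_channels:
        raise ValidationError(
            f"{path}: expected {n_channels} channel pages, found {arr.shape[0]}"
        )
    return [np.asarray(arr[i], dtype=float) for i in range(n_channels)]


# ---- tables ---------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_traces_csv(traces: Sequence[CalciumTrace], path: str | Path) -> None:
    """Long-format trace table: cell_id, pattern_id, frame, value."""
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "pattern_id": t.pattern_id,
                    "frame": np.arange(len(t.values)),
                    "value": t.values,
                }
            )
        )
    write_table(pd.concat(frames, ignore_index=True), path)


def read_traces_csv(
    path: str | Path, induction_frame: int, frame_rate_hz: float = 5.0
) -> list[CalciumTrace]:
    df = read_table(path)
    missing = {"cell_id", "pattern_id", "frame", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"trace table lacks columns: {sorted(missing)}")
    traces = []
    for (cell_id, pattern_id), grp in df.groupby(["cell_id", "pattern_id"], sort=True):
        grp = grp.sort_values("frame")
        traces.append(
            CalciumTrace(
                cell_id=int(cell_id),
                pattern_id=int(pattern_id),
                values=grp["value"].to_numpy(dtype=float),
                frame_rate_hz=frame_rate_hz,
                induction_frame=induction_frame,
            )
        )
    return traces


# ---- JSON -----------------------------------------------------------------


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path} is not valid JSON: {exc}") from exc
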