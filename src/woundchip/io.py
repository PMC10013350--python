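"""Shared readers/writers: TIFF stacks, track tables, reports, configs.

All image I/O goes through tifffile (multi-page TIFF, lossless round-trip
for 16-bit grayscale and 8-bit RGB).  Track tables are CSV with the schema
(frame:int, cell_id:int, x:float, y:float); frames must increase within
each track.  Reports are plain JSON; run configs are YAML with explicit
units in the key names (current_uA, interval_min, ...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


TRACK_COLUMNS = ("frame", "cell_id", "x", "y")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF stack as (T, H, W) or (T, H, W, C)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write an image stack as multi-page TIFF (bit-identical round-trip)."""
    stack = np.asarray(stack)
    if stack.size == 0 or stack.ndim < 3:
        raise ValueError("refusing to write an empty or 2-D stack")
    tifffile.imwrite(str(path), stack)


def write_field_map(array: np.ndarray, path: str | Path) -> None:
    """Export a float field map (potential, |E|, ...) as single-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32))


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read and validate a track CSV (frame, cell_id, x, y)."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"track CSV {path} missing column(s): {', '.join(missing)}"
        )
    df = df[list(TRACK_COLUMNS)]
    try:
        df = df.astype({"frame": int, "cell_id": int, "x": float, "y": float})
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"track CSV {path} has non-numeric values: {exc}") from exc
    for cid, sub in df.groupby("cell_id"):
        fr = sub["frame"].to_numpy()
        if np.any(np.diff(fr) <= 0):
            raise SchemaError(f"non-monotone frames within track {cid}")
    return df.reset_index(drop=True)


def write_tracks(df: pd.DataFrame, path: str | Path) -> None:
    df[list(TRACK_COLUMNS)].to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    """Write a JSON report (numpy scalars/arrays converted to plain types)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> dict:
    """Load a YAML run config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping of sections")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    """Write the resolved config next to the outputs of a run."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
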