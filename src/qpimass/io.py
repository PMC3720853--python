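"""File formats: multi-page TIFF stacks, CSV tables, JSON models/events.

Stacks are written as 32-bit float multi-page TIFF with the physical units
recorded in the ImageJ-style metadata; ground truth and tabular outputs are
plain CSV (comma, '.', UTF-8, header row); models, events and run manifests
are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import OpticsConfig, RunConfig


def write_stack(path: str | Path, stack: np.ndarray, optics: OpticsConfig, kind: str = "opd_um") -> None:
    """Write a (T, H, W) stack as multi-page float32 TIFF with unit metadata."""
    arr = np.asarray(stack, dtype=np.float32)
    meta = {
        "unit": "um",
        "kind": kind,
        "pixel_um": optics.pixel_um,
        "wavelength_um": optics.wavelength_um,
        "frame_interval_min": optics.frame_interval_min,
    }
    tifffile.imwrite(path, arr, photometric="minisblack", metadata=meta)


def read_stack(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])
        elif tf.imagej_metadata:
            meta = dict(tf.imagej_metadata)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.float64), meta


def write_int_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.int32), photometric="minisblack")


def write_truth_csv(path: str | Path, table: pd.DataFrame) -> None:
    cols = ["frame", "cell_id", "mass_pg", "area_um2", "x_um", "y_um", "state", "partner_id"]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, obj: Any) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_run_config(path: str | Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
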