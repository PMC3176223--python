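"""Configuration and file I/O: masks, reports, snapshots, run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import datetime
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams
from .state import BinaryPattern, FieldState, SimulationState

__all__ = [
    "load_config",
    "save_report",
    "read_mask",
    "write_mask",
    "write_snapshot",
    "write_manifest",
]


def load_config(path: str | Path) -> tuple[ModelParams, dict[str, Any]]:
    """Load a YAML/JSON config with ``params`` and optional ``scenario`` keys.

    A flat file (parameters only) is accepted too.  Schema violations raise
    ``ValueError`` naming the offending key.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "params" in doc:
        params = ModelParams.from_dict(doc["params"] or {})
        scenario = doc.get("scenario") or {}
    else:
        params = ModelParams.from_dict(doc)
        scenario = {}
    return params, scenario


def save_report(
    table: pd.DataFrame | list[dict], path: str | Path, format: str | None = None
) -> Path:
    """Write a feature table as CSV or (nested) JSON, inferred from suffix."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower() or "csv"
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        df.to_csv(path)
    elif fmt == "json":
        df.reset_index().to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def write_mask(pattern: BinaryPattern, path: str | Path) -> Path:
    """Write a binary mask as single-channel PNG or TIFF (0/255)."""
    path = Path(path)
    img = (pattern.grid * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img, extension=path.suffix or ".png")
    return path


def read_mask(path: str | Path, pixel_size: float = 1.0) -> BinaryPattern:
    """Read a single-channel 0/255 (or 0/1) image as a binary pattern.

    Non-binary images are rejected with a thresholding suggestion.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., 0]
    vals = np.unique(img)
    if np.isin(vals, (0, 1)).all():
        grid = img.astype(np.uint8)
    elif np.isin(vals, (0, 255)).all():
        grid = (img > 0).astype(np.uint8)
    else:
        raise ValueError(
            f"{path}: image is not binary (values {vals[:8]}...); threshold it "
            f"first, e.g. mask = image > {int(np.median(vals))}"
        )
    return BinaryPattern(grid, pixel_size)


def write_snapshot(
    state: SimulationState,
    fields: FieldState | None,
    path: str | Path,
) -> Path:
    """Write a compressed array archive of a simulation snapshot (plus a
    sibling PNG of the cell mask)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"sigma": state.sigma, "areas": state.areas,
              "mcs_elapsed": np.array(state.mcs_elapsed)}
    if fields is not None:
        arrays.update(s=fields.s, e=fields.e, b=fields.b)
    np.savez_compressed(path, **arrays)
    from .state import cell_mask

    write_mask(cell_mask(state), path.with_suffix(".png"))
    return path


def config_hash(params: ModelParams) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    path: str | Path,
    params: ModelParams,
    seed: int,
    scenario: dict | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a JSON run manifest from which the run can be regenerated."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "vasculogen",
        "version": __version__,
        "config_hash": config_hash(params),
        "seed": int(seed),
        "params": params.to_dict(),
        "scenario": scenario or {},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
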