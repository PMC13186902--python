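"""Standard-format I/O: TIFF stacks, CSV tables, JSON summaries, YAML config."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ValidationError
from .nuclei import LabelMap, NucleusRecord

# Floating-point images are scaled linearly into uint16 on write; the scale is
# stored in the TIFF description so reads are (quantized but) reversible.
_U16_MAX = 65535


def write_stack(path, stack: np.ndarray) -> None:
    """Write an image or movie as multi-page 16-bit TIFF with linear scaling."""
    stack = np.asarray(stack)
    lo, hi = float(stack.min()), float(stack.max())
    scale = _U16_MAX / (hi - lo) if hi > lo else 1.0
    data = np.round((stack - lo) * scale).astype(np.uint16)
    meta = json.dumps({"offset": lo, "scale": scale})
    tifffile.imwrite(str(path), data, description=meta, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a TIFF written by :func:`write_stack`, undoing the linear scaling."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        data = data / meta["scale"] + meta["offset"]
    except (json.JSONDecodeError, KeyError, TypeError):
        pass  # plain TIFF from elsewhere: return raw intensities
    return data


def write_label_map(path, label_map: LabelMap) -> None:
    labels = label_map.labels
    if labels.max() > _U16_MAX:
        raise ValidationError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(str(path), labels.astype(np.uint16), photometric="minisblack")


def read_label_map(path, pixel_size: float | None = None) -> LabelMap:
    return LabelMap(tifffile.imread(str(path)).astype(np.int32), pixel_size)


def write_nucleus_records(path, records: list[NucleusRecord]) -> None:
    pd.DataFrame(
        {
            "label": [r.label for r in records],
            "area_px2": [r.area for r in records],
            "solidity": [r.solidity for r in records],
            "centroid_row": [r.centroid[0] for r in records],
            "centroid_col": [r.centroid[1] for r in records],
            "intact": [r.intact for r in records],
        }
    ).to_csv(path, index=False)


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def load_config(path, defaults: dict) -> dict:
    """Load a YAML config and merge over ``defaults``, rejecting unknown keys."""
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    return merge_config(defaults, user)


def merge_config(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        if isinstance(default, dict) and isinstance(user.get(key), dict):
            out[key] = merge_config(default, user[key], prefix=f"{prefix}{key}.")
        else:
            out[key] = user.get(key, default)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValidationError(
            f"unknown config key '{prefix}{sorted(unknown)[0]}'"
        )
    return out
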