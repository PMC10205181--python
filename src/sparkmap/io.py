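"""File I/O: TIFF stacks, tables and YAML/JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from sparkmap.paint import to_uint16


def write_movie_tiff(path, movie: np.ndarray) -> None:
    """Write a float movie as a multi-page 16-bit TIFF (clipped at zero)."""
    arr = np.clip(np.asarray(movie, float), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_movie_tiff(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def write_rendered_tiff(path, rendered: np.ndarray) -> None:
    tifffile.imwrite(str(path), to_uint16(rendered), photometric="minisblack")


def write_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
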