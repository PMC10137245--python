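"""File interfaces: RGB patches as PNG, label masks as 16-bit PNG, TSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["save_patch", "load_patch", "save_mask", "load_mask",
           "save_table", "load_table"]


def save_patch(path: str | Path, rgb: np.ndarray) -> None:
    """Write an 8-bit RGB patch as PNG."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ValueError("patch must be HxWx3 uint8")
    Image.fromarray(arr, mode="RGB").save(path)


def load_patch(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write an integer label mask as single-channel 16-bit PNG."""
    arr = np.asarray(mask)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels must fit in uint16")
    Image.fromarray(arr.astype(np.uint16)).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint16)


def save_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
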