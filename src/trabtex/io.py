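"""File round-trips: grayscale images, ROI masks, feature CSVs, labels."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "read_grayscale",
    "read_mask",
    "write_image",
    "write_mask",
    "read_labels",
    "write_dataset",
    "load_dataset",
]


def read_grayscale(path: str | Path) -> np.ndarray:
    """8-bit grayscale PNG/TIFF; color inputs are luminance-converted."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def read_mask(path: str | Path) -> np.ndarray:
    """Binary mask image: any nonzero pixel counts as foreground."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, np.asarray(mask, bool).astype(np.uint8) * 255)


def read_labels(path: str | Path) -> pd.Series:
    """labels.csv with columns ``id`` and ``label``."""
    df = pd.read_csv(path)
    if not {"id", "label"} <= set(df.columns):
        raise ValueError("labels file needs 'id' and 'label' columns")
    return df.set_index("id")["label"]


def write_dataset(outdir: str | Path, images, masks, labels, ids=None) -> None:
    """Write images/, masks/ and labels.csv under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    if ids is None:
        ids = [f"img{k:03d}" for k in range(len(images))]
    for img_id, image, mask in zip(ids, images, masks):
        write_image(outdir / "images" / f"{img_id}.png", image)
        write_mask(outdir / "masks" / f"{img_id}.png", mask)
    pd.DataFrame({"id": ids, "label": labels}).to_csv(
        outdir / "labels.csv", index=False)


def load_dataset(indir: str | Path):
    """Read back a directory written by :func:`write_dataset`."""
    indir = Path(indir)
    labels = read_labels(indir / "labels.csv")
    images, masks = [], []
    for img_id in labels.index:
        images.append(read_grayscale(indir / "images" / f"{img_id}.png"))
        masks.append(read_mask(indir / "masks" / f"{img_id}.png"))
    return images, masks, labels
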