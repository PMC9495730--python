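"""Slide manifests and flat raster image I/O (PNG/TIFF)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["SlideRecord", "read_manifest", "write_manifest", "read_image", "write_image"]


@dataclass(frozen=True)
class SlideRecord:
    """One manifest row: slide id, subject id, image path, class label."""

    slide_id: str
    subject_id: str | None
    path: str
    label: str


def read_image(path: str | Path) -> np.ndarray:
    """Load an image as HxWx3 uint8 RGB (alpha dropped, grayscale expanded)."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[..., :3]
    return np.ascontiguousarray(img[..., :3]).astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), image)


def read_manifest(path: str | Path) -> list[SlideRecord]:
    df = pd.read_csv(path)
    required = {"slide_id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        subject = getattr(row, "subject_id", None)
        records.append(
            SlideRecord(
                slide_id=str(row.slide_id),
                subject_id=None if subject is None or pd.isna(subject) else str(subject),
                path=str(row.path),
                label=str(row.label),
            )
        )
    return records


def write_manifest(records: list[SlideRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)
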