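"""Slide manifests and the region-reader contract.

A manifest is a CSV with columns ``slide_id, case_id, label, source,
image_uri`` — one row per whole-slide image. Labels are the two diagnostic
classes handled by the pipeline: ``normal`` and ``coeliac``.

Pixel access goes through a small region-reader contract so that the rest of
the pipeline never touches file formats directly: plain PNG/TIFF rasters back
the readers here; a pyramidal WSI reader can implement the same two methods
for deployment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Protocol, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

LABELS = ("normal", "coeliac")

MANIFEST_COLUMNS = ["slide_id", "case_id", "label", "source", "image_uri"]


@dataclass(frozen=True)
class SlideRecord:
    """One manifest row: slide identity, case grouping, label, provenance."""

    slide_id: str
    case_id: str
    label: str
    source: str
    image_uri: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"label must be one of {LABELS}, got {self.label!r}"
            )
        if not self.case_id:
            raise ValueError("case_id must be non-empty")

    @property
    def is_positive(self) -> bool:
        return self.label == "coeliac"


def read_manifest(path: str | os.PathLike) -> list[SlideRecord]:
    """Read a manifest CSV into validated :class:`SlideRecord` rows."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns {missing}")
    records = [
        SlideRecord(
            slide_id=row.slide_id,
            case_id=row.case_id,
            label=row.label,
            source=row.source,
            image_uri=row.image_uri,
        )
        for row in df.itertuples()
    ]
    ids = [r.slide_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("slide_id values must be unique within a manifest")
    return records


def write_manifest(records: Sequence[SlideRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


class RegionReader(Protocol):
    """Minimal pixel-access contract: dimensions plus rectangular RGB reads."""

    @property
    def dims(self) -> tuple[int, int]:
        """(width, height) in pixels at working resolution."""
        ...

    def read_region(self, x: int, y: int, width: int, height: int) -> np.ndarray:
        """Return the RGB uint8 region with top-left corner (x, y)."""
        ...


class ArrayRegionReader:
    """Region reader over an in-memory RGB uint8 array (H x W x 3)."""

    def __init__(self, image: np.ndarray):
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an H x W x 3 RGB array")
        self._image = image

    @property
    def dims(self) -> tuple[int, int]:
        h, w = self._image.shape[:2]
        return (w, h)

    def read_region(self, x: int, y: int, width: int, height: int) -> np.ndarray:
        w, h = self.dims
        if x < 0 or y < 0 or x + width > w or y + height > h:
            raise ValueError("region outside slide bounds")
        return self._image[y : y + height, x : x + width]


class FileRegionReader(ArrayRegionReader):
    """Region reader backed by a raster file (PNG/TIFF), loaded lazily."""

    def __init__(self, path: str | os.PathLike):
        self._path = os.fspath(path)
        image = iio.imread(self._path)
        if image.ndim == 2:  # greyscale raster: promote to RGB
            image = np.stack([image] * 3, axis=-1)
        if image.shape[2] == 4:  # drop alpha
            image = image[:, :, :3]
        super().__init__(np.ascontiguousarray(image[:, :, :3]))


def open_slide(record: SlideRecord | str | os.PathLike) -> RegionReader:
    """Open the raster behind a manifest row (or a bare path)."""
    uri = record.image_uri if isinstance(record, SlideRecord) else record
    return FileRegionReader(uri)
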