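"""Core raster containers: intensity images and label maps with physical pixel size.

All geometry in the package is 0-based (row, col). Physical lengths are carried
in micrometres and converted to pixels by rounding half up, so that a parameter
of exactly n + 0.5 pixels maps to n + 1.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


def um_to_px(value_um: float, pixel_size_um: float) -> int:
    """Convert a length in µm to whole pixels, rounding half up."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return int(np.floor(value_um / pixel_size_um + 0.5))


@dataclass
class Image2D:
    """A single-channel 2D intensity image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Non-negative intensities (float).
    pixel_size_um : float
        Physical edge length of one pixel in µm; pixel area is its square.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def to_px(self, value_um: float) -> int:
        return um_to_px(value_um, self.pixel_size_um)


@dataclass
class LabelMap:
    """An integer segmentation raster; 0 is background, labels are positive."""

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMap requires a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_ids.size)

    def area_um2(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.pixel_size_um ** 2


def write_field_tiff(path: str | Path, channels: dict[str, Image2D]) -> None:
    """Write a multi-channel field as one TIFF plus a JSON sidecar naming channels."""
    path = Path(path)
    names = list(channels)
    stack = np.stack([channels[n].pixels.astype(np.float32) for n in names])
    tifffile.imwrite(path, stack)
    sidecar = {
        "channels": names,
        "pixel_size_um": channels[names[0]].pixel_size_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_field_tiff(path: str | Path) -> dict[str, Image2D]:
    """Read a multi-channel TIFF written by :func:`write_field_tiff`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    px = float(sidecar["pixel_size_um"])
    return {
        name: Image2D(np.clip(stack[i].astype(float), 0, None), px)
        for i, name in enumerate(sidecar["channels"])
    }


def write_labelmap_tiff(path: str | Path, labels: LabelMap) -> None:
    arr = labels.labels
    if arr.max() >= 2 ** 16:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(Path(path), arr.astype(np.uint16))


def read_labelmap_tiff(path: str | Path, pixel_size_um: float = 1.0) -> LabelMap:
    return LabelMap(tifffile.imread(Path(path)).astype(np.int32), pixel_size_um)
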