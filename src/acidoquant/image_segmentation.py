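"""Nuclei-seeded cell segmentation.

The recipe mirrors a standard high-content workflow: morphological background
subtraction, intensity thresholding of the nuclear channel to detect and count
nuclei, growth of each nucleus over bright guide pixels out to a maximum
radius (colliding fronts resolved by nearest-nucleus assignment), and removal
of any cell region touching the image border.

Connectivity is 4-connected throughout. Nearest-nucleus distances are
Euclidean to the nucleus mask; within the admissible (supra-floor) region this
coincides with the geodesic distance whenever the region is locally convex
around each nucleus, which holds for the intensity floors used here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

from .images import Image2D, LabelMap, um_to_px

__all__ = [
    "SegmentationResult",
    "subtract_background",
    "detect_nuclei",
    "grow_cells",
    "resolve_threshold",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class SegmentationResult:
    nuclei: LabelMap
    cells: LabelMap
    n_nuclei: int
    removed_border_labels: list[int]
    params_used: dict = field(default_factory=dict)


def subtract_background(
    image: Image2D, radius_um: float, presmooth_px: int = 3, remove_pedestal: bool = True
) -> Image2D:
    """Remove smooth background by a morphological (rolling-ball-like) opening.

    The background is the grayscale opening (with a disk of the given radius)
    of a lightly mean-filtered copy of the image; the opening of the raw image
    would track local noise minima and leave a noise-floor offset of a couple
    of noise sigmas. Because even the smoothed opening sits slightly below the
    true background level, a residual pedestal (the median of the subtracted
    image, valid while background pixels are the majority) is removed as well.
    The background is subtracted from the *original* pixels, so small bright
    features are preserved unattenuated, and the result is clamped
    non-negative. A constant image maps to zero.
    """
    radius_px = um_to_px(radius_um, image.pixel_size_um)
    if radius_px < 1:
        raise ValueError("background radius is smaller than one pixel")
    base = image.pixels
    if presmooth_px > 1:
        base = ndimage.uniform_filter(base, size=presmooth_px)
    footprint = disk(radius_px, decomposition="sequence")
    background = opening(base, footprint=footprint)
    out = image.pixels - background
    if remove_pedestal:
        out = out - np.median(out)
    return Image2D(np.clip(out, 0.0, None), image.pixel_size_um)


def resolve_threshold(pixels: np.ndarray, threshold_spec) -> float:
    """Turn a threshold spec ('otsu' or a number) into an intensity value."""
    if threshold_spec == "otsu":
        if np.ptp(pixels) == 0:
            return float(pixels.flat[0]) + 1.0  # nothing above threshold
        return float(threshold_otsu(pixels))
    return float(threshold_spec)


def detect_nuclei(
    nuclear_channel: Image2D,
    threshold_spec="otsu",
    min_area_um2: float = 10.0,
) -> LabelMap:
    """Label connected supra-threshold components of the nuclear channel.

    Components smaller than ``min_area_um2`` are discarded; survivors are
    relabelled 1..n in raster order. Touching nuclei are not declumped: one
    connected blob yields one label.
    """
    thr = resolve_threshold(nuclear_channel.pixels, threshold_spec)
    binary = nuclear_channel.pixels >= thr
    labels, n = ndimage.label(binary, structure=_FOUR_CONN)
    if n == 0:
        return LabelMap(labels, nuclear_channel.pixel_size_um)
    min_px = max(int(np.ceil(min_area_um2 / nuclear_channel.pixel_area_um2)), 1)
    areas = np.bincount(labels.ravel())
    keep = np.nonzero(areas >= min_px)[0]
    keep = keep[keep > 0]
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1)
    return LabelMap(lut[labels], nuclear_channel.pixel_size_um)


def grow_cells(
    nuclei: LabelMap,
    guide_channel: Image2D,
    max_radius_um: float,
    intensity_floor: float = 0.0,
) -> SegmentationResult:
    """Grow each nucleus over bright guide pixels into a cell region.

    A pixel joins the cell of its nearest nucleus (Euclidean distance to the
    nucleus mask; ties resolved by the distance transform's deterministic
    nearest-index rule, then lower label) if it is admissible (guide intensity
    >= ``intensity_floor`` or inside a nucleus) and within ``max_radius_um``
    of that nucleus. Pixels not 4-connected to their nucleus are dropped.
    Cells touching the image border are deleted and recorded.
    """
    if nuclei.shape != guide_channel.shape:
        raise ValueError("nuclei and guide channel shapes differ")
    lab = nuclei.labels
    px = nuclei.pixel_size_um
    max_px = max_radius_um / px

    dist, (ir, ic) = ndimage.distance_transform_edt(lab == 0, return_indices=True)
    nearest = lab[ir, ic]
    admissible = (guide_channel.pixels >= intensity_floor) | (lab > 0)
    cells = np.where(admissible & (dist <= max_px), nearest, 0).astype(np.int32)

    if intensity_floor > float(guide_channel.pixels.min()):
        cells = _keep_connected_to_seed(cells, lab)

    removed = sorted(_border_labels(cells))
    if removed:
        mask = np.isin(cells, removed)
        cells[mask] = 0

    return SegmentationResult(
        nuclei=nuclei,
        cells=LabelMap(cells, px),
        n_nuclei=nuclei.n_labels,
        removed_border_labels=[int(r) for r in removed],
        params_used={
            "max_radius_um": max_radius_um,
            "intensity_floor": intensity_floor,
        },
    )


def _border_labels(labels: np.ndarray) -> set[int]:
    edge = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    return set(int(v) for v in np.unique(edge[edge > 0]))


def _keep_connected_to_seed(cells: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    out = cells.copy()
    for sl, lab_id in zip(ndimage.find_objects(cells), range(1, cells.max() + 1)):
        if sl is None:
            continue
        region = cells[sl] == lab_id
        comp, n = ndimage.label(region, structure=_FOUR_CONN)
        if n <= 1:
            continue
        seed_comps = np.unique(comp[(seeds[sl] == lab_id) & region])
        seed_comps = seed_comps[seed_comps > 0]
        drop = region & ~np.isin(comp, seed_comps)
        out[sl][drop] = 0
    return out
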