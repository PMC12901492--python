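"""Two-channel test beds for colocalization metrics.

One simulated object carries two independent constructions:

* a pair of continuous channels built from shared + independent Gaussian
  components so the population Pearson correlation equals ``rho_target``;
* a punctate organelle-marker mask and a signal mask in which an exact
  fraction ``overlap_target`` of equal-sized marker structures lies wholly
  inside the signal mask (the rest wholly outside), so the area overlap
  fraction is exact by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..images import Image2D
from ._placement import PlacementError, rasterize_disks

__all__ = ["ColocSim", "simulate_coloc_pair"]


@dataclass
class ColocSim:
    channel_a: Image2D
    channel_b: Image2D
    marker: Image2D
    signal: Image2D
    truth: dict


def simulate_coloc_pair(
    rho_target: float,
    overlap_target: float,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.5,
    seed: int = 0,
    mean: float = 1000.0,
    sd: float = 100.0,
    n_structures: int = 100,
    structure_radius_um: float = 1.5,
    n_signal_blobs: int = 30,
    signal_blob_radius_um: float = 10.0,
    amplitude: float = 1.0,
) -> ColocSim:
    """Build the correlated channel pair and the overlap mask pair."""
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must be in [-1, 1]")
    if not 0.0 <= overlap_target <= 1.0:
        raise ValueError("overlap_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = shape

    z1 = rng.standard_normal(shape)
    z2 = rng.standard_normal(shape)
    a = mean + sd * z1
    b = mean + sd * (rho_target * z1 + np.sqrt(1 - rho_target**2) * z2)
    a = np.clip(a, 0, None)
    b = np.clip(b, 0, None)

    r_blob = signal_blob_radius_um / pixel_size_um
    blob_centers = np.column_stack(
        [rng.uniform(r_blob, rows - r_blob, n_signal_blobs),
         rng.uniform(r_blob, cols - r_blob, n_signal_blobs)]
    )
    signal_mask = (
        rasterize_disks(shape, blob_centers, np.full(n_signal_blobs, r_blob)) > 0
    )

    r_s = structure_radius_um / pixel_size_um
    n_inside = int(round(overlap_target * n_structures))
    inside_ok = ndimage.distance_transform_edt(signal_mask) > r_s + 1
    outside_ok = ndimage.distance_transform_edt(~signal_mask) > r_s + 1
    centers = _place_structures(rng, inside_ok, outside_ok, n_inside,
                                n_structures - n_inside, min_sep=2 * r_s + 2)
    # integer centres: every structure is the same pixelated disk, so areas are
    # exactly equal and the overlap fraction is exactly n_inside / n_structures
    marker_mask = rasterize_disks(shape, centers, np.full(n_structures, r_s)) > 0

    return ColocSim(
        channel_a=Image2D(a, pixel_size_um),
        channel_b=Image2D(b, pixel_size_um),
        marker=Image2D(marker_mask.astype(float) * amplitude, pixel_size_um),
        signal=Image2D(signal_mask.astype(float) * amplitude, pixel_size_um),
        truth={
            "rho_target": rho_target,
            "overlap_target": overlap_target,
            "n_structures": n_structures,
            "n_inside": n_inside,
            "exact_overlap": n_inside / n_structures if n_structures else np.nan,
        },
    )


def _place_structures(
    rng: np.random.Generator,
    inside_ok: np.ndarray,
    outside_ok: np.ndarray,
    n_inside: int,
    n_outside: int,
    min_sep: float,
) -> np.ndarray:
    placed: list[np.ndarray] = []
    for region, count in ((inside_ok, n_inside), (outside_ok, n_outside)):
        coords = np.column_stack(np.nonzero(region))
        if count > 0 and len(coords) == 0:
            raise PlacementError("no admissible region for marker structures", len(placed))
        for _ in range(count):
            for _ in range(400):
                cand = coords[rng.integers(len(coords))].astype(float)
                if all(np.hypot(*(cand - p)) >= min_sep for p in placed):
                    placed.append(cand)
                    break
            else:
                raise PlacementError(
                    "could not place marker structures without overlap", len(placed)
                )
    return np.array(placed) if placed else np.empty((0, 2))
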