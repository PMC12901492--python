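"""Colocalization readouts: Pearson correlation above threshold and the
fraction of organelle-marker area overlapping a signal mask.

The Pearson readout correlates two channels over the pixels where at least
one channel exceeds its threshold (union rule by default; switchable to
intersection). Thresholds may be fixed values or chosen automatically by a
Costes-style bisection that seeks thresholds below which the residual
correlation vanishes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .images import Image2D

__all__ = [
    "ColocResult",
    "pearson_above_threshold",
    "overlap_fraction",
    "costes_thresholds",
    "ColocUndefinedError",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


class ColocUndefinedError(ValueError):
    """Raised when a colocalization readout is undefined for the input."""


@dataclass
class ColocResult:
    pearson_above_threshold: float | None = None
    n_pixels_used: int = 0
    thresholds: tuple[float, float] | None = None
    overlap_fraction: float | None = None
    marker_area_um2: float | None = None
    overlapping_area_um2: float | None = None


def costes_thresholds(a: np.ndarray, b: np.ndarray, tol: float = 1e-3) -> tuple[float, float]:
    """Automatic threshold pair by Costes bisection.

    Thresholds walk down the orthogonal regression line b = m*a + c; the
    selected pair is the highest at which pixels below both thresholds are
    uncorrelated (|r| <= tol), or the intensity minimum if no such point
    exists.
    """
    a = a.ravel()
    b = b.ravel()
    m, c = _orthogonal_regression(a, b)
    lo, hi = float(a.min()), float(a.max())
    if _below_r(a, b, hi, m, c) > tol:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _below_r(a, b, mid, m, c) > tol:
                hi = mid
            else:
                lo = mid
        t_a = 0.5 * (lo + hi)
    else:
        t_a = hi
    return t_a, m * t_a + c


def _orthogonal_regression(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    cov = np.cov(a, b)
    if cov[0, 1] == 0:
        return 0.0, float(b.mean())
    lam = 0.5 * (
        cov[0, 0]
        + cov[1, 1]
        + np.sqrt((cov[0, 0] - cov[1, 1]) ** 2 + 4 * cov[0, 1] ** 2)
    )
    m = cov[0, 1] / (lam - cov[1, 1]) if lam != cov[1, 1] else 1.0
    return float(m), float(b.mean() - m * a.mean())


def _below_r(a, b, t_a, m, c) -> float:
    sel = (a < t_a) & (b < m * t_a + c)
    if sel.sum() < 10 or np.ptp(a[sel]) == 0 or np.ptp(b[sel]) == 0:
        return 0.0
    return float(stats.pearsonr(a[sel], b[sel])[0])


def _resolve_pair(a: np.ndarray, b: np.ndarray, threshold_spec) -> tuple[float, float]:
    if threshold_spec == "costes":
        return costes_thresholds(a, b)
    if np.isscalar(threshold_spec):
        return float(threshold_spec), float(threshold_spec)
    t_a, t_b = threshold_spec
    return float(t_a), float(t_b)


def pearson_above_threshold(
    ch_a: Image2D,
    ch_b: Image2D,
    threshold_spec="costes",
    roi: np.ndarray | None = None,
    rule: str = "union",
) -> ColocResult:
    """Pearson r over pixels where at least one channel is supra-threshold.

    ``threshold_spec`` is ``"costes"``, a scalar, or a (t_a, t_b) pair.
    ``rule`` selects the pixel-inclusion rule: ``"union"`` (default, either
    channel above its threshold) or ``"intersection"``.
    """
    if ch_a.shape != ch_b.shape:
        raise ValueError("channel shapes differ")
    a = ch_a.pixels
    b = ch_b.pixels
    if roi is not None:
        if roi.shape != a.shape:
            raise ValueError("ROI shape differs from the channels")
        a = a[roi]
        b = b[roi]
    t_a, t_b = _resolve_pair(a, b, threshold_spec)
    if rule == "union":
        sel = (a >= t_a) | (b >= t_b)
    elif rule == "intersection":
        sel = (a >= t_a) & (b >= t_b)
    else:
        raise ValueError("rule must be 'union' or 'intersection'")
    n = int(sel.sum())
    if n < 10:
        raise ColocUndefinedError(f"only {n} qualifying pixels")
    if np.ptp(a[sel]) == 0 or np.ptp(b[sel]) == 0:
        raise ColocUndefinedError("zero variance among qualifying pixels")
    r = float(stats.pearsonr(a[sel], b[sel])[0])
    return ColocResult(pearson_above_threshold=r, n_pixels_used=n, thresholds=(t_a, t_b))


def overlap_fraction(
    marker: Image2D,
    signal: Image2D,
    threshold_spec=0.5,
    min_structure_area_um2: float = 0.0,
) -> ColocResult:
    """Fraction of organelle-marker area overlapping the signal mask.

    Both channels are thresholded to masks; marker components smaller than
    ``min_structure_area_um2`` are dropped. The fraction is
    area(marker AND signal) / area(marker).
    """
    if marker.shape != signal.shape:
        raise ValueError("channel shapes differ")
    t_m, t_s = _resolve_pair(marker.pixels, signal.pixels, threshold_spec)
    marker_mask = marker.pixels >= t_m
    signal_mask = signal.pixels >= t_s
    if min_structure_area_um2 > 0:
        labels, n = ndimage.label(marker_mask, structure=_FOUR_CONN)
        if n:
            min_px = int(np.ceil(min_structure_area_um2 / marker.pixel_area_um2))
            areas = np.bincount(labels.ravel())
            good = areas >= min_px
            good[0] = False
            marker_mask = good[labels]
    m_area = int(marker_mask.sum())
    if m_area == 0:
        raise ColocUndefinedError("empty marker mask")
    inter = int((marker_mask & signal_mask).sum())
    pa = marker.pixel_area_um2
    return ColocResult(
        overlap_fraction=inter / m_area,
        thresholds=(t_m, t_s),
        marker_area_um2=m_area * pa,
        overlapping_area_um2=inter * pa,
        n_pixels_used=m_area,
    )
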