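"""Random geometry helpers shared by the field generators."""
from __future__ import annotations

import numpy as np


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap in the field.

    Attributes
    ----------
    n_placed : int
        Number of objects successfully placed before giving up.
    """

    def __init__(self, message: str, n_placed: int):
        super().__init__(message)
        self.n_placed = n_placed


def sample_nucleus_layout(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radius_mean_px: float,
    radius_sd_px: float,
    min_gap_px: float = 2.0,
    max_tries_per_cell: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample non-overlapping nucleus centres and radii (in pixels).

    Centres are uniform over the field with each nucleus kept fully inside the
    border; two nuclei i, j satisfy dist >= r_i + r_j + min_gap_px. Raises
    :class:`PlacementError` (carrying the count placed) if the field is too
    crowded after bounded retries.
    """
    rows, cols = shape
    radii = np.maximum(rng.normal(radius_mean_px, radius_sd_px, size=n), 1.0)
    centers = np.empty((n, 2))
    for i in range(n):
        r = radii[i]
        lo_r, hi_r = r + 1.0, rows - 1 - r - 1.0
        lo_c, hi_c = r + 1.0, cols - 1 - r - 1.0
        if hi_r <= lo_r or hi_c <= lo_c:
            raise PlacementError("field smaller than one nucleus", i)
        for _ in range(max_tries_per_cell):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            if i == 0:
                centers[0] = cand
                break
            d = np.hypot(*(centers[:i] - cand).T)
            if np.all(d >= radii[:i] + r + min_gap_px):
                centers[i] = cand
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n} after {max_tries_per_cell} tries",
                i,
            )
    return centers, radii


def rasterize_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Paint disks into an int32 label raster (later disks overwrite earlier)."""
    out = np.zeros(shape, dtype=np.int32)
    if len(centers) == 0:
        return out
    if labels is None:
        labels = np.arange(1, len(centers) + 1)
    for (cr, cc), r, lab in zip(centers, radii, labels):
        r0, r1 = max(int(cr - r) - 1, 0), min(int(cr + r) + 2, shape[0])
        c0, c1 = max(int(cc - r) - 1, 0), min(int(cc + r) + 2, shape[1])
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        mask = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= r * r
        out[r0:r1, c0:c1][mask] = lab
    return out


def add_gaussian_spot(
    canvas: np.ndarray, center: tuple[float, float], sigma_px: float, amplitude: float
) -> None:
    """Add an isotropic Gaussian bump in place (window of +-4 sigma)."""
    cr, cc = center
    w = int(np.ceil(4 * sigma_px))
    r0, r1 = max(int(cr) - w, 0), min(int(cr) + w + 1, canvas.shape[0])
    c0, c1 = max(int(cc) - w, 0), min(int(cc) + w + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - cr) ** 2 + (cc_ - cc) ** 2) / (2 * sigma_px**2)
    )


class BlurredDiskProfile:
    """Radial intensity profile of a unit disk convolved with a Gaussian PSF.

    Models an amplified punctum: a flat-top spot of well-defined area with
    edges softened over the PSF scale. The disk radius is calibrated so the
    area enclosed by the half-maximum contour equals ``area_px2`` (the blur
    shifts the half-max contour slightly inside the nominal disk edge).
    """

    def __init__(self, area_px2: float, psf_sigma_px: float, n_samples: int = 2048):
        from scipy.stats import ncx2

        self.psf_sigma_px = float(psf_sigma_px)
        r_nominal = np.sqrt(area_px2 / np.pi)

        def half_max_radius(disk_r: float) -> float:
            rs = np.linspace(0, disk_r + 5 * psf_sigma_px, 800)
            prof = ncx2.cdf(
                (disk_r / psf_sigma_px) ** 2, 2, (rs / psf_sigma_px) ** 2
            )
            return float(np.interp(-0.5, -prof, rs))

        # one bisection step family: scale disk radius so pi * r_half^2 = area
        disk_r = r_nominal
        for _ in range(30):
            rh = half_max_radius(disk_r)
            if abs(rh - r_nominal) < 1e-4:
                break
            disk_r += r_nominal - rh
        self.disk_radius_px = disk_r
        self.extent_px = disk_r + 4 * psf_sigma_px
        rs = np.linspace(0.0, self.extent_px, n_samples)
        from scipy.stats import ncx2 as _ncx2

        self._rs = rs
        self._profile = _ncx2.cdf(
            (disk_r / psf_sigma_px) ** 2, 2, (rs / psf_sigma_px) ** 2
        )

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return np.interp(r, self._rs, self._profile, right=0.0)


def add_disk_spot(
    canvas: np.ndarray,
    center: tuple[float, float],
    profile: BlurredDiskProfile,
    amplitude: float,
) -> None:
    """Add a blurred-disk punctum in place (intensities are additive)."""
    cr, cc = center
    w = int(np.ceil(profile.extent_px))
    r0, r1 = max(int(cr) - w, 0), min(int(cr) + w + 1, canvas.shape[0])
    c0, c1 = max(int(cc) - w, 0), min(int(cc) + w + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    r = np.hypot(rr - cr, cc_ - cc)
    canvas[r0:r1, c0:c1] += amplitude * profile(r)
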