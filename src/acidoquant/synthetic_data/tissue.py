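"""Synthetic in situ hybridization tissue fields with per-cell ground truth.

A field is a set of non-overlapping nuclei, each surrounded by a cell
territory (all pixels nearer to that nucleus than to any other, out to a
configured growth distance). Each transcript appears as an amplified punctum:
a flat-top disk whose half-maximum contour encloses the configured unit dot
area (6 µm² by default), with edges softened by a Gaussian PSF; intensities of
overlapping puncta add. Optional clustering places a new dot adjacent to an
existing one (centre offset of 0.5-1 dot diameters), producing the fused
signal clusters that area-based dot estimation is designed to handle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..images import Image2D, LabelMap
from ._placement import (
    BlurredDiskProfile,
    PlacementError,
    add_disk_spot,
    rasterize_disks,
    sample_nucleus_layout,
)

__all__ = [
    "CountDistribution",
    "ChannelSpec",
    "TissueSimConfig",
    "TissueField",
    "simulate_tissue_field",
    "simulate_coexpression_counts",
    "PlacementError",
]


@dataclass(frozen=True)
class CountDistribution:
    """Per-cell dot-count distribution: constant, Poisson, or negative binomial.

    For the negative binomial, ``dispersion`` is the gamma shape parameter, so
    variance = mean + mean^2 / dispersion.
    """

    family: str = "negbin"
    mean: float = 7.0
    dispersion: float = 0.8

    def __post_init__(self) -> None:
        if self.family not in ("constant", "poisson", "negbin"):
            raise ValueError(f"unknown count family {self.family!r}")
        if self.mean < 0:
            raise ValueError("mean must be non-negative")
        if self.family == "negbin" and self.dispersion <= 0:
            raise ValueError("negbin dispersion must be positive")

    def sample(self, rng: np.random.Generator, n: int, zero_truncated: bool = False) -> np.ndarray:
        if self.family == "constant":
            counts = np.full(n, int(round(self.mean)))
        elif self.family == "poisson":
            counts = rng.poisson(self.mean, size=n)
        else:
            lam = rng.gamma(self.dispersion, self.mean / self.dispersion, size=n)
            counts = rng.poisson(lam)
        if zero_truncated and self.mean > 0:
            for _ in range(1000):
                zeros = counts == 0
                if not zeros.any():
                    break
                counts[zeros] = self.sample(rng, int(zeros.sum()), zero_truncated=False)
            else:  # pragma: no cover - pathological parameters
                counts[counts == 0] = 1
        return counts.astype(int)


@dataclass(frozen=True)
class ChannelSpec:
    """One signal channel: probe name, positivity rate, and count distribution."""

    name: str = "PACC1"
    fraction_positive: float = 0.85
    dots: CountDistribution = field(default_factory=CountDistribution)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValueError("fraction_positive must be in [0, 1]")


@dataclass(frozen=True)
class TissueSimConfig:
    """Study conditions for a simulated tissue field.

    ``cell_radius_um`` gives the territory radius (mean, sd) measured from the
    nucleus centroid; territory growth beyond the nucleus boundary is
    cell_radius - nucleus_radius (means), perturbed per cell by the cell sd.
    The default sd of 0 keeps growth uniform, matching the single growth-radius
    parameter the segmentation stage uses.
    """

    n_cells: int = 200
    field_size_px: tuple[int, int] = (896, 896)
    pixel_size_um: float = 0.5
    nucleus_radius_um: tuple[float, float] = (4.0, 0.4)
    cell_radius_um: tuple[float, float] = (12.0, 0.0)
    channels: tuple[ChannelSpec, ...] = (ChannelSpec(),)
    dot_area_um2: float = 6.0
    dot_psf_sigma_um: float = 0.65
    cluster_probability: float = 0.0
    dot_min_separation_um: float | None = None
    dot_amplitude: float = 1.0
    nucleus_amplitude: float = 1.0
    background_level: float = 0.1
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.pixel_size_um <= 0 or self.dot_area_um2 <= 0:
            raise ValueError("lengths and areas must be positive")
        if self.nucleus_radius_um[0] <= 0 or self.cell_radius_um[0] <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 <= self.cluster_probability <= 1.0:
            raise ValueError("cluster_probability must be in [0, 1]")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background and noise must be non-negative")



@dataclass
class TissueField:
    """A simulated field plus generator-side ground truth (for tests only)."""

    channels: dict[str, Image2D]
    nuclei_truth: LabelMap
    territory_truth: LabelMap
    truth: pd.DataFrame
    config: TissueSimConfig


def _territories(
    nuclei: np.ndarray, grow_px: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-nucleus partition out to a per-label growth distance (pixels)."""
    dist, (ir, ic) = ndimage.distance_transform_edt(nuclei == 0, return_indices=True)
    nearest = nuclei[ir, ic]
    reach = np.zeros(int(nuclei.max()) + 1)
    reach[1:] = grow_px
    territory = np.where(dist <= reach[nearest], nearest, 0).astype(np.int32)
    return territory, dist


def _touches_border(labels: np.ndarray) -> set[int]:
    edge = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    return set(np.unique(edge[edge > 0]).tolist())


def simulate_tissue_field(config: TissueSimConfig) -> TissueField:
    """Render a multi-channel field of nucleated cells with known dot counts.

    Returns the channel images (a ``"nuclei"`` channel plus one per
    :class:`ChannelSpec`), the true nucleus and territory label maps, and a
    per-cell truth table with one row per simulated cell.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.field_size_px
    px = config.pixel_size_um
    n = config.n_cells

    truth_cols = ["cell_id", "row", "col", "nucleus_radius_px", "touches_border"]
    for ch in config.channels:
        truth_cols += [f"positive_{ch.name}", f"dots_{ch.name}"]

    if n == 0:
        empty = np.zeros((rows, cols))
        channels = {"nuclei": Image2D(_finish(empty, config, rng), px)}
        for ch in config.channels:
            channels[ch.name] = Image2D(_finish(np.zeros((rows, cols)), config, rng), px)
        return TissueField(
            channels,
            LabelMap(np.zeros((rows, cols), np.int32), px),
            LabelMap(np.zeros((rows, cols), np.int32), px),
            pd.DataFrame(columns=truth_cols),
            config,
        )

    nuc_mean_px = config.nucleus_radius_um[0] / px
    nuc_sd_px = config.nucleus_radius_um[1] / px
    centers, radii = sample_nucleus_layout(rng, n, (rows, cols), nuc_mean_px, nuc_sd_px)
    nuclei = rasterize_disks((rows, cols), centers, radii)

    grow_um = config.cell_radius_um[0] - config.nucleus_radius_um[0]
    if grow_um <= 0:
        raise ValueError("cell radius must exceed nucleus radius")
    grow_px = np.maximum(
        (grow_um + rng.normal(0.0, config.cell_radius_um[1], size=n)) / px, 1.0
    )
    territory, _ = _territories(nuclei, grow_px)
    border = _touches_border(territory)

    profile = BlurredDiskProfile(
        config.dot_area_um2 / px**2, config.dot_psf_sigma_um / px
    )
    r_half_px = np.sqrt(config.dot_area_um2 / np.pi) / px
    pad_px = int(np.ceil(r_half_px)) + 1
    diameter_px = 2 * r_half_px

    # per-cell interior pixels (territory eroded so supra-threshold dot area
    # stays inside the territory)
    objects = ndimage.find_objects(territory)

    records = []
    signal = {ch.name: np.zeros((rows, cols)) for ch in config.channels}
    for i in range(1, n + 1):
        rec = {
            "cell_id": i,
            "row": centers[i - 1][0],
            "col": centers[i - 1][1],
            "nucleus_radius_px": radii[i - 1],
            "touches_border": i in border,
        }
        sl = objects[i - 1]
        interior_coords = None
        if sl is not None:
            local = territory[sl] == i
            interior = ndimage.distance_transform_edt(local) >= pad_px
            if not interior.any():
                interior = local
            rr, cc = np.nonzero(interior)
            interior_coords = np.column_stack(
                [rr + sl[0].start, cc + sl[1].start]
            ).astype(float)
        for ch in config.channels:
            positive = bool(rng.random() < ch.fraction_positive)
            count = 0
            if positive and interior_coords is not None and len(interior_coords) > 0:
                count = int(ch.dots.sample(rng, 1, zero_truncated=True)[0])
                min_sep_px = (
                    config.dot_min_separation_um / px
                    if config.dot_min_separation_um
                    else 0.0
                )
                _render_dots(
                    signal[ch.name],
                    interior_coords,
                    count,
                    config.cluster_probability,
                    diameter_px,
                    profile,
                    config.dot_amplitude,
                    rng,
                    min_sep_px,
                )
            rec[f"positive_{ch.name}"] = positive and count > 0
            rec[f"dots_{ch.name}"] = count
        records.append(rec)

    nuclei_img = (nuclei > 0).astype(float) * config.nucleus_amplitude
    channels = {"nuclei": Image2D(_finish(nuclei_img, config, rng), px)}
    for ch in config.channels:
        channels[ch.name] = Image2D(_finish(signal[ch.name], config, rng), px)

    return TissueField(
        channels,
        LabelMap(nuclei, px),
        LabelMap(territory, px),
        pd.DataFrame.from_records(records, columns=truth_cols),
        config,
    )


def _render_dots(
    canvas: np.ndarray,
    interior_coords: np.ndarray,
    count: int,
    cluster_probability: float,
    diameter_px: float,
    profile: BlurredDiskProfile,
    amplitude: float,
    rng: np.random.Generator,
    min_sep_px: float = 0.0,
) -> None:
    coord_set = {(int(r), int(c)) for r, c in interior_coords}
    placed: list[np.ndarray] = []
    for _ in range(count):
        center = None
        if placed and rng.random() < cluster_probability:
            anchor = placed[rng.integers(len(placed))]
            for _ in range(20):
                ang = rng.uniform(0, 2 * np.pi)
                # adjacent placement: centre offset between half and one dot
                # diameter, so clustered dots touch or partially fuse rather
                # than stack on top of each other
                rad = diameter_px * rng.uniform(0.5, 1.0)
                cand = anchor + rad * np.array([np.sin(ang), np.cos(ang)])
                if (int(round(cand[0])), int(round(cand[1]))) in coord_set:
                    center = cand
                    break
        if center is None:
            for _ in range(200):
                base = interior_coords[rng.integers(len(interior_coords))]
                cand = base + rng.uniform(-0.5, 0.5, size=2)
                if min_sep_px <= 0 or all(
                    np.hypot(*(cand - p)) >= min_sep_px for p in placed
                ):
                    center = cand
                    break
            else:
                base = interior_coords[rng.integers(len(interior_coords))]
                center = base + rng.uniform(-0.5, 0.5, size=2)
        placed.append(center)
        add_disk_spot(canvas, (center[0], center[1]), profile, amplitude)


def _finish(img: np.ndarray, config: TissueSimConfig, rng: np.random.Generator) -> np.ndarray:
    out = img + config.background_level
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(out, 0.0, None)


def simulate_coexpression_counts(
    n_cells: int,
    mean_a: float,
    mean_b: float,
    shared_dispersion: float | None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cell counts for two probes sharing a latent expression factor.

    Counts are Poisson with rates mean * L where L ~ Gamma(shape=d, scale=1/d)
    is shared between channels (``shared_dispersion=d``); pass ``None`` for
    independent channels. Returns (counts_a, counts_b, construction_pearson),
    the latter from the closed-form moments of the mixture.
    """
    rng = np.random.default_rng(seed)
    if shared_dispersion is None:
        a = rng.poisson(mean_a, n_cells)
        b = rng.poisson(mean_b, n_cells)
        return a, b, 0.0
    d = shared_dispersion
    lat = rng.gamma(d, 1.0 / d, size=n_cells)
    a = rng.poisson(mean_a * lat)
    b = rng.poisson(mean_b * lat)
    v = 1.0 / d
    rho = (mean_a * mean_b * v) / np.sqrt(
        (mean_a + mean_a**2 * v) * (mean_b + mean_b**2 * v)
    )
    return a, b, float(rho)
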