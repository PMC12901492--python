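"""Synthetic Hoechst/propidium-iodide viability fields.

All nuclei appear in the Hoechst channel; each nucleus is dead with the
configured Bernoulli probability and, if dead, its propidium-iodide (PI)
intensity is drawn from the PI-positive distribution, otherwise from the
PI-negative one. The two distributions are required to be separable at the
configured defaults so the scoring threshold is well posed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..images import Image2D, LabelMap
from ._placement import rasterize_disks, sample_nucleus_layout

__all__ = ["DeathSimConfig", "DeathField", "simulate_death_field"]


@dataclass(frozen=True)
class DeathSimConfig:
    n_nuclei: int = 250
    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    nucleus_radius_um: tuple[float, float] = (3.0, 0.3)
    death_probability: float = 0.3
    pi_positive_level: tuple[float, float] = (0.6, 0.1)
    pi_negative_level: tuple[float, float] = (0.05, 0.02)
    hoechst_amplitude: float = 1.0
    background_level: float = 0.05
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.death_probability <= 1.0:
            raise ValueError("death_probability must be in [0, 1]")
        mp, sp = self.pi_positive_level
        mn, sn = self.pi_negative_level
        if mp - 2 * sp <= mn + 2 * sn:
            raise ValueError("PI-positive and PI-negative intensities must be separable")
        if self.n_nuclei < 0 or self.pixel_size_um <= 0:
            raise ValueError("invalid geometry")


@dataclass
class DeathField:
    hoechst: Image2D
    pi: Image2D
    nuclei_truth: LabelMap
    truth: pd.DataFrame
    config: DeathSimConfig


def simulate_death_field(config: DeathSimConfig) -> DeathField:
    rng = np.random.default_rng(config.seed)
    rows, cols = config.field_size_px
    px = config.pixel_size_um
    n = config.n_nuclei

    if n == 0:
        zero = np.zeros((rows, cols))
        return DeathField(
            Image2D(_finish(zero, config, rng), px),
            Image2D(_finish(zero, config, rng), px),
            LabelMap(np.zeros((rows, cols), np.int32), px),
            pd.DataFrame(columns=["cell_id", "row", "col", "dead", "pi_level"]),
            config,
        )

    centers, radii = sample_nucleus_layout(
        rng, n, (rows, cols), config.nucleus_radius_um[0] / px, config.nucleus_radius_um[1] / px
    )
    nuclei = rasterize_disks((rows, cols), centers, radii)

    dead = rng.random(n) < config.death_probability
    mp, sp = config.pi_positive_level
    mn, sn = config.pi_negative_level
    pi_levels = np.where(
        dead,
        np.clip(rng.normal(mp, sp, size=n), 0, None),
        np.clip(rng.normal(mn, sn, size=n), 0, None),
    )

    hoechst = (nuclei > 0).astype(float) * config.hoechst_amplitude
    level_lut = np.zeros(n + 1)
    level_lut[1:] = pi_levels
    pi = level_lut[nuclei]

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "dead": dead,
            "pi_level": pi_levels,
        }
    )
    return DeathField(
        Image2D(_finish(hoechst, config, rng), px),
        Image2D(_finish(pi, config, rng), px),
        LabelMap(nuclei, px),
        truth,
        config,
    )


def _finish(img: np.ndarray, config: DeathSimConfig, rng: np.random.Generator) -> np.ndarray:
    out = img + config.background_level
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(out, 0.0, None)
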