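"""Synthetic dual-transferrin flow-cytometry samples.

Each event carries a pH-insensitive reference intensity (AF633-transferrin,
lognormal across cells), a pH-sensitive FITC-transferrin intensity whose
expected ratio to the reference follows a logistic function of endosomal pH
(fluorescein-like pKa), and an mCherry transfection-reporter intensity. The
generator emits calibration samples at known buffer pHs and experimental
samples at configured true pHs, with untransfected events carrying their own
(typically more acidic) pH so that reporter gating matters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FitcPhResponse", "CytometrySimConfig", "CytometrySim", "simulate_cytometry"]


@dataclass(frozen=True)
class FitcPhResponse:
    """Logistic pH -> expected FITC/AF633 ratio, increasing with pH."""

    pka: float = 6.4
    slope: float = 1.0
    ratio_max: float = 2.0
    ratio_min: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.ratio_max <= self.ratio_min:
            raise ValueError("response must be strictly increasing in pH")

    def __call__(self, pH: float | np.ndarray) -> float | np.ndarray:
        return self.ratio_min + (self.ratio_max - self.ratio_min) / (
            1.0 + 10.0 ** (self.slope * (self.pka - np.asarray(pH, dtype=float)))
        )


@dataclass(frozen=True)
class CytometrySimConfig:
    n_events: int = 10_000
    true_pH: dict[str, float] = field(
        default_factory=lambda: {"parental": 5.30, "KO": 4.63, "V1": 5.68, "V2": 5.85}
    )
    calibration_pHs: tuple[float, ...] = (7.4, 6.5, 5.5, 4.5)
    af633_lognormal_params: tuple[float, float] = (np.log(5000.0), 0.4)
    fitc_ph_response: FitcPhResponse = field(default_factory=FitcPhResponse)
    transfected_fraction: float = 1.0
    untransfected_pH: float = 4.7
    mcherry_positive_level: tuple[float, float] = (5000.0, 0.3)
    mcherry_negative_level: tuple[float, float] = (50.0, 0.3)
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if len(self.calibration_pHs) < 2:
            raise ValueError("need at least two calibration pHs")
        diffs = np.diff(self.calibration_pHs)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("calibration_pHs must be strictly monotone")
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        grid = np.linspace(4.0, 7.5, 50)
        if np.any(np.diff(self.fitc_ph_response(grid)) <= 0):
            raise ValueError("fitc_ph_response must be strictly increasing over [4, 7.5]")


@dataclass
class CytometrySim:
    calibration: dict[float, pd.DataFrame]
    samples: dict[str, pd.DataFrame]
    control: pd.DataFrame
    truth: dict


def _noise_sigma(cv: float) -> float:
    # lognormal factor with median exactly 1; sigma chosen so the factor's
    # coefficient of variation equals cv
    return float(np.sqrt(np.log(1.0 + cv**2)))


def _events(
    rng: np.random.Generator,
    config: CytometrySimConfig,
    pH_per_event: np.ndarray,
    transfected: np.ndarray,
    sample_id: str,
) -> pd.DataFrame:
    n = len(pH_per_event)
    mu, sg = config.af633_lognormal_params
    af633 = rng.lognormal(mu, sg, size=n)
    s = _noise_sigma(config.noise_cv)
    factor = np.exp(rng.normal(0.0, s, size=n)) if s > 0 else np.ones(n)
    fitc = np.asarray(config.fitc_ph_response(pH_per_event)) * af633 * factor
    lvl_p, sd_p = config.mcherry_positive_level
    lvl_n, sd_n = config.mcherry_negative_level
    mcherry = np.where(
        transfected,
        rng.lognormal(np.log(lvl_p), sd_p, size=n),
        rng.lognormal(np.log(lvl_n), sd_n, size=n),
    )
    return pd.DataFrame(
        {"fitc": fitc, "af633": af633, "mcherry": mcherry, "sample_id": sample_id}
    )


def simulate_cytometry(config: CytometrySimConfig) -> CytometrySim:
    """Generate calibration, experimental, and untransfected-control tables."""
    rng = np.random.default_rng(config.seed)
    n = config.n_events

    calibration = {}
    for pH in config.calibration_pHs:
        # calibration cells are untransfected wild type equilibrated at the buffer pH
        calibration[pH] = _events(
            rng, config, np.full(n, pH), np.zeros(n, bool), f"calib_{pH:g}"
        )

    samples = {}
    for sample_id, pH in config.true_pH.items():
        transfected = rng.random(n) < config.transfected_fraction
        pHs = np.where(transfected, pH, config.untransfected_pH)
        samples[sample_id] = _events(rng, config, pHs, transfected, sample_id)

    control = _events(
        rng, config, np.full(n, config.untransfected_pH), np.zeros(n, bool), "control"
    )

    truth = {
        "true_pH": dict(config.true_pH),
        "transfected_fraction": config.transfected_fraction,
        "expected_ratio": {k: float(config.fitc_ph_response(v)) for k, v in config.true_pH.items()},
        "calibration_ratio": {
            pH: float(config.fitc_ph_response(pH)) for pH in config.calibration_pHs
        },
    }
    return CytometrySim(calibration, samples, control, truth)
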