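"""Synthetic HS-YFP quench time courses.

Each well records ``duration_s`` seconds at ``sample_interval_s``; the first
``baseline_s`` seconds precede the iodide injection. After injection the
normalized model fluorescence decays exponentially to a plateau with a rate
constant set so that the initial slope magnitude equals a Hill function of
the extracellular pH. Raw traces carry an instrument background and scale so
that normalization is a real operation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..quench_kinetics import Trace, hill_rate

__all__ = ["TraceSimConfig", "TraceSet", "simulate_traces"]


@dataclass(frozen=True)
class TraceSimConfig:
    duration_s: float = 14.0
    baseline_s: float = 2.0
    sample_interval_s: float = 0.2
    pH_values: tuple[float, ...] = (7.5, 6.5, 6.0, 5.8, 5.5, 5.2, 4.8, 4.2)
    hill_pH50: float = 5.5
    hill_n: float = 2.0
    rate_max: float = 0.23
    plateau_fraction: float = 0.15
    noise_sd: float = 0.02
    n_replicate_wells: int = 3
    amplitude: float = 1000.0
    background: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_s < self.duration_s:
            raise ValueError("baseline must be positive and shorter than the trace")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")
        if not 0.0 <= self.plateau_fraction < 1.0:
            raise ValueError("plateau_fraction must be in [0, 1)")
        if self.hill_n <= 0 or self.rate_max < 0 or self.noise_sd < 0:
            raise ValueError("hill_n must be > 0; rate_max and noise_sd non-negative")


@dataclass
class TraceSet:
    traces: list[Trace]
    truth: pd.DataFrame
    config: TraceSimConfig


def model_curve(t: np.ndarray, config: TraceSimConfig, pH: float) -> np.ndarray:
    """Noise-free normalized fluorescence for one well."""
    rate = float(hill_rate(pH, config.rate_max, config.hill_pH50, config.hill_n))
    p = config.plateau_fraction
    k = rate / (1.0 - p)
    out = np.ones_like(t)
    post = t >= config.baseline_s
    out[post] = p + (1.0 - p) * np.exp(-k * (t[post] - config.baseline_s))
    return out


def simulate_traces(config: TraceSimConfig) -> TraceSet:
    """Generate raw traces for every (pH, replicate well) with rate truth."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration_s + 1e-9, config.sample_interval_s)
    traces: list[Trace] = []
    records = []
    for pH in config.pH_values:
        rate = float(hill_rate(pH, config.rate_max, config.hill_pH50, config.hill_n))
        k = rate / (1.0 - config.plateau_fraction)
        for rep in range(config.n_replicate_wells):
            norm = model_curve(t, config, pH)
            if config.noise_sd > 0:
                norm = norm + rng.normal(0.0, config.noise_sd, size=t.size)
            raw = config.background + config.amplitude * norm
            well = f"pH{pH:g}_r{rep}"
            traces.append(Trace(t, raw, config.baseline_s, well, pH))
            records.append(
                {
                    "well_id": well,
                    "pH": pH,
                    "replicate": rep,
                    "true_rate": rate,
                    "true_k": k,
                    "true_plateau": config.plateau_fraction,
                }
            )
    return TraceSet(traces, pd.DataFrame.from_records(records), config)
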