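"""Ratiometric endosomal pH from dual-transferrin flow cytometry.

Workflow: gate transfected events on the reporter channel against an
untransfected control, compute each sample's central (median) FITC/AF633
ratio, build a standard curve from calibration samples equilibrated at known
pHs, and invert it to absolute pH.

The default inverse interpolation is piecewise linear in (log10 ratio -> pH):
for a pH-sensitive fluorophore with a logistic pH response, log-ratio is
nearly linear in pH below the pKa, so log-space interpolation between the
calibration buffers tracks the underlying response far more closely than
interpolation in the raw ratio (which is convex between nodes and biases
interpolated pH downward by up to ~0.2 with a 4-point curve). Plain-ratio and
4-parameter sigmoid fits remain available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CalibrationCurve",
    "PhResult",
    "gate_transfected",
    "event_ratios",
    "build_calibration",
    "interpolate_pH",
]

_REQUIRED = ("fitc", "af633", "mcherry")


def _check_table(events: pd.DataFrame, name: str = "events") -> None:
    for col in _REQUIRED:
        if col not in events.columns:
            raise ValueError(f"{name} table lacks required column {col!r}")


def gate_transfected(
    events: pd.DataFrame, control: pd.DataFrame, percentile: float = 99.0
) -> pd.DataFrame:
    """Keep events whose reporter intensity exceeds the control percentile.

    The gate value (the given percentile of the untransfected control's
    mcherry distribution) is recorded in ``DataFrame.attrs['mcherry_gate']``.
    """
    _check_table(events)
    _check_table(control, "control")
    if len(control) == 0:
        raise ValueError("empty control table")
    gate = float(np.percentile(control["mcherry"], percentile))
    out = events[events["mcherry"] > gate].copy()
    out.attrs["mcherry_gate"] = gate
    return out


def event_ratios(events: pd.DataFrame, af633_floor_fraction: float = 0.01) -> np.ndarray:
    """Per-event FITC/AF633 ratios, excluding events with a dim reference.

    Events whose AF633 intensity is below ``af633_floor_fraction`` times the
    sample median are excluded to avoid ratio blow-ups.
    """
    _check_table(events)
    if len(events) == 0:
        raise ValueError("no events")
    af = events["af633"].to_numpy(dtype=float)
    floor = af633_floor_fraction * float(np.median(af))
    keep = af > max(floor, 0.0)
    if not keep.any():
        raise ValueError("no events with usable reference intensity")
    return events["fitc"].to_numpy(dtype=float)[keep] / af[keep]


@dataclass
class CalibrationCurve:
    """pH <-> central-ratio standard curve with a chosen inverse interpolation."""

    points: list[tuple[float, float]]  # (pH, median ratio), sorted by pH
    kind: str = "log-linear"

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("need at least 2 calibration points")
        self.points = sorted(self.points)
        ratios = np.array([r for _, r in self.points])
        if np.any(ratios <= 0):
            raise ValueError("calibration ratios must be positive")
        if not (np.all(np.diff(ratios) > 0) or np.all(np.diff(ratios) < 0)):
            raise ValueError(
                "calibration medians are not monotone in pH: "
                + ", ".join(f"pH {p:g} -> {r:.4g}" for p, r in self.points)
            )
        if self.kind == "sigmoid":
            self._sigmoid = _fit_sigmoid(self.points)

    @property
    def pH_range(self) -> tuple[float, float]:
        return self.points[0][0], self.points[-1][0]

    def ratio_to_pH(self, ratio: float) -> tuple[float, bool]:
        """Invert the curve; out-of-range ratios clamp to the nearest node."""
        phs = np.array([p for p, _ in self.points])
        ratios = np.array([r for _, r in self.points])
        if ratios[0] > ratios[-1]:  # make ratios ascending for interp
            phs, ratios = phs[::-1], ratios[::-1]
        lo, hi = ratios[0], ratios[-1]
        clamped = bool(ratio < lo or ratio > hi)
        r = float(np.clip(ratio, lo, hi))
        if self.kind == "linear":
            pH = float(np.interp(r, ratios, phs))
        elif self.kind == "log-linear":
            pH = float(np.interp(np.log10(r), np.log10(ratios), phs))
        elif self.kind == "sigmoid":
            pH = float(self._sigmoid(r))
        else:
            raise ValueError(f"unknown interpolation kind {self.kind!r}")
        return pH, clamped


def _fit_sigmoid(points):
    phs = np.array([p for p, _ in points])
    ratios = np.array([r for _, r in points])

    def model(pH, bottom, top, mid, slope):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (mid - pH)))

    p0 = (ratios.min() * 0.5, ratios.max() * 1.2, float(np.median(phs)), 1.0)
    popt, _ = optimize.curve_fit(model, phs, ratios, p0=p0, maxfev=10000)

    def invert(r: float) -> float:
        res = optimize.brentq(
            lambda pH: model(pH, *popt) - r, phs.min() - 2, phs.max() + 2
        )
        return res

    return invert


@dataclass
class PhResult:
    sample_id: str
    n_events_gated: int
    central_ratio: float
    pH: float
    clamped: bool
    mcherry_gate: float | None = None


def build_calibration(
    calib_tables: dict[float, pd.DataFrame],
    kind: str = "log-linear",
    af633_floor_fraction: float = 0.01,
) -> CalibrationCurve:
    """Median-ratio standard curve from one event table per calibration pH.

    Construction fails with a diagnostic when the medians are not strictly
    monotone in pH. Input order is irrelevant; points are sorted internally.
    """
    points = []
    for pH, table in calib_tables.items():
        ratios = event_ratios(table, af633_floor_fraction)
        points.append((float(pH), float(np.median(ratios))))
    return CalibrationCurve(points, kind=kind)


def interpolate_pH(
    sample: pd.DataFrame,
    curve: CalibrationCurve,
    sample_id: str | None = None,
    af633_floor_fraction: float = 0.01,
) -> PhResult:
    """Map a gated sample's median ratio to pH via the standard curve."""
    ratios = event_ratios(sample, af633_floor_fraction)
    central = float(np.median(ratios))
    pH, clamped = curve.ratio_to_pH(central)
    if sample_id is None:
        ids = sample["sample_id"].unique() if "sample_id" in sample else []
        sample_id = str(ids[0]) if len(ids) else ""
    return PhResult(
        sample_id=sample_id,
        n_events_gated=len(sample),
        central_ratio=central,
        pH=pH,
        clamped=clamped,
        mcherry_gate=sample.attrs.get("mcherry_gate"),
    )
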