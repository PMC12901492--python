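"""Acid-induced cell-death scoring from Hoechst/PI image pairs.

Nuclei are detected on the Hoechst channel; each nucleus's mean propidium-
iodide intensity classifies it as dead (PI-positive) or live. The PI
threshold is either fixed or derived by an automatic two-class (Otsu) split
over per-nucleus mean intensities — preferably pooled across a plate so both
classes are represented (Otsu on a single all-live or all-dead field would
split a unimodal distribution).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .image_segmentation import detect_nuclei
from .images import Image2D, LabelMap
from .stats_report import compare_groups

__all__ = [
    "DeathAssayResult",
    "nucleus_pi_means",
    "pooled_pi_threshold",
    "score_death",
    "death_dose_response",
]


@dataclass
class DeathAssayResult:
    condition_id: str
    n_nuclei: int
    n_pi_positive: int
    death_fraction: float
    pi_threshold_used: float


def nucleus_pi_means(
    hoechst: Image2D,
    pi: Image2D,
    nuclear_threshold="otsu",
    min_nucleus_area_um2: float = 10.0,
) -> tuple[np.ndarray, LabelMap]:
    """Detect nuclei on Hoechst and return each nucleus's mean PI intensity."""
    if hoechst.shape != pi.shape:
        raise ValueError("Hoechst and PI shapes differ")
    nuclei = detect_nuclei(hoechst, nuclear_threshold, min_nucleus_area_um2)
    ids = nuclei.label_ids
    if ids.size == 0:
        return np.empty(0), nuclei
    means = ndimage.mean(pi.pixels, labels=nuclei.labels, index=ids)
    return np.asarray(means, dtype=float), nuclei


def pooled_pi_threshold(per_nucleus_means: np.ndarray) -> float:
    """Otsu split over pooled per-nucleus mean PI intensities."""
    values = np.asarray(per_nucleus_means, dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("cannot derive a threshold from fewer than two distinct values")
    return float(threshold_otsu(values))


def score_death(
    hoechst: Image2D,
    pi: Image2D,
    pi_threshold: float | str = "otsu",
    condition_id: str = "",
    nuclear_threshold="otsu",
    min_nucleus_area_um2: float = 10.0,
) -> DeathAssayResult:
    """Score one field: fraction of nuclei whose mean PI exceeds the threshold.

    ``pi_threshold`` is a fixed intensity (recommended: derive it once from
    per-nucleus means pooled across the plate with
    :func:`pooled_pi_threshold`) or ``"otsu"`` to split within this field.
    """
    means, _ = nucleus_pi_means(hoechst, pi, nuclear_threshold, min_nucleus_area_um2)
    if means.size == 0:
        raise ValueError("no nuclei detected")
    thr = pooled_pi_threshold(means) if pi_threshold == "otsu" else float(pi_threshold)
    n_pos = int((means > thr).sum())
    return DeathAssayResult(
        condition_id=condition_id,
        n_nuclei=int(means.size),
        n_pi_positive=n_pos,
        death_fraction=n_pos / means.size,
        pi_threshold_used=thr,
    )


def death_dose_response(results: list[DeathAssayResult]) -> dict:
    """Summarize replicate fields per (condition, pH) and test across conditions.

    ``condition_id`` is expected as ``"<condition>@<pH>"``. Per group the mean
    and SEM (sd/sqrt(n) over fields) of the death fraction are reported; at
    each pH with >= 2 conditions of >= 2 replicates, conditions are compared
    by two-tailed t-test (2 groups) or one-way ANOVA with Tukey post hoc.
    """
    rows = []
    for r in results:
        cond, _, ph = r.condition_id.partition("@")
        rows.append(
            {"condition": cond, "pH": float(ph) if ph else np.nan, "fraction": r.death_fraction}
        )
    frame = pd.DataFrame(rows)
    summary = (
        frame.groupby(["condition", "pH"], dropna=False)["fraction"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
            n="count",
        )
        .reset_index()
    )
    tests = {}
    for ph, sub in frame.groupby("pH"):
        groups = {
            cond: g["fraction"].to_numpy()
            for cond, g in sub.groupby("condition")
            if len(g) >= 2
        }
        if len(groups) >= 2:
            try:
                tests[float(ph)] = compare_groups(groups)
            except ValueError:
                continue
    return {"summary": summary, "tests": tests}
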