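"""Group comparison recipe and report assembly.

The testing recipe: Kolmogorov–Smirnov normality screening per group, then a
two-tailed Student's t-test for two groups or one-way ANOVA followed by
Tukey's post hoc test for more. Groups failing the normality screen are
flagged but the parametric test still runs (no silent nonparametric
fallback). The KS statistic is computed against a normal with the group's
sample mean and sd; with estimated parameters the p-value is approximate
(anticonservative), which is why it is used only as a flag.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["StatReport", "compare_groups", "sem", "render_report"]


def sem(values: np.ndarray) -> float:
    """Standard error of the mean, sd/sqrt(n) with ddof=1."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


@dataclass
class StatReport:
    test_name: str
    groups: list[str]
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    alpha: float
    normality: dict[str, dict] = field(default_factory=dict)
    pairwise: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "groups": self.groups,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": self.n_per_group,
            "alpha": self.alpha,
            "normality": self.normality,
            "pairwise": self.pairwise,
        }


def _ks_normality(values: np.ndarray) -> dict:
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        return {"statistic": float("nan"), "p_value": float("nan"), "normal": False}
    stat, p = stats.kstest(values, "norm", args=(mu, sd))
    return {"statistic": float(stat), "p_value": float(p), "normal": bool(p >= 0.05)}


def compare_groups(data: dict[str, np.ndarray], alpha: float = 0.05) -> StatReport:
    """Compare >= 2 numeric groups with the t-test / ANOVA + Tukey recipe."""
    if len(data) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if all(np.ptp(arr) == 0 for arr in arrays.values()):
        raise ValueError("all groups have zero within-group variance")

    names = list(arrays)
    normality = {name: _ks_normality(arr) for name, arr in arrays.items()}
    n_per_group = {name: int(arr.size) for name, arr in arrays.items()}

    if len(arrays) == 2:
        a, b = (arrays[n] for n in names)
        t, p = stats.ttest_ind(a, b)
        if np.allclose(a.mean(), b.mean()) and np.isnan(p):
            t, p = 0.0, 1.0
        return StatReport(
            "t_two_tailed", names, float(t), float(p), n_per_group, alpha, normality
        )

    f, p = stats.f_oneway(*arrays.values())
    tukey = stats.tukey_hsd(*arrays.values())
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "difference": float(arrays[names[i]].mean() - arrays[names[j]].mean()),
                    "p_value": float(tukey.pvalue[i, j]),
                }
            )
    return StatReport(
        "anova_tukey", names, float(f), float(p), n_per_group, alpha, normality, pairwise
    )


def render_report(
    out_dir: str | Path,
    sections: dict[str, dict],
    manifest: dict | None = None,
    make_plots: bool = True,
) -> Path:
    """Write a machine-readable JSON report (plus optional summary plots).

    ``sections`` maps a section name to a JSON-serializable payload; empty
    sections are omitted. ``manifest`` (configs, seeds, versions) is stored
    alongside so a run can be reproduced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {name: sec for name, sec in sections.items() if sec}
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(payload, indent=2, default=_jsonable, sort_keys=True) + "\n")
    if manifest is not None:
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_jsonable, sort_keys=True) + "\n"
        )
    if make_plots:
        _plot_sections(out_dir, payload)
    return report_path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, StatReport):
        return obj.to_dict()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _plot_sections(out_dir: Path, payload: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, sec in payload.items():
        series = sec.get("plot_series") if isinstance(sec, dict) else None
        if not series:
            continue
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        for label, (x, y) in series.items():
            ax.plot(x, y, marker="o", label=label)
        ax.set_title(name)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / f"{name}.png", dpi=120)
        plt.close(fig)
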