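"""BF-versus-EF statistical comparison of vessel and hydraulic parameters.

The two identification criteria are compared segment by segment: conductive
vessel counts per xylem type, mean diameters, theoretical conductivity
K_ht, specific conductivities, the per-segment percent ratio
100 * K_h / K_ht (the report stores the mean of per-segment ratios, never
the ratio of means), its coefficient of variation, and the K_h ~ K_ht
ordinary-least-squares regression per criterion.  Paired tests are the
Wilcoxon signed-rank test (exact null for small n, zero differences
discarded) and the paired t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hydraulics import HydraulicSummary


@dataclass
class PairedSample:
    """Values of one parameter under BF (x) and EF (y), paired by segment."""

    labels: Sequence
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.labels) == self.x.size == self.y.size):
            raise ValueError("labels, x and y must have equal length")


def paired_wilcoxon(sample: PairedSample) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; tied magnitudes get mid-ranks.  The
    exact null distribution is used for up to 25 non-zero differences
    without ties, otherwise the normal approximation with continuity
    correction.
    """
    d = sample.x - sample.y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value is degenerate")
        return 0.0, 1.0
    exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
    res = sps.wilcoxon(d, zero_method="wilcox",
                       method="exact" if exact else "approx",
                       correction=not exact)
    return float(res.statistic), float(res.pvalue)


def paired_ttest(sample: PairedSample) -> Tuple[float, float]:
    """Two-sided paired t-test on the differences."""
    d = sample.x - sample.y
    if d.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            warnings.warn("identical samples; t = 0, p = 1 by convention")
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences; p -> 0 limit")
        return math.inf if d.mean() > 0 else -math.inf, 0.0
    res = sps.ttest_rel(sample.x, sample.y)
    return float(res.statistic), float(res.pvalue)


def fit_regression(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """OLS fit y = slope * x + intercept; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def percent_reduction(mean_ref: float, mean_new: float) -> int:
    """Integer percent reduction from a reference mean, half away from zero."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    value = 100.0 * (mean_ref - mean_new) / mean_ref
    return int(math.floor(value + 0.5)) if value >= 0 else int(math.ceil(value - 0.5))


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / math.sqrt(values.size)) if values.size > 1 else float("nan")


@dataclass
class SegmentData:
    """Input bundle for one segment: its summary plus the vessel table."""

    segment_id: str
    segment_type: str  # "apical" or "basal"
    summary: HydraulicSummary
    vessels: Optional[pd.DataFrame] = None  # classified vessel table


@dataclass
class ComparisonReport:
    """All derived BF-vs-EF comparison cells; every cell is recomputable."""

    n_segments: int
    parameter_tables: pd.DataFrame     # mean/SE/n/p per parameter x segment group
    counts: pd.DataFrame               # per-segment conductive counts
    reductions: Dict[str, int]
    ratios: Dict[str, float]
    regressions: Dict[str, Dict[str, float]]
    pooled_diameters: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_segments": self.n_segments,
            "parameter_tables": self.parameter_tables.to_dict(orient="records"),
            "counts": self.counts.to_dict(orient="records"),
            "reductions": self.reductions,
            "ratios": self.ratios,
            "regressions": self.regressions,
            "pooled_diameters": self.pooled_diameters,
        }

    def to_markdown(self) -> str:
        lines = ["# BF vs EF comparison", "",
                 f"Segments: {self.n_segments}", "", "## Parameter summaries", "",
                 self.parameter_tables.to_markdown(index=False), "",
                 "## Conductive-vessel count reductions (EF vs BF, %)", ""]
        lines += [f"- {k}: {v}" for k, v in self.reductions.items()]
        lines += ["", "## K_h / K_ht ratios (%)", ""]
        lines += [f"- {k}: {v:.4g}" for k, v in self.ratios.items()]
        lines += ["", "## K_h ~ K_ht regressions", ""]
        for crit, reg in self.regressions.items():
            lines.append(f"- {crit}: slope {reg['slope']:.4g}, "
                         f"intercept {reg['intercept']:.4g}, R2 {reg['r2']:.4f} "
                         f"(n = {int(reg['n'])})")
        return "\n".join(lines) + "\n"


_PARAMS = ("mean_diameter", "kht", "khs", "khts")


def _paired_rows(segs: List[SegmentData], group: str) -> List[dict]:
    rows = []
    for param in _PARAMS:
        xs, ys, labels = [], [], []
        for s in segs:
            x = getattr(s.summary, f"{param}_bf")
            y = getattr(s.summary, f"{param}_ef")
            if x is None or y is None:
                continue
            xs.append(x)
            ys.append(y)
            labels.append(s.segment_id)
        if len(xs) < 2:
            continue
        xs_a, ys_a = np.asarray(xs), np.asarray(ys)
        sample = PairedSample(labels, xs_a, ys_a)
        try:
            _, p_w = paired_wilcoxon(sample)
        except ValueError:
            p_w = float("nan")
        _, p_t = paired_ttest(sample)
        rows.append({
            "group": group, "parameter": param, "n": len(xs),
            "mean_bf": xs_a.mean(), "se_bf": _sem(xs_a),
            "mean_ef": ys_a.mean(), "se_ef": _sem(ys_a),
            "p_wilcoxon": p_w, "p_ttest": p_t,
        })
    return rows


def compare_bf_ef(segments: List[SegmentData]) -> ComparisonReport:
    """Full BF-vs-EF comparison report over a set of segments.

    Pooled and per-segment-type parameter tables with paired tests, percent
    count reductions computed from the per-segment mean counts, mean +/- SE
    and CV of the per-segment K_h/K_ht percent ratios, and the K_h ~ K_ht
    regression per criterion.  Segments without a K_h are excluded from the
    ratio, CV and regression computations with a warning.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to compare")

    rows = _paired_rows(segments, "pooled")
    for group in ("apical", "basal"):
        rows += _paired_rows([s for s in segments if s.segment_type == group], group)
    parameter_tables = pd.DataFrame(rows)

    count_rows = []
    for s in segments:
        c = s.summary.counts
        count_rows.append({
            "segment_id": s.segment_id, "segment_type": s.segment_type,
            "px_bf": c.get("px_bf", 0), "px_ef": c.get("px_ef", 0),
            "mx_bf": c.get("mx_bf", 0), "mx_ef": c.get("mx_ef", 0),
            "total_bf": c.get("total_bf", 0), "total_ef": c.get("total_ef", 0),
        })
    counts = pd.DataFrame(count_rows)
    reductions = {}
    for key in ("px", "mx", "total"):
        ref = counts[f"{key}_bf"].mean()
        new = counts[f"{key}_ef"].mean()
        if ref > 0:
            reductions[key] = percent_reduction(ref, new)

    usable = [s for s in segments if s.summary.kh is not None]
    dropped = len(segments) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} segment(s) lack K_h and are excluded from "
                      "ratio, CV and regression computations")
    ratios: Dict[str, float] = {}
    regressions: Dict[str, Dict[str, float]] = {}
    for crit in ("bf", "ef"):
        r = np.asarray([getattr(s.summary, f"ratio_{crit}_percent") for s in usable
                        if getattr(s.summary, f"ratio_{crit}_percent") is not None])
        if r.size >= 2:
            ratios[f"mean_{crit}"] = float(r.mean())
            ratios[f"se_{crit}"] = _sem(r)
            ratios[f"cv_{crit}"] = coefficient_of_variation(r)
            ratios[f"n_{crit}"] = int(r.size)
        kht = [getattr(s.summary, f"kht_{crit}") for s in usable]
        kh = [s.summary.kh for s in usable]
        pairs = [(x, y) for x, y in zip(kht, kh) if x is not None and x > 0]
        if len(pairs) >= 3:
            slope, intercept, r2 = fit_regression([p[0] for p in pairs],
                                                  [p[1] for p in pairs])
            regressions[crit] = {"slope": slope, "intercept": intercept,
                                 "r2": r2, "n": len(pairs)}
    if "mean_bf" in ratios and "mean_ef" in ratios:
        ratios["difference_ef_minus_bf"] = ratios["mean_ef"] - ratios["mean_bf"]

    pooled_diam: Dict[str, float] = {}
    tables = [s.vessels for s in segments if s.vessels is not None]
    if tables:
        allv = pd.concat(tables, ignore_index=True)
        for crit in ("bf", "ef"):
            sel = allv[allv[f"conductive_{crit}"].astype(bool)]
            if len(sel):
                pooled_diam[f"mean_{crit}"] = float(sel["diameter_um"].mean())
                pooled_diam[f"n_{crit}"] = int(len(sel))

    return ComparisonReport(
        n_segments=len(segments),
        parameter_tables=parameter_tables,
        counts=counts,
        reductions=reductions,
        ratios=ratios,
        regressions=regressions,
        pooled_diameters=pooled_diam,
    )
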