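#!/usr/bin/env python
"""BF-versus-EF comparison over the simulated cohort.

Aggregates results/hydraulics.csv and the per-segment vessel tables into
the comparison report: conductive-count reductions, Table-1-style parameter
summaries with paired tests, mean +/- SE and CV of the per-segment
K_h/K_ht ratios, and the K_h ~ K_ht regressions under both criteria (with
a scatter figure).  Writes results/report.json, report.md and
fig_kh_kht.png.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from xylemtrace import hydraulics as hyd
from xylemtrace import io as xio
from xylemtrace import stats as xst


def _summary_from_row(row) -> hyd.HydraulicSummary:
    get = lambda k: None if pd.isna(row[k]) else float(row[k])
    return hyd.HydraulicSummary(
        kh=get("kh"), kht_bf=float(row["kht_bf"]), kht_ef=float(row["kht_ef"]),
        total_lumen_area_bf=float(row["total_lumen_area_bf"]),
        total_lumen_area_ef=float(row["total_lumen_area_ef"]),
        khs_bf=get("khs_bf"), khs_ef=get("khs_ef"),
        khts_bf=get("khts_bf"), khts_ef=get("khts_ef"),
        ratio_bf_percent=get("ratio_bf_percent"),
        ratio_ef_percent=get("ratio_ef_percent"),
        mean_diameter_bf=get("mean_diameter_bf"),
        mean_diameter_ef=get("mean_diameter_ef"),
        counts={k: int(row[k]) for k in ("px_bf", "mx_bf", "total_bf",
                                         "px_ef", "mx_ef", "total_ef")})


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    out = Path(args.results)

    hydraulics = pd.read_csv(out / "hydraulics.csv")
    data = []
    for _, row in hydraulics.iterrows():
        vessels_csv = out / f"vessels_{row['segment_id']}.csv"
        vessels = pd.read_csv(vessels_csv) if vessels_csv.exists() else None
        data.append(xst.SegmentData(segment_id=row["segment_id"],
                                    segment_type=row["segment_type"],
                                    summary=_summary_from_row(row),
                                    vessels=vessels))
    report = xst.compare_bf_ef(data)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2,
                                                default=float))
    (out / "report.md").write_text(report.to_markdown())
    print(report.to_markdown())

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping scatter figure")
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    usable = [d for d in data if d.summary.kh is not None]
    for ax, crit in zip(axes, ("bf", "ef")):
        x = [getattr(d.summary, f"kht_{crit}") for d in usable]
        y = [d.summary.kh for d in usable]
        reg = report.regressions[crit]
        ax.scatter(x, y, s=25,
                   c=["k" if d.segment_type == "apical" else "none"
                      for d in usable],
                   edgecolors="k")
        lim = max(max(x), max(y)) * 1.05
        ax.plot([0, lim], [0, lim], "--", color="0.6", lw=1, label="1:1")
        ax.plot([0, lim], [reg["intercept"], reg["intercept"] + reg["slope"] * lim],
                "r-", lw=1, label=f"fit, $R^2$={reg['r2']:.3f}")
        ax.set_xlabel(r"$K_{ht}$ (m$^4$ MPa$^{-1}$ s$^{-1}$)")
        ax.set_title(crit.upper())
        ax.legend(frameon=False)
    axes[0].set_ylabel(r"$K_h$ (m$^4$ MPa$^{-1}$ s$^{-1}$)")
    fig.tight_layout()
    fig.savefig(out / "fig_kh_kht.png", dpi=150)
    print(f"figure -> {out / 'fig_kh_kht.png'}")


if __name__ == "__main__":
    main()
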