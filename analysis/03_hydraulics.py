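#!/usr/bin/env python
"""Per-segment hydraulic summaries for the whole cohort.

Reads every segment's files from results/data/segments/: the flow trace
gives K_h; the classified vessel table (image-measured where a rendered
pair exists — results/vessels_<stem>.csv from script 02 — otherwise
classified directly from the stored ground truth) gives K_ht, lumen areas,
specific conductivities and per-type counts under both criteria.  Writes
results/hydraulics.csv.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from xylemtrace import classification as cls
from xylemtrace import hydraulics as hyd
from xylemtrace import io as xio
from xylemtrace import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data/segments")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    data = Path(args.data)
    out = Path(args.out)
    stems = sorted(p.name[:-len("_truth.json")] for p in data.glob("*_truth.json"))
    if not stems:
        raise SystemExit(f"no segments under {data}; run 01 first")

    rows = []
    for stem in stems:
        measured_csv = out / f"vessels_{stem}.csv"
        if measured_csv.exists():
            records = xio.frame_to_vessels(pd.read_csv(measured_csv))
            source = "image"
        else:
            truth = xio.read_truth(str(data / f"{stem}_truth.json"))
            records = cls.classify_all(sd.records_from_truth(truth))
            source = "truth"
            xio.vessels_to_frame(records).to_csv(measured_csv, index=False)
        trace = xio.read_flow_trace(str(data / f"{stem}_flow.csv"))
        summary = hyd.summarize_segment(records, trace)
        row = {"segment_id": stem,
               "segment_type": "apical" if "apical" in stem else "basal",
               "vessel_source": source}
        row.update({k: v for k, v in dataclasses.asdict(summary).items()
                    if k != "counts"})
        row.update(summary.counts)
        rows.append(row)
        print(f"{stem} ({source}): K_h {summary.kh:.3e}, "
              f"K_ht BF {summary.kht_bf:.3e} / EF {summary.kht_ef:.3e}, "
              f"ratio EF {summary.ratio_ef_percent:.1f}%")

    df = pd.DataFrame(rows)
    df.to_csv(out / "hydraulics.csv", index=False, float_format="%.6e")
    print(f"\nwrote {len(df)} segment summaries -> {out / 'hydraulics.csv'}")


if __name__ == "__main__":
    main()
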