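#!/usr/bin/env python
"""Measure and classify vessels in every rendered section.

For each BF/EF pair under results/data/segments/: detect lumens, measure
wall completeness and stain fraction, apply both conductivity criteria and
assign xylem types; write vessels_<stem>.csv next to the report directory
and print the agreement with the generator's ground truth.
"""

import argparse
import math
from pathlib import Path

from xylemtrace import classification as cls
from xylemtrace import io as xio
from xylemtrace import segmentation as seg


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data/segments")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    data = Path(args.data)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    stems = sorted(p.name[:-len("_bf.tif")] for p in data.glob("*_bf.tif"))
    if not stems:
        raise SystemExit(f"no rendered image pairs under {data}; run 01 first")

    for stem in stems:
        pair = xio.read_image_pair(str(data / stem))
        records = seg.measure_vessels(pair)
        records = cls.classify_all(records, image_center_um=pair.center_um)
        xio.vessels_to_frame(records).to_csv(out / f"vessels_{stem}.csv",
                                             index=False)
        truth = xio.read_truth(str(data / f"{stem}_truth.json"))
        ok_call = ok_type = 0
        for r in records:
            v = min(truth, key=lambda v: math.hypot(v.center[0] - r.centroid[0],
                                                    v.center[1] - r.centroid[1]))
            ok_call += r.conductive_ef == v.true_conductive
            ok_type += r.type == v.type
        n_ef = sum(bool(r.conductive_ef) for r in records)
        print(f"{stem}: {len(records)}/{len(truth)} vessels detected, "
              f"{n_ef} EF-conductive; EF-call agreement "
              f"{100 * ok_call / max(len(records), 1):.1f}%, "
              f"type agreement {100 * ok_type / max(len(records), 1):.1f}%")


if __name__ == "__main__":
    main()
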