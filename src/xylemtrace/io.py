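"""File formats and the end-to-end pipeline runner.

On disk a segment is a file family sharing a stem: ``<stem>_bf.tif`` and
``<stem>_ef.tif`` (16-bit grayscale), ``<stem>_meta.json`` (pixel size,
pressure gradient, segment length, solution density, segment type, seed),
``<stem>_flow.csv`` (columns ``time_s, cumulative_mass_g``) and, for
synthetic data, ``<stem>_truth.json``.  Tabular outputs are UTF-8 CSV with
a header row; conductivities are written in scientific notation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classification, hydraulics, segmentation, stats, synthetic_data
from .classification import ClassificationParams, VesselRecord
from .hydraulics import FlowTrace
from .segmentation import ImagePair, SegmentationParams

log = logging.getLogger(__name__)

_UINT16_MAX = 65535


def write_image_pair(path_stem: str, pair: ImagePair) -> None:
    stem = Path(path_stem)
    for name, img in (("bf", pair.bf), ("ef", pair.ef)):
        data = np.clip(img, 0.0, 1.0)
        tifffile.imwrite(f"{stem}_{name}.tif",
                         (data * _UINT16_MAX).round().astype(np.uint16))


def read_image_pair(path_stem: str) -> ImagePair:
    """Load a BF/EF pair plus its sidecar metadata."""
    stem = Path(path_stem)
    meta_path = Path(f"{stem}_meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata: {meta_path}")
    meta = json.loads(meta_path.read_text())
    images = {}
    for name in ("bf", "ef"):
        p = Path(f"{stem}_{name}.tif")
        if not p.exists():
            raise FileNotFoundError(f"missing image: {p}")
        images[name] = tifffile.imread(p).astype(float) / _UINT16_MAX
    pixel_size = float(meta.get("pixel_size_um", 0))
    if pixel_size <= 0:
        raise ValueError(f"non-positive pixel size in {meta_path}")
    if images["bf"].shape != images["ef"].shape:
        raise ValueError("BF and EF image shapes differ")
    return ImagePair(bf=images["bf"], ef=images["ef"], pixel_size=pixel_size)


def write_flow_trace(path: str, trace: FlowTrace) -> None:
    pd.DataFrame({"time_s": trace.time_s,
                  "cumulative_mass_g": trace.cumulative_mass_g}).to_csv(path, index=False)


def read_flow_trace(path: str, meta_path: Optional[str] = None) -> FlowTrace:
    """Read a flow CSV; hydraulic metadata comes from the meta JSON."""
    df = pd.read_csv(path)
    for col in ("time_s", "cumulative_mass_g"):
        if col not in df.columns:
            raise ValueError(f"flow CSV {path} lacks column {col}")
    if len(df) < 3:
        raise ValueError(f"flow CSV {path} has fewer than 3 rows")
    if np.any(np.diff(df["time_s"].to_numpy()) <= 0):
        raise ValueError(f"flow CSV {path} times are not strictly increasing")
    if meta_path is None:
        meta_path = str(Path(path).with_name(
            Path(path).name.replace("_flow.csv", "_meta.json")))
    meta = json.loads(Path(meta_path).read_text())
    for key in ("pressure_gradient_mpa", "segment_length_m", "water_density_kg_m3"):
        if key not in meta:
            raise KeyError(f"metadata {meta_path} lacks key {key}")
    return FlowTrace(time_s=df["time_s"].to_numpy(),
                     cumulative_mass_g=df["cumulative_mass_g"].to_numpy(),
                     pressure_gradient=float(meta["pressure_gradient_mpa"]),
                     segment_length=float(meta["segment_length_m"]),
                     water_density=float(meta["water_density_kg_m3"]))


def write_segment(out_dir: str, stem: str, segment: synthetic_data.SyntheticSegment) -> None:
    """Persist one synthetic segment as its on-disk file family."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = out / stem
    cfg = segment.config
    meta = {
        "pixel_size_um": cfg.pixel_size,
        "pressure_gradient_mpa": cfg.pressure_gradient,
        "segment_length_m": cfg.segment_length,
        "water_density_kg_m3": cfg.water_density,
        "segment_type": segment.segment_type,
        "seed": cfg.seed,
        "plant_id": segment.plant_id,
        "true_kht": segment.true_kht,
        "true_kh": segment.true_kh,
    }
    (Path(f"{base}_meta.json")).write_text(json.dumps(meta, indent=2))
    if segment.image_pair is not None:
        write_image_pair(str(base), segment.image_pair)
    if segment.flow_trace is not None:
        write_flow_trace(f"{base}_flow.csv", segment.flow_trace)
    truth = [dataclasses.asdict(v) for v in segment.ground_truth]
    (Path(f"{base}_truth.json")).write_text(json.dumps(truth, indent=1))


def read_truth(path: str) -> List[synthetic_data.GroundTruthVessel]:
    raw = json.loads(Path(path).read_text())
    return [synthetic_data.GroundTruthVessel(
        **{**v, "center": tuple(v["center"])}) for v in raw]


_VESSEL_COLUMNS = ["id", "centroid_x_um", "centroid_y_um", "area_um2", "diameter_um",
                   "wall_completeness", "stain_fraction", "expanding", "type",
                   "conductive_bf", "conductive_ef"]


def vessels_to_frame(records: List[VesselRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        cx, cy = r.centroid if r.centroid is not None else (np.nan, np.nan)
        rows.append({
            "id": r.id, "centroid_x_um": cx, "centroid_y_um": cy,
            "area_um2": r.area_um2, "diameter_um": r.diameter_um,
            "wall_completeness": r.wall_completeness,
            "stain_fraction": r.stain_fraction,
            "expanding": r.expanding, "type": r.type,
            "conductive_bf": r.conductive_bf, "conductive_ef": r.conductive_ef,
        })
    return pd.DataFrame(rows, columns=_VESSEL_COLUMNS)


def frame_to_vessels(df: pd.DataFrame) -> List[VesselRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(VesselRecord(
            id=int(row["id"]),
            area_um2=float(row["area_um2"]),
            diameter_um=float(row["diameter_um"]),
            wall_completeness=float(row["wall_completeness"]),
            stain_fraction=float(row["stain_fraction"]),
            centroid=(float(row["centroid_x_um"]), float(row["centroid_y_um"])),
            expanding=None if pd.isna(row.get("expanding")) else bool(row["expanding"]),
            type=None if pd.isna(row.get("type")) else str(row["type"]),
            conductive_bf=(None if pd.isna(row.get("conductive_bf"))
                           else bool(row["conductive_bf"])),
            conductive_ef=(None if pd.isna(row.get("conductive_ef"))
                           else bool(row["conductive_ef"])),
        ))
    return records


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    n_plants: int = 11
    render_images: bool = False
    generator_apical: dict = field(default_factory=dict)
    generator_basal: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    hydraulics: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def summaries_from_segments(segments, seg_params: SegmentationParams,
                             cls_params: ClassificationParams,
                             use_images: bool):
    """Measure/classify/summarise every segment; returns stats.SegmentData list."""
    data = []
    for i, seg in enumerate(segments):
        if use_images and seg.image_pair is not None:
            records = segmentation.measure_vessels(seg.image_pair, seg_params)
            center = seg.image_pair.center_um
        else:
            records = synthetic_data.records_from_truth(seg.ground_truth)
            center = seg.config.image_center_um
        records = classification.classify_all(records, cls_params,
                                              image_center_um=center)
        summary = hydraulics.summarize_segment(records, seg.flow_trace)
        data.append(stats.SegmentData(
            segment_id=f"plant{seg.plant_id}_{seg.segment_type}",
            segment_type=seg.segment_type,
            summary=summary,
            vessels=vessels_to_frame(records),
        ))
    return data


def run_pipeline(config: RunConfig) -> stats.ComparisonReport:
    """simulate -> segment -> classify -> hydraulics -> report.

    Writes per-stage artifacts (segment file families, the classified vessel
    tables, ``hydraulics.csv``, ``report.json``/``report.md``) plus the
    resolved configuration into ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2))

    stage = "simulate"
    try:
        cfg_api = synthetic_data.default_config("apical", **config.generator_apical)
        cfg_bas = synthetic_data.default_config("basal", **config.generator_basal)
        segments = synthetic_data.generate_cohort(
            config.n_plants, cfg_api, cfg_bas, seed=config.seed,
            render_images=config.render_images)
        for seg in segments:
            write_segment(str(out / "segments"),
                          f"plant{seg.plant_id}_{seg.segment_type}", seg)

        stage = "segment/classify/hydraulics"
        seg_params = SegmentationParams(**config.segmentation)
        cls_params = ClassificationParams(**config.classification)
        data = summaries_from_segments(segments, seg_params, cls_params,
                                       use_images=config.render_images)
        rows = []
        for d in data:
            d.vessels.to_csv(out / f"vessels_{d.segment_id}.csv", index=False)
            row = {"segment_id": d.segment_id, "segment_type": d.segment_type}
            row.update({k: v for k, v in dataclasses.asdict(d.summary).items()
                        if k != "counts"})
            row.update(d.summary.counts)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "hydraulics.csv", index=False,
                                  float_format="%.6e")

        stage = "report"
        report = stats.compare_bf_ef(data)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2,
                                                    default=float))
        (out / "report.md").write_text(report.to_markdown())
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
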