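"""Conductive-vessel classification and xylem-type assignment.

Two independent criteria decide whether a vessel is conductive:

* **Bright field (BF)** — the secondary cell wall is fully developed
  (wall completeness at or above ``theta_bf``) and the vessel is not an
  expanding, immature cell.
* **Epifluorescence (EF)** — strictly more than one half of the wall
  perimeter is stained by the perfused tracer (stain fraction > 0.5).

Vessels are typed as protoxylem (PX; narrow, pith-facing, first formed) or
metaxylem (MX; wide, outward; secondary-xylem vessels are pooled with MX).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

PX = "PX"
MX = "MX"


@dataclass
class VesselRecord:
    """One measured vessel with optional classification calls and truth."""

    id: int
    area_um2: float
    diameter_um: float
    wall_completeness: float
    stain_fraction: float
    centroid: Optional[Tuple[float, float]] = None  # (x_um, y_um)
    bundle_id: Optional[int] = None
    expanding: Optional[bool] = None
    type: Optional[str] = None
    conductive_bf: Optional[bool] = None
    conductive_ef: Optional[bool] = None
    # ground-truth fields, populated only for synthetic data
    true_conductive: Optional[bool] = None
    true_type: Optional[str] = None
    true_expanding: Optional[bool] = None


@dataclass
class ClassificationParams:
    theta_bf: float = 0.9            # wall completeness for "fully developed"
    expanding_area_percentile: float = 50.0
    px_diameter_cutoff_um: float = 8.0
    min_cluster_separation: float = 1.25  # geometric-mean diameter ratio


def classify_bf(wall_completeness: float, expanding: bool, theta_bf: float = 0.9) -> bool:
    """BF criterion: fully developed secondary wall, excluding expanding cells."""
    if not 0 < theta_bf <= 1:
        raise ValueError("theta_bf must be in (0, 1]")
    if not 0 <= wall_completeness <= 1:
        raise ValueError("wall completeness must be in [0, 1]")
    return wall_completeness >= theta_bf and not expanding


def classify_ef(stain_fraction: float) -> bool:
    """EF criterion: strictly more than half of the wall perimeter stained."""
    if not 0 <= stain_fraction <= 1:
        raise ValueError("stain fraction must be in [0, 1]")
    return stain_fraction > 0.5


def flag_expanding(records: Sequence[VesselRecord],
                   params: Optional[ClassificationParams] = None) -> np.ndarray:
    """Flag expanding (immature, enlarging) vessels in one section.

    A vessel is flagged when its wall is not fully developed and its lumen
    area exceeds the configured percentile of the unwalled vessels in the
    same image: expanding cells are conspicuously large while other unwalled
    profiles (young, still-narrow elements) are small.
    """
    params = params or ClassificationParams()
    completeness = np.array([r.wall_completeness for r in records], dtype=float)
    areas = np.array([r.area_um2 for r in records], dtype=float)
    unwalled = completeness < params.theta_bf
    flags = np.zeros(len(records), dtype=bool)
    if not np.any(unwalled):
        return flags
    cutoff = np.percentile(areas[unwalled], params.expanding_area_percentile)
    flags[unwalled & (areas > cutoff)] = True
    return flags


def _best_1d_split(values: np.ndarray) -> Tuple[float, int]:
    """Exact 1-D two-cluster split minimising within-cluster sum of squares.

    Returns ``(sse, k)`` where the sorted array splits into ``values[:k]``
    and ``values[k:]``.  Equivalent to converged 2-means in one dimension,
    but deterministic and free of initialisation effects.
    """
    v = np.sort(values)
    n = v.size
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    best = (math.inf, 1)
    for k in range(1, n):
        sse1 = csq[k - 1] - csum[k - 1] ** 2 / k
        sse2 = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        sse = sse1 + sse2
        if sse < best[0]:
            best = (sse, k)
    return best


def assign_xylem_type(records: Sequence[VesselRecord],
                      params: Optional[ClassificationParams] = None,
                      image_center_um: Optional[Tuple[float, float]] = None) -> List[str]:
    """Assign PX/MX to every vessel of a section.

    Vessel diameter is the separating feature: the section's log-diameters
    are split into two clusters (exact 1-D two-means) and the
    smaller-diameter cluster is PX.  When the two clusters are not clearly
    separated (geometric-mean ratio below ``min_cluster_separation``), or
    fewer than two vessels are present, each vessel falls back to a fixed
    diameter cutoff: below ``px_diameter_cutoff_um`` is PX, otherwise MX.

    When centroids and the section centre are available, the orientation of
    the assignment is sanity-checked: PX should lie closer to the pith
    (image centre) than MX on average.
    """
    params = params or ClassificationParams()
    n = len(records)
    if n == 0:
        return []
    diameters = np.array([r.diameter_um for r in records], dtype=float)
    if n < 2:
        return [PX if diameters[0] < params.px_diameter_cutoff_um else MX]

    logs = np.log(diameters)
    order = np.argsort(logs)
    _, k = _best_1d_split(logs)
    small_idx = order[:k]
    large_idx = order[k:]
    gm_small = float(np.exp(np.mean(logs[small_idx])))
    gm_large = float(np.exp(np.mean(logs[large_idx])))
    if gm_large / gm_small < params.min_cluster_separation:
        # unimodal section: no reliable split, use the absolute cutoff
        return [PX if d < params.px_diameter_cutoff_um else MX for d in diameters]

    types = np.full(n, MX, dtype=object)
    types[small_idx] = PX

    if image_center_um is not None and all(r.centroid is not None for r in records):
        cx, cy = image_center_um
        radial = np.array([math.hypot(r.centroid[0] - cx, r.centroid[1] - cy)
                           for r in records])
        if radial[small_idx].mean() > radial[large_idx].mean():
            # narrow vessels farther from the pith than wide ones would be
            # anatomically inverted; diameter still wins, but this situation
            # indicates the section is not a standard collateral bundle ring.
            import warnings
            warnings.warn("PX cluster lies outward of MX cluster; "
                          "check section orientation")
    return list(types)


def classify_all(records: Sequence[VesselRecord],
                 params: Optional[ClassificationParams] = None,
                 image_center_um: Optional[Tuple[float, float]] = None) -> List[VesselRecord]:
    """Apply expanding flags, both conductivity criteria and typing.

    Pure function of the measured fields, hence idempotent: re-classifying
    classified records leaves them unchanged.
    """
    params = params or ClassificationParams()
    flags = flag_expanding(records, params)
    types = assign_xylem_type(records, params, image_center_um=image_center_um)
    out = []
    for rec, exp, vtype in zip(records, flags, types):
        out.append(replace(
            rec,
            expanding=bool(exp),
            type=vtype,
            conductive_bf=classify_bf(rec.wall_completeness, bool(exp), params.theta_bf),
            conductive_ef=classify_ef(rec.stain_fraction),
        ))
    return out
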