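"""Experimental and theoretical hydraulic conductivities of stem segments.

The experimental conductivity of a segment is obtained from the steady slope
of a cumulative-mass balance trace recorded under a fixed pressure gradient::

    K_h = F * L / dP        [m^4 MPa^-1 s^-1]

where ``F`` is the volumetric flow rate (m^3 s^-1), ``L`` the segment length
(m) and ``dP`` the pressure gradient (MPa).  The theoretical conductivity of
the conductive-vessel population treats every vessel lumen as an ideal
circular capillary and sums the Hagen-Poiseuille law over vessels::

    K_ht = sum_i pi * D_i^4 / (128 * eta)

with ``D_i`` the inner lumen diameter (m) and ``eta`` the dynamic viscosity
of water at 20 degC (1.002e-9 MPa s).  Specific conductivities divide either
quantity by the total lumen area of the same vessel set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: dynamic viscosity of water at 20 degC, in MPa s
ETA_WATER_20C = 1.002e-9


@dataclass
class FlowTrace:
    """Cumulative-mass record from an analytical balance.

    Times are seconds from the start of the steady measurement; masses are
    grams of solution collected.  The pressure gradient (MPa), segment length
    (m) and solution density (kg m^-3) travel with the trace so that a trace
    is self-describing.
    """

    time_s: np.ndarray
    cumulative_mass_g: np.ndarray
    pressure_gradient: float
    segment_length: float
    water_density: float = 998.2

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.cumulative_mass_g = np.asarray(self.cumulative_mass_g, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.cumulative_mass_g.shape:
            raise ValueError("time and mass arrays must be 1-D and equally long")
        if self.time_s.size < 3:
            raise ValueError("a flow trace needs at least 3 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.pressure_gradient <= 0:
            raise ValueError("pressure gradient must be positive")
        if self.segment_length <= 0:
            raise ValueError("segment length must be positive")
        if self.water_density <= 0:
            raise ValueError("water density must be positive")


@dataclass
class HydraulicSummary:
    """Per-segment hydraulic quantities under both identification criteria.

    ``*_bf`` fields use the bright-field criterion (fully developed secondary
    wall), ``*_ef`` fields the epifluorescence criterion (more than half of
    the wall perimeter stained).  Quantities that are undefined for a segment
    (e.g. specific conductivity when no vessel is conductive under a
    criterion) are ``None`` rather than an error.
    """

    kh: Optional[float] = None
    kht_bf: float = 0.0
    kht_ef: float = 0.0
    total_lumen_area_bf: float = 0.0
    total_lumen_area_ef: float = 0.0
    khs_bf: Optional[float] = None
    khs_ef: Optional[float] = None
    khts_bf: Optional[float] = None
    khts_ef: Optional[float] = None
    ratio_bf_percent: Optional[float] = None
    ratio_ef_percent: Optional[float] = None
    mean_diameter_bf: Optional[float] = None
    mean_diameter_ef: Optional[float] = None
    counts: dict = field(default_factory=dict)


def estimate_flow_rate(trace: FlowTrace, window_fraction: float = 0.5) -> float:
    """Volumetric flow rate (m^3 s^-1) from the steady tail of a trace.

    An ordinary least-squares line is fitted to cumulative mass versus time
    over the final ``window_fraction`` of the samples; the initial portion is
    discarded so that any filling/relaxation transient does not bias the
    slope.  The mass rate (g s^-1) is converted to volume using the trace's
    solution density.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    n = trace.time_s.size
    k = int(math.ceil(n * window_fraction))
    if k < 3:
        raise ValueError("fewer than 3 points in the fitting window")
    t = trace.time_s[n - k:]
    m = trace.cumulative_mass_g[n - k:]
    slope = float(np.polyfit(t, m, 1)[0])  # g/s
    if slope <= 0:
        raise ValueError("no positive steady flow in the fitted window")
    return slope * 1e-3 / trace.water_density  # g/s -> kg/s -> m^3/s


def compute_kh(flow_rate: float, segment_length: float, pressure_gradient: float) -> float:
    """Experimental hydraulic conductivity K_h = F * L / dP."""
    if flow_rate <= 0 or segment_length <= 0 or pressure_gradient <= 0:
        raise ValueError("flow rate, length and pressure gradient must be positive")
    return flow_rate * segment_length / pressure_gradient


def diameter_from_area(area_um2: float) -> float:
    """Equivalent circular diameter (um) of a lumen of given area (um^2)."""
    if area_um2 <= 0:
        raise ValueError("lumen area must be positive")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def compute_kht(diameters_um: Sequence[float], eta: float = ETA_WATER_20C) -> float:
    """Hagen-Poiseuille conductivity sum over vessel lumen diameters.

    Diameters are in micrometres; the result is in m^4 MPa^-1 s^-1.  An empty
    vessel set has zero theoretical conductivity.
    """
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    d = np.asarray(list(diameters_um), dtype=float)
    if d.size == 0:
        return 0.0
    bad = np.nonzero(d <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive diameter at index {int(bad[0])}")
    return float(np.sum(math.pi * (d * 1e-6) ** 4) / (128.0 * eta))


def specific_conductivity(conductivity: float, total_lumen_area: float) -> float:
    """Conductivity divided by total vessel-lumen area (area in m^2)."""
    if total_lumen_area <= 0:
        raise ValueError("total lumen area must be positive")
    return conductivity / total_lumen_area


def relative_contribution(kh: float, kht: float) -> float:
    """Percent contribution of experimental to theoretical conductivity."""
    if kht <= 0:
        raise ValueError("theoretical conductivity must be positive")
    return 100.0 * kh / kht


def resistivity(kh: float) -> float:
    """Lumen resistivity (MPa s m^-4), the reciprocal of a conductivity."""
    if kh <= 0:
        raise ValueError("conductivity must be positive")
    return 1.0 / kh


def summarize_segment(records, trace: Optional[FlowTrace], eta: float = ETA_WATER_20C,
                      window_fraction: float = 0.5) -> HydraulicSummary:
    """Hydraulic summary of one segment from classified vessels and a trace.

    ``records`` are classified :class:`~xylemtrace.classification.VesselRecord`
    objects; conductive subsets are taken separately under the BF and EF
    criteria.  ``trace`` may be ``None`` for segments without a usable flow
    measurement, in which case K_h-derived quantities are ``None``.
    """
    summary = HydraulicSummary()
    if trace is not None:
        flow = estimate_flow_rate(trace, window_fraction=window_fraction)
        summary.kh = compute_kh(flow, trace.segment_length, trace.pressure_gradient)

    for crit in ("bf", "ef"):
        subset = [r for r in records if getattr(r, f"conductive_{crit}")]
        diameters = [r.diameter_um for r in subset]
        kht = compute_kht(diameters, eta=eta)
        area_m2 = sum(r.area_um2 for r in subset) * 1e-12
        setattr(summary, f"kht_{crit}", kht)
        setattr(summary, f"total_lumen_area_{crit}", area_m2)
        if diameters:
            setattr(summary, f"mean_diameter_{crit}", float(np.mean(diameters)))
        if area_m2 > 0:
            if summary.kh is not None:
                setattr(summary, f"khs_{crit}", specific_conductivity(summary.kh, area_m2))
            if kht > 0:
                setattr(summary, f"khts_{crit}", specific_conductivity(kht, area_m2))
        if kht > 0 and summary.kh is not None:
            setattr(summary, f"ratio_{crit}_percent", relative_contribution(summary.kh, kht))
        for vtype in ("PX", "MX"):
            summary.counts[f"{vtype.lower()}_{crit}"] = sum(
                1 for r in subset if r.type == vtype)
        summary.counts[f"total_{crit}"] = len(subset)
    if not records:
        warnings.warn("segment has no vessels; theoretical quantities are zero")
    return summary
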