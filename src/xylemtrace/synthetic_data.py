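"""Seeded synthetic stem-section generator with per-vessel ground truth.

No micrographs or balance recordings are deposited with the study this
package reconstructs, so every pipeline stage is exercised against synthetic
segments whose latent truth is known exactly.  A synthetic segment consists
of

* a list of :class:`GroundTruthVessel` — collateral vascular bundles placed
  on a ring around the pith, each with a compact protoxylem (PX) cluster of
  narrow vessels on the pith-facing side and a radial metaxylem (MX) file of
  wider vessels running outward (secondary-xylem vessels are pooled with
  MX).  Vessels are fully walled and conductive, fully walled but
  nonconductive (lignified yet not perfused), or expanding/immature;
* a co-registered bright-field / epifluorescence image pair rendered from
  that truth (dark wall annuli and bright lumens in BF; stained wall arcs,
  fibre speckle near the PX clusters and an autofluorescence floor in EF;
  Gaussian PSF and additive Gaussian noise);
* a cumulative-mass flow trace whose underlying steady rate corresponds to
  the segment's true experimental conductivity.

The default configuration mirrors the study conditions: expected walled
vessel counts of 61 PX and 40 MX per segment of which 43 and 23 are
conductive, lognormal lumen diameters with apical/basal medians chosen so
the conductive-vessel mean diameters are ~8.3 um (apical) and ~12.7 um
(basal), a 40 kPa pressure gradient over a 30 mm segment, 20 s balance
sampling for 30 min, and a K_h/K_ht efficiency drawn from a lognormal with
mean 0.33 and CV 0.69 truncated to (0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage as ndi

from .classification import MX, PX, VesselRecord
from .hydraulics import FlowTrace, compute_kht
from .segmentation import ImagePair

_RENDER_STREAM = 101  # sub-stream tags for seed splitting
_FLOW_STREAM = 102
_EFFICIENCY_STREAM = 103


class PlacementError(RuntimeError):
    """Raised when the requested vessel density cannot be placed."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-segment generator.

    Counts are per-segment expectations of *lignified* (fully walled)
    vessels; expanding vessels are drawn on top at rate ``frac_expanding``
    relative to them.  ``frac_walled_nonconductive`` may be a single
    fraction or a per-type mapping; the default per-type values reproduce
    the study's conductive counts (43 of 61 PX, 23 of 40 MX).
    """

    seed: int = 0
    segment_type: str = "basal"           # {"apical", "basal"}
    image_shape: Optional[Tuple[int, int]] = None  # (H, W) px; None = default
    pixel_size: float = 0.2               # um / px
    n_bundles: int = 7
    px_count_mean: float = 61.0
    mx_count_mean: float = 40.0
    # per-type lognormal lumen diameters: {type: (median_um, geometric_sd)}
    diameter_params: Optional[Dict[str, Tuple[float, float]]] = None
    diameter_truncation: float = 1.25     # hard bounds median/f .. median*f
    frac_walled_nonconductive: Union[float, Dict[str, float], None] = None
    # between-segment heterogeneity, calibrated to the study's printed
    # per-segment dispersions (count SEs far above Poisson; EF K_ht spread
    # roughly twice the BF spread in basal segments):
    count_cv: Optional[float] = None      # CV of the shared count multiplier
    count_multiplier_clip: Optional[Tuple[float, float]] = None
    frac_concentration: Optional[float] = None  # Beta concentration of the
    # nonconductive fraction (None = per-segment-type default; 0 disables)
    frac_expanding: float = 0.08
    stain_fraction_conductive: Tuple[float, float] = (0.7, 1.0)
    stain_fraction_nonconductive: Tuple[float, float] = (0.0, 0.45)
    fiber_density: float = 0.01           # speckles per um^2 of PX neighbourhood
    psf_sigma: float = 0.2                # um
    noise_sd: float = 0.01                # intensity units (images live in [0,1])
    # hydraulic side
    pressure_gradient: float = 0.04       # MPa
    segment_length: float = 0.03          # m
    sampling_interval: float = 20.0       # s
    duration: float = 1800.0              # s
    water_density: float = 998.2          # kg m^-3
    efficiency_params: Tuple[float, float] = (0.33, 0.69)  # (mean, CV) of K_h/K_ht
    transient_amplitude: float = 0.3      # initial excess flow, fraction of steady
    transient_tau: float = 180.0          # s
    balance_noise_sd: float = 2e-5        # g
    # geometry
    ring_radius_um: Optional[float] = None  # None = default per segment type
    wall_thickness_um: float = 1.5
    placement_margin_um: float = 6.0      # clearance between lumen boundaries
    px_mx_gap_um: float = 10.0
    cluster_packing: float = 0.45
    max_px_per_bundle: int = 24
    max_mx_per_bundle: int = 14
    max_expanding_per_bundle: int = 2
    # rendered intensity levels (normalised)
    bf_background: float = 0.5
    bf_lumen: float = 0.85
    bf_wall: float = 0.15
    ef_background: float = 0.02
    ef_stain: float = 0.9
    ef_fiber: float = 0.7

    _DEFAULT_MEDIANS = {
        "apical": {PX: 6.6, MX: 11.5},
        "basal": {PX: 9.2, MX: 19.4},
    }
    _DEFAULT_GSD = 1.12
    _DEFAULT_SHAPES = {"apical": (4000, 4000), "basal": (4800, 4800)}
    _DEFAULT_RING = {"apical": 110.0, "basal": 130.0}
    _DEFAULT_COUNT_CV = {"apical": 0.5, "basal": 0.2}
    _DEFAULT_CLIP = {"apical": (0.3, 2.2), "basal": (0.3, 1.6)}
    _DEFAULT_FRAC_NU = {"apical": 8.0, "basal": 2.0}

    def __post_init__(self) -> None:
        if self.segment_type not in ("apical", "basal"):
            raise ValueError("segment_type must be 'apical' or 'basal'")
        if self.diameter_params is None:
            med = self._DEFAULT_MEDIANS[self.segment_type]
            self.diameter_params = {t: (m, self._DEFAULT_GSD) for t, m in med.items()}
        if self.frac_walled_nonconductive is None:
            self.frac_walled_nonconductive = {PX: 18.0 / 61.0, MX: 17.0 / 40.0}
        if self.image_shape is None:
            self.image_shape = self._DEFAULT_SHAPES[self.segment_type]
        if self.ring_radius_um is None:
            self.ring_radius_um = self._DEFAULT_RING[self.segment_type]
        if self.count_cv is None:
            self.count_cv = self._DEFAULT_COUNT_CV[self.segment_type]
        if self.count_multiplier_clip is None:
            self.count_multiplier_clip = self._DEFAULT_CLIP[self.segment_type]
        if self.frac_concentration is None:
            self.frac_concentration = self._DEFAULT_FRAC_NU[self.segment_type]
        self.validate()

    def nonconductive_fraction(self, vessel_type: str) -> float:
        f = self.frac_walled_nonconductive
        return float(f[vessel_type]) if isinstance(f, dict) else float(f)

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.px_count_mean < 0 or self.mx_count_mean < 0 or self.n_bundles < 1:
            raise ValueError("counts must be non-negative and n_bundles >= 1")
        for t in (PX, MX):
            frac = self.nonconductive_fraction(t)
            if not 0 <= frac < 1:
                raise ValueError("frac_walled_nonconductive must be in [0, 1)")
        if not 0 <= self.frac_expanding < 1:
            raise ValueError("frac_expanding must be in [0, 1)")
        lo, hi = self.stain_fraction_conductive
        if not (0.5 < lo <= hi <= 1):
            raise ValueError("conductive stain interval must lie in (0.5, 1]")
        lo, hi = self.stain_fraction_nonconductive
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("nonconductive stain interval must lie in [0, 0.5]")
        if self.duration < 3 * self.sampling_interval:
            raise ValueError("duration must cover at least 3 sampling intervals")
        mean, cv = self.efficiency_params
        if not (0 < mean <= 1 and cv > 0):
            raise ValueError("efficiency mean must be in (0,1] with positive CV")

    @property
    def image_center_um(self) -> Tuple[float, float]:
        h, w = self.image_shape
        return ((w - 1) / 2.0 * self.pixel_size, (h - 1) / 2.0 * self.pixel_size)


def default_config(segment_type: str, **overrides) -> GeneratorConfig:
    """Study-condition configuration for one segment type."""
    return GeneratorConfig(segment_type=segment_type, **overrides)


@dataclass
class GroundTruthVessel:
    """Latent truth for one vessel of a synthetic section."""

    id: int
    bundle_id: int
    center: Tuple[float, float]    # (x_um, y_um), image coordinates
    true_diameter: float           # lumen diameter, um
    type: str                      # PX or MX
    wall_state: str                # {"full", "partial", "absent"}
    expanding: bool
    true_conductive: bool
    true_stain_fraction: float
    wall_completeness: float       # rendered angular extent of the wall, 0..1

    def __post_init__(self) -> None:
        if self.true_conductive and (self.wall_state != "full"
                                     or self.true_stain_fraction <= 0.5):
            raise ValueError("conductive vessels must be fully walled and stained")
        if self.wall_state != "full" and (self.true_conductive
                                          or self.true_stain_fraction > 0.5):
            raise ValueError("unwalled vessels cannot be conductive or majority-stained")


@dataclass
class SyntheticSegment:
    """One generated stem segment: truth, optional images, flow trace."""

    ground_truth: List[GroundTruthVessel]
    image_pair: Optional[ImagePair]
    flow_trace: Optional[FlowTrace]
    true_kht: float
    true_kh: float
    segment_type: str
    plant_id: int
    config: GeneratorConfig


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


def _truncated_lognormal(rng: np.random.Generator, median: float, gsd: float,
                         factor: float) -> float:
    sigma = math.log(gsd)
    bound = math.log(factor)
    for _ in range(1000):
        z = rng.normal(0.0, 1.0) * sigma
        if abs(z) <= bound:
            return median * math.exp(z)
    return median


def _draw_vessel_attributes(rng: np.random.Generator, config: GeneratorConfig,
                            vessel_type: str, expanding: bool,
                            frac_nonconductive: Optional[float] = None) -> dict:
    median, gsd = config.diameter_params[vessel_type]
    if expanding:
        median *= config.diameter_truncation  # enlarging cells are conspicuously wide
    diameter = _truncated_lognormal(rng, median, gsd, config.diameter_truncation)
    if frac_nonconductive is None:
        frac_nonconductive = config.nonconductive_fraction(vessel_type)
    if expanding:
        wall_state = "partial" if rng.random() < 0.5 else "absent"
        completeness = rng.uniform(0.55, 0.80) if wall_state == "partial" else 0.0
        conductive = False
        stain = 0.0
    else:
        wall_state = "full"
        completeness = 1.0
        conductive = rng.random() >= frac_nonconductive
        if conductive:
            stain = rng.uniform(*config.stain_fraction_conductive)
        else:
            lo, hi = config.stain_fraction_nonconductive
            stain = 0.0 if rng.random() < 0.5 else rng.uniform(max(lo, 0.05), hi)
    return dict(true_diameter=diameter, wall_state=wall_state, expanding=expanding,
                true_conductive=conductive, true_stain_fraction=stain,
                wall_completeness=completeness)


def _no_overlap(pos: Tuple[float, float], radius: float,
                placed: List[Tuple[float, float, float]], margin: float) -> bool:
    for (x, y, r) in placed:
        if math.hypot(pos[0] - x, pos[1] - y) < radius + r + margin:
            return False
    return True


def build_ground_truth(config: GeneratorConfig,
                       seed: Optional[int] = None) -> List[GroundTruthVessel]:
    """Place all vessels of one synthetic segment; deterministic per seed.

    Bundles sit on a ring around the image centre (the pith); inside each
    bundle the PX cluster is placed by rejection sampling in a disc sized to
    its vessel count, and the MX vessels (plus any expanding cells) form a
    staggered double file running radially outward.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    margin = config.placement_margin_um
    wall = config.wall_thickness_um
    cx, cy = config.image_center_um
    n = config.n_bundles

    # segment-level heterogeneity: a shared count multiplier (stem size/age)
    # and per-type nonconductive fractions drawn around their means
    if config.count_cv and config.count_cv > 0:
        s2 = math.log(1 + config.count_cv ** 2)
        mult = float(np.clip(rng.lognormal(-s2 / 2, math.sqrt(s2)),
                             *config.count_multiplier_clip))
    else:
        mult = 1.0
    fracs = {}
    for t in (PX, MX):
        fbar = config.nonconductive_fraction(t)
        nu = config.frac_concentration
        if nu and nu > 0 and 0 < fbar < 1:
            fracs[t] = float(rng.beta(fbar * nu, (1 - fbar) * nu))
        else:
            fracs[t] = fbar
    ring = config.ring_radius_um * max(1.0, math.sqrt(mult))

    placed: List[Tuple[float, float, float]] = []
    vessels: List[GroundTruthVessel] = []
    vid = 0
    for b in range(n):
        phi = 2 * math.pi * (b + rng.uniform(-0.1, 0.1)) / n
        ur = (math.cos(phi), math.sin(phi))
        ut = (-math.sin(phi), math.cos(phi))

        n_px = min(int(rng.poisson(mult * config.px_count_mean / n)),
                   config.max_px_per_bundle)
        n_mx = min(int(rng.poisson(mult * config.mx_count_mean / n)),
                   config.max_mx_per_bundle)
        n_exp = min(int(rng.poisson(config.frac_expanding * mult
                                    * (config.px_count_mean + config.mx_count_mean) / n)),
                    config.max_expanding_per_bundle)

        px_attrs = [_draw_vessel_attributes(rng, config, PX, False, fracs[PX])
                    for _ in range(n_px)]
        mx_attrs = [_draw_vessel_attributes(rng, config, MX, False, fracs[MX])
                    for _ in range(n_mx)]
        exp_attrs = [_draw_vessel_attributes(rng, config, MX, True) for _ in range(n_exp)]

        # --- PX cluster: rejection sampling in a disc on the pith-facing side
        radii = sorted((a["true_diameter"] / 2 for a in px_attrs), reverse=True)
        excl = sum(math.pi * (r + margin / 2) ** 2 for r in radii)
        cluster_r = max(18.0, math.sqrt(excl / config.cluster_packing / math.pi)) if radii else 0.0
        ccx = cx + ur[0] * ring
        ccy = cy + ur[1] * ring
        px_order = sorted(range(n_px), key=lambda i: -px_attrs[i]["true_diameter"])
        px_positions: Dict[int, Tuple[float, float]] = {}
        r_eff = cluster_r
        for attempt_round in range(7):
            trial: List[Tuple[float, float, float]] = []
            positions: Dict[int, Tuple[float, float]] = {}
            ok = True
            for i in px_order:
                r = px_attrs[i]["true_diameter"] / 2
                for _ in range(300):
                    rho = r_eff * math.sqrt(rng.random())
                    ang = rng.uniform(0, 2 * math.pi)
                    pos = (ccx + rho * math.cos(ang), ccy + rho * math.sin(ang))
                    if _no_overlap(pos, r, placed + trial, margin):
                        trial.append((pos[0], pos[1], r))
                        positions[i] = pos
                        break
                else:
                    ok = False
                    break
            if ok:
                placed.extend(trial)
                px_positions = positions
                break
            r_eff *= 1.12
        else:
            raise PlacementError(f"cannot place PX cluster of bundle {b}")
        cluster_extent = (max((math.hypot(x - ccx, y - ccy) + r
                               for (x, y, r) in placed[-n_px:]), default=0.0)
                          if n_px else 0.0)

        # --- MX radial file (staggered double file), expanding cells at the end
        file_attrs = mx_attrs + exp_attrs
        u_cursor = ring + cluster_extent + config.px_mx_gap_um + wall
        idx = 0
        while idx < len(file_attrs):
            pair_attrs = file_attrs[idx:idx + 2]
            row_r = max(a["true_diameter"] / 2 for a in pair_attrs)
            u = u_cursor + row_r
            offsets = ([0.0] if len(pair_attrs) == 1
                       else [-(pair_attrs[0]["true_diameter"] / 2 + margin / 2 + 0.3),
                             pair_attrs[1]["true_diameter"] / 2 + margin / 2 + 0.3])
            for a, v_off in zip(pair_attrs, offsets):
                r = a["true_diameter"] / 2
                for jitter_try in range(30):
                    jv = v_off + rng.uniform(-1.0, 1.0)
                    pos = (cx + ur[0] * u + ut[0] * jv, cy + ur[1] * u + ut[1] * jv)
                    if _no_overlap(pos, r, placed, margin):
                        placed.append((pos[0], pos[1], r))
                        a["_pos"] = pos
                        break
                else:
                    raise PlacementError(f"cannot place MX file of bundle {b}")
            u_cursor = u + row_r + margin
            idx += 2

        for i, a in enumerate(px_attrs):
            vessels.append(GroundTruthVessel(
                id=vid, bundle_id=b, center=px_positions[i], type=PX, **a))
            vid += 1
        for a in mx_attrs + exp_attrs:
            pos = a.pop("_pos")
            vessels.append(GroundTruthVessel(
                id=vid, bundle_id=b, center=pos, type=MX, **a))
            vid += 1

    _assert_no_overlap(vessels, margin)
    return vessels


def _assert_no_overlap(vessels: Sequence[GroundTruthVessel], margin: float) -> None:
    for i, v in enumerate(vessels):
        for w in vessels[i + 1:]:
            d = math.hypot(v.center[0] - w.center[0], v.center[1] - w.center[1])
            need = (v.true_diameter + w.true_diameter) / 2 + margin
            if d < need - 1e-9:
                raise PlacementError(f"vessels {v.id} and {w.id} overlap")


def fit_image(truth: Sequence[GroundTruthVessel], config: GeneratorConfig,
              margin_um: float = 8.0) -> Tuple[List[GroundTruthVessel], GeneratorConfig]:
    """Shift a vessel layout onto a canvas that tightly contains it.

    Placement is relative to the configured image centre, so translating all
    centres by a constant is exact; this lets small test layouts be rendered
    without hand-tuning ``image_shape``.  Returns the shifted truth and a
    config with the fitted shape.
    """
    if not truth:
        return list(truth), config
    wall = config.wall_thickness_um
    ext = [(v.center[0], v.center[1], v.true_diameter / 2 + wall + 1.0) for v in truth]
    xmin = min(x - r for x, _, r in ext) - margin_um
    xmax = max(x + r for x, _, r in ext) + margin_um
    ymin = min(y - r for _, y, r in ext) - margin_um
    ymax = max(y + r for _, y, r in ext) + margin_um
    px = config.pixel_size
    shape = (int(math.ceil((ymax - ymin) / px)) + 1,
             int(math.ceil((xmax - xmin) / px)) + 1)
    shifted = [replace(v, center=(v.center[0] - xmin, v.center[1] - ymin))
               for v in truth]
    return shifted, replace(config, image_shape=shape)


def _soft_disc(rho: np.ndarray, radius: float, pixel_size: float) -> np.ndarray:
    return np.clip((radius - rho) / pixel_size + 0.5, 0.0, 1.0)


def _arc_mask(theta: np.ndarray, start: float, extent: float) -> np.ndarray:
    if extent >= 2 * math.pi - 1e-9:
        return np.ones_like(theta, dtype=bool)
    delta = np.mod(theta - start, 2 * math.pi)
    return delta <= extent


def render_pair(truth: Sequence[GroundTruthVessel], config: GeneratorConfig) -> ImagePair:
    """Render co-registered BF and EF rasters from ground truth.

    Deterministic for a given (truth, config); the per-vessel arc phases,
    fibre speckle and noise come from a render-specific stream split off
    ``config.seed``.
    """
    h, w = config.image_shape
    px = config.pixel_size
    wall = config.wall_thickness_um
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _RENDER_STREAM]))

    bf = np.full((h, w), config.bf_background, dtype=float)
    ef = np.full((h, w), config.ef_background, dtype=float)

    xmax, ymax = (w - 1) * px, (h - 1) * px
    for v in truth:
        r = v.true_diameter / 2
        ext = r + wall + 1.0
        x0, y0 = v.center
        if x0 - ext < 0 or y0 - ext < 0 or x0 + ext > xmax or y0 + ext > ymax:
            raise ValueError(f"vessel {v.id} extends outside image bounds")
        c_lo, c_hi = int(math.floor((x0 - ext) / px)), int(math.ceil((x0 + ext) / px)) + 1
        r_lo, r_hi = int(math.floor((y0 - ext) / px)), int(math.ceil((y0 + ext) / px)) + 1
        cols = np.arange(c_lo, c_hi)
        rows = np.arange(r_lo, r_hi)
        xg = cols[None, :] * px - x0
        yg = rows[:, None] * px - y0
        rho = np.hypot(xg, yg)
        theta = np.arctan2(yg, xg)

        lum = _soft_disc(rho, r, px)
        band = np.clip((rho - r) / px + 0.5, 0, 1) * np.clip((r + wall - rho) / px + 0.5, 0, 1)

        wall_arc = np.zeros_like(band)
        phase_wall = rng.uniform(0, 2 * math.pi)
        phase_stain = rng.uniform(0, 2 * math.pi)
        if v.wall_completeness > 0:
            wall_arc = band * _arc_mask(theta, phase_wall,
                                        v.wall_completeness * 2 * math.pi)
        lum_eff = lum * (1 - wall_arc)
        bf_patch = bf[r_lo:r_hi, c_lo:c_hi]
        bf_patch += lum_eff * (config.bf_lumen - config.bf_background)
        bf_patch += wall_arc * (config.bf_wall - config.bf_background)

        if v.true_stain_fraction > 0:
            stain_arc = band * _arc_mask(theta, phase_stain,
                                         v.true_stain_fraction * 2 * math.pi)
            ef[r_lo:r_hi, c_lo:c_hi] += stain_arc * (config.ef_stain - config.ef_background)

    _add_tissue_background(ef, truth, config, rng)

    sigma_px = config.psf_sigma / px
    if sigma_px > 0:
        bf = ndi.gaussian_filter(bf, sigma_px)
        ef = ndi.gaussian_filter(ef, sigma_px)
    if config.noise_sd > 0:
        bf = bf + rng.normal(0.0, config.noise_sd, size=bf.shape)
        ef = ef + rng.normal(0.0, config.noise_sd, size=ef.shape)
    np.clip(bf, 0.0, 1.0, out=bf)
    np.clip(ef, 0.0, 1.0, out=ef)
    return ImagePair(bf=bf, ef=ef, pixel_size=px)


def _add_tissue_background(ef: np.ndarray, truth: Sequence[GroundTruthVessel],
                           config: GeneratorConfig, rng: np.random.Generator) -> None:
    """Fibre speckle near each PX cluster plus an autofluorescence floor.

    Fibres are genuinely stained in the PX neighbourhood, so they are drawn
    bright (they must be rejected *spatially* by the wall-annulus geometry,
    not by thresholding); the autofluorescence floor is kept two noise SDs
    above background so exposure normalisation removes it.
    """
    px = config.pixel_size
    wall = config.wall_thickness_um
    h, w = ef.shape
    bundles: Dict[int, List[GroundTruthVessel]] = {}
    for v in truth:
        bundles.setdefault(v.bundle_id, []).append(v)
    floor = 2.0 * config.noise_sd
    for b, vs in bundles.items():
        px_vessels = [v for v in vs if v.type == PX]
        anchor = px_vessels or vs
        ax = float(np.mean([v.center[0] for v in anchor]))
        ay = float(np.mean([v.center[1] for v in anchor]))
        spread = max(max((math.hypot(v.center[0] - ax, v.center[1] - ay)
                          + v.true_diameter / 2 for v in anchor)), 10.0)
        # autofluorescence: soft disc over the whole bundle footprint
        if floor > 0:
            bx = float(np.mean([v.center[0] for v in vs]))
            by = float(np.mean([v.center[1] for v in vs]))
            b_r = max((math.hypot(v.center[0] - bx, v.center[1] - by)
                       + v.true_diameter / 2 for v in vs)) + 8.0
            _paint_soft_disc(ef, (bx, by), b_r, floor, px)
        # fibre speckle in an annular neighbourhood of the PX cluster
        zone_r = spread + 10.0
        n_fibers = rng.poisson(config.fiber_density * math.pi * zone_r ** 2)
        for _ in range(n_fibers):
            for _try in range(50):
                rho = zone_r * math.sqrt(rng.random())
                ang = rng.uniform(0, 2 * math.pi)
                fx, fy = ax + rho * math.cos(ang), ay + rho * math.sin(ang)
                fr = rng.uniform(0.6, 1.2)
                if not (fr < fx < (w - 1) * px - fr and fr < fy < (h - 1) * px - fr):
                    continue
                clear = all(math.hypot(fx - v.center[0], fy - v.center[1])
                            > v.true_diameter / 2 + wall + fr + 3.0 for v in truth)
                if clear:
                    _paint_soft_disc(ef, (fx, fy), fr,
                                     config.ef_fiber - config.ef_background, px)
                    break


def _paint_soft_disc(img: np.ndarray, center: Tuple[float, float], radius: float,
                     amplitude: float, pixel_size: float) -> None:
    h, w = img.shape
    x0, y0 = center
    c_lo = max(int(math.floor((x0 - radius) / pixel_size)) - 1, 0)
    c_hi = min(int(math.ceil((x0 + radius) / pixel_size)) + 2, w)
    r_lo = max(int(math.floor((y0 - radius) / pixel_size)) - 1, 0)
    r_hi = min(int(math.ceil((y0 + radius) / pixel_size)) + 2, h)
    if c_lo >= c_hi or r_lo >= r_hi:
        return
    xg = np.arange(c_lo, c_hi)[None, :] * pixel_size - x0
    yg = np.arange(r_lo, r_hi)[:, None] * pixel_size - y0
    rho = np.hypot(xg, yg)
    patch = img[r_lo:r_hi, c_lo:c_hi]
    patch += _soft_disc(rho, radius, pixel_size) * amplitude


def synthesize_flow_trace(true_kh: float, config: GeneratorConfig,
                          seed: Optional[int] = None) -> FlowTrace:
    """Cumulative-mass balance trace for a segment of known conductivity.

    The steady volumetric rate is ``F = K_h * dP / L``; an optional initial
    exponential transient (excess flow decaying with ``transient_tau``) and
    additive Gaussian balance noise are superimposed.
    """
    if true_kh <= 0:
        raise ValueError("true_kh must be positive")
    if config.duration < 3 * config.sampling_interval:
        raise ValueError("duration too short: need at least 3 sampling intervals")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _FLOW_STREAM]))
    t = np.arange(0.0, config.duration + config.sampling_interval / 2,
                  config.sampling_interval)
    flow = true_kh * config.pressure_gradient / config.segment_length  # m^3/s
    mass_rate = flow * config.water_density * 1e3  # g/s
    mass = mass_rate * t
    if config.transient_amplitude > 0 and config.transient_tau > 0:
        tau = config.transient_tau
        mass = mass + mass_rate * config.transient_amplitude * tau * (1 - np.exp(-t / tau))
    if config.balance_noise_sd > 0:
        mass = mass + rng.normal(0.0, config.balance_noise_sd, size=t.shape)
    return FlowTrace(time_s=t, cumulative_mass_g=mass,
                     pressure_gradient=config.pressure_gradient,
                     segment_length=config.segment_length,
                     water_density=config.water_density)


def _draw_efficiency(rng: np.random.Generator, mean: float, cv: float) -> float:
    sigma2 = math.log(1 + cv ** 2)
    mu = math.log(mean) - sigma2 / 2
    sigma = math.sqrt(sigma2)
    for _ in range(1000):
        e = math.exp(rng.normal(mu, sigma))
        if 0 < e <= 1:
            return e
    return mean


def records_from_truth(truth: Sequence[GroundTruthVessel]) -> List[VesselRecord]:
    """Vessel records taken directly from ground truth, bypassing imaging.

    Useful for exercising classification, hydraulics and statistics at
    scales where rendering and re-segmenting every section would add nothing
    but runtime; measured fields equal the latent truth exactly.
    """
    records = []
    for v in truth:
        records.append(VesselRecord(
            id=v.id,
            bundle_id=v.bundle_id,
            area_um2=math.pi * (v.true_diameter / 2) ** 2,
            diameter_um=v.true_diameter,
            wall_completeness=v.wall_completeness,
            stain_fraction=v.true_stain_fraction,
            centroid=v.center,
            true_conductive=v.true_conductive,
            true_type=v.type,
            true_expanding=v.expanding,
        ))
    return records


def generate_cohort(n_plants: int, config_apical: GeneratorConfig,
                    config_basal: GeneratorConfig, seed: int,
                    render_images: bool = True) -> List[SyntheticSegment]:
    """Generate one apical and one basal segment per plant.

    Child seeds are split deterministically from the master seed, so any
    segment can be regenerated in isolation.  Each segment's true K_ht is
    the Hagen-Poiseuille sum over its conductive vessels; its true K_h is
    that value scaled by an efficiency drawn from the configured lognormal
    truncated to (0, 1].
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    segments = []
    for plant in range(n_plants):
        for j, base in enumerate((config_apical, config_basal)):
            child = _child_seed(int(seed), plant, j)
            cfg = replace(base, seed=child)
            truth = build_ground_truth(cfg)
            conductive = [v.true_diameter for v in truth if v.true_conductive]
            true_kht = compute_kht(conductive)
            check = sum(math.pi * (d * 1e-6) ** 4 for d in conductive) / (128 * 1.002e-9)
            assert true_kht == 0 or abs(true_kht - check) / check < 1e-12
            e_rng = np.random.default_rng(
                np.random.SeedSequence([child, _EFFICIENCY_STREAM]))
            eff = _draw_efficiency(e_rng, *cfg.efficiency_params)
            true_kh = eff * true_kht
            pair = render_pair(truth, cfg) if render_images else None
            trace = (synthesize_flow_trace(true_kh, cfg, seed=child)
                     if true_kh > 0 else None)
            segments.append(SyntheticSegment(
                ground_truth=truth, image_pair=pair, flow_trace=trace,
                true_kht=true_kht, true_kh=true_kh,
                segment_type=cfg.segment_type, plant_id=plant, config=cfg))
    return segments
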