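# Methods

This note documents the models, parameter choices and numerical decisions
behind `xylemtrace`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The measurement model

A stem segment of length `L` (default 0.03 m, the trimmed sealed-tube
length) is perfused under a pressure gradient `ΔP` (default 0.04 MPa) while
an analytical balance records cumulative outflow mass every 20 s for
30 min. The experimental hydraulic conductivity is `K_h = F·L/ΔP`, with the
volumetric flow `F` obtained from the ordinary-least-squares slope of mass
versus time over the **final 50% of samples** (the window excludes any
initial filling/relaxation transient; the fraction is a parameter). Mass is
converted to volume with the perfusate density, default 998.2 kg m⁻³
(water at 20 °C; the 10 mM KCl solution used in practice is within 0.05% of
that).

Each section contributes one vessel table. A vessel's lumen is treated as
an ideal circular capillary: its diameter is the equivalent-area diameter
`D = 2√(A/π)`, and a vessel set has theoretical conductivity
`K_ht = Σ πD⁴/(128η)` with `η = 1.002×10⁻⁹ MPa·s`. Specific conductivities
divide `K_h` or `K_ht` by the summed lumen area of the same vessel set.
Resistivity is the reciprocal conductivity, `1/K_h` (MPa·s·m⁻⁴); no
additional length normalisation is applied, matching the units of the
quantity it reproduces.

### Conductivity criteria

* **BF**: conductive ⇔ wall completeness ≥ `theta_bf` (default **0.9**) and
  not flagged as expanding. "Fully developed" is not a printed number
  anywhere; 0.9 cleanly separates a closed annulus (measures ≈ 1.0) from
  the partial arcs the generator draws (< 0.875 after measurement error)
  and is exposed as a flag.
* **EF**: conductive ⇔ stain fraction **strictly greater than 0.5** ("more
  than one half of the perimeter").

Expanding (immature, enlarging) vessels are excluded from BF counts. They
are identified quantitatively as vessels whose wall is incomplete *and*
whose lumen area exceeds the median (configurable percentile) of the
unwalled vessels in the same section — expanding cells are conspicuously
large, other unwalled profiles small. This rule is this package's
quantitative stand-in for what the original workflow did by eye.

### Xylem types

PX (protoxylem: narrow, pith-facing, fiber-flanked) and MX (metaxylem,
with secondary xylem pooled into MX). Typing uses an **exact 1-D
two-means split of log lumen diameters** across the section; the
smaller-diameter cluster is PX. Position-based clustering (inner/outer
axis) was tried first and abandoned: for the realistic geometry of a tight
PX cluster plus an elongated MX radial file, one-dimensional k-means on
axis position provably splits the *file*, not the PX/MX boundary (the
within-cluster sum of squares is lower when the innermost MX vessels join
the PX cluster). Diameter is the feature that actually separates the
classes; axis position is retained as an orientation sanity check (PX
should lie nearer the pith; a violation warns). Degenerate fallbacks:
sections with fewer than two vessels, or without a clear bimodal split
(cluster geometric-mean ratio < 1.25), use a fixed cutoff of 8 µm.

## 2. Segmentation

Lumens are bright regions on a mid-grey tissue ground in BF. Detection:
Gaussian smoothing (0.3 µm), Otsu threshold computed over the
above-median intensities (the sub-median half of the histogram is wall and
background and would otherwise dominate), a floor of background
median + 5 robust SD so a signal-free raster yields nothing, hole filling,
watershed on the distance transform to split touching lumens, then area
(4–1000 µm²) and solidity (≥ 0.8) filters.

Each detected region is then **re-thresholded locally** midway between its
interior median and the 10th percentile of a thin outer shell
(0.3–2 µm outside the boundary). For a Gaussian-blurred step edge the
half-contrast contour coincides with the true boundary, so pixel-count
areas are unbiased to first order in the PSF width; the global Otsu level
alone would sit asymmetrically within the lumen→wall edge profile and bias
`D⁴` by several percent. The local threshold is additionally kept 3 noise
SDs above background so the refined component cannot percolate through
background noise into a neighbouring lumen.

Perimeter measurements sample the **lumen boundary** (the source study leaves open
whether "perimeter" means the lumen or the outer wall contour; the lumen
boundary is what thresholding delivers) at 360 equal-arc points. At each
point a radial ray runs outward across a wall annulus of width 2 µm
(spanning typical secondary-wall thickness at these pixel sizes):

* *wall completeness* — the fraction of rays whose minimum BF intensity
  falls below the dark-wall threshold;
* *stain fraction* — the fraction of rays whose annulus contains any pixel
  of the EF stain mask.

All intensity thresholds are relative: `median ± k · s`, where `s` is the
robust scale `max(1.4826·MAD, 0.04·(extreme percentile − median))`. The
MAD term adapts to noise; the dynamic-range term keeps the threshold
meaningful on noise-free data (where the MAD of a mostly-constant image is
zero) and vanishes as `k → ∞`. Defaults `k_bf = 3` (dark walls),
`k_ef = 6` (stain mask — the software analogue of choosing an exposure
short enough to suppress autofluorescence). Everything is therefore
invariant to scaling the intensities by a positive constant.

## 3. The synthetic-data generator

The generator is the study's stand-in for its unavailable micrographs and
balance recordings; its defaults are the study conditions.

**Layout.** Seven collateral bundles on a ring around the image centre
(the pith). Per bundle, a compact PX cluster (rejection-sampled in a disc
sized to its vessel count) sits on the pith-facing side; MX vessels form a
staggered double file running radially outward, with expanding cells
appended at the cambium-facing end. Vessels never overlap (centre distance
exceeds the radii sum plus a 6 µm clearance, which also keeps every
vessel's 2 µm measurement annulus free of its neighbours' walls).

**Counts.** Expected walled-vessel counts are the study's per-segment BF
means: 61 PX and 40 MX; expanding cells are added at 8% of that total.
Counts are Poisson *mixed over a shared lognormal segment-size multiplier*
(CV 0.5 apical / 0.2 basal, clipped for renderability): the study's
printed count SEs (±3 PX, ±7 MX over n = 22) correspond to SDs several
times the Poisson value, so i.i.d. Poisson counts would misrepresent the
between-segment variance structure that the comparison statistics live on.

**Conductive states.** A walled vessel is nonconductive with per-type
probabilities 18/61 (PX) and 17/40 (MX) — reproducing the study's
conductive counts 43 and 23 — with the per-segment fraction drawn from a
Beta distribution around those means (concentration 8 apical, 2 basal).
This mixing is calibrated to the study's Table-1 dispersions, where the
basal EF `K_ht` varies about twice as strongly as the BF `K_ht` (CV ≈ 0.61
vs 0.25): most of that excess can only come from segment-to-segment
variation in *which fraction of lignified vessels actually conducts*.
Conductive vessels carry stain fractions drawn from (0.7, 1.0);
nonconductive walled vessels are unstained half the time, otherwise
(0.05, 0.45); expanding vessels are unstained with absent or partial
(completeness 0.55–0.8) walls.

**Diameters.** Lognormal per type and segment level, truncated to
median×[1/1.25, 1.25], geometric SD 1.12. Medians (µm): apical PX 6.6 /
MX 11.5; basal PX 9.2 / MX 19.4 — chosen so the conductive-vessel mean
diameters reproduce the study's 8.26 µm (apical) and 12.73 µm (basal) and
the resulting `K_ht` magnitudes land on the printed 10⁻¹¹–10⁻¹⁰ m⁴ MPa⁻¹
s⁻¹ scale. The truncation makes the PX and MX diameter supports disjoint,
which is what renders the diameter-based typing exact on synthetic truth.
Only means ± SE are printed in the source study; the lognormal shape is an
assumption (positive, right-skewed, standard for conduit diameters).
Nonconductive vessels draw from the same distribution as conductive ones;
the small BF/EF mean-diameter shift the study reports (9.43 vs 9.66 µm) is
*not* emulated, because shrinking the nonconductive population would make
the type clusters overlap.

**Rendering.** BF: background 0.5, lumens 0.85, wall annuli 0.15 with
angular extent = wall completeness (full = 360°); EF: background 0.02,
stained wall arcs 0.9 with extent = stain fraction × 360°, bright fibre
speckle near the PX clusters (fibres *are* stained in reality, so they are
rejected spatially by the annulus geometry, not by thresholding — they are
kept ≥ 3 µm clear of lumen boundaries), and an autofluorescence floor at
2 noise SDs above background (below the `k_ef = 6` mask threshold by
construction, emulating correct exposure). Sub-pixel soft edges, Gaussian
PSF (σ = 0.2 µm), additive Gaussian noise (σ = 0.01 on a [0, 1] intensity
scale), 16-bit TIFF on disk. Default pixel size 0.2 µm/px (≈ 40×
objective with a standard microscopy camera).

**Flow traces.** Steady mass rate `K_h·ΔP/L·ρ`, an optional initial
exponential transient (amplitude 0.3 of the steady rate, τ = 180 s, i.e.
confined to the discarded first half of the 30-min trace), balance noise
SD 2×10⁻⁵ g (order of a 0.01 mg-readability balance). Per-segment true
`K_h = e · K_ht(conductive)`, with the efficiency `e` lognormal with mean
0.33 and CV 0.69 — the study's EF ratio statistics — truncated to (0, 1]
by redraw. The truncation lowers the realised mean to ≈ 0.31 and the CV to
≈ 0.58; the configured moments are the untruncated ones.

**Determinism.** Every stochastic element derives from a single integer
seed through `numpy.random.SeedSequence` splitting (cohort → per-segment
child seeds → separate render / flow / efficiency streams), so identical
(config, seed) reproduce bit-identical truth, images and traces.

**What the generator does not emulate** — and hence what passing tests do
not certify about real micrographs: optical anisotropy and chromatic
effects, uneven illumination, sectioning artefacts (smearing, torn walls),
dye-transport physics (partial staining is painted as a contiguous arc of
the drawn fraction, not a pit-pattern), photobleaching, touching lumens in
the default layout (watershed splitting is exercised by dedicated
fixtures), non-circular lumens, and the BF/EF diameter shift noted above.

## 4. Statistics

Paired BF-vs-EF tests across segments use the Wilcoxon signed-rank test
(zero differences discarded; exact null for ≤ 25 untied non-zero
differences, else the normal approximation with continuity correction) and
the paired t-test, via `scipy.stats`; the exact small-sample null is
independently verified in the tests by brute-force enumeration of sign
assignments. `K_h ~ K_ht` is ordinary least squares with `R²` the squared
Pearson correlation. The per-segment percent ratio `100·K_h/K_ht` is
summarised as the **mean of per-segment ratios** (never the ratio of mean
conductivities — the two differ, and only the former matches how the
reproduced summary statistics were constructed); its CV uses the n−1
sample SD. Percent count reductions are computed from per-segment mean
counts and rounded **half away from zero** — required for the printed
means 61→43, 40→23, 102→66 to give 30%, 43%, 35%. Segments without a
usable `K_h` are excluded from ratio/CV/regression cells with a warning.
No multiple-testing correction is applied, matching the reproduced
analysis. The published summary values that seed the in-study arithmetic
live in `xylemtrace.reference` as inputs; everything derived from them is
recomputed at run time.

## 5. Problem sizes in tests and acceptance

The acceptance script and test suite scale the imaging stages down —
small sections of 2–3 bundles (≈ 25–80 vessels) at 0.25 and 0.2 µm/px,
one 0.1 µm/px section for the sub-pixel `K_ht` recovery check — while the
statistical properties run on full-size cohorts (200 cohorts × 11 plants ×
2 segments, truth-derived vessel tables, synthesized flow traces). These
sizes were chosen so the whole suite completes in a few minutes while
every stage is still exercised at full fidelity somewhere: the two
rendered default-size sections in `analysis/` (≈ 120–130 vessels each)
confirm that agreement does not degrade with section size.

## 6. Known limitations

* The expanding-vessel flag is only as good as its size rule; on truth
  tables where all unwalled vessels are expanding, the percentile rule
  flags about half of them. This cannot affect conductivity calls (any
  incomplete wall already fails the BF criterion) but the flag itself
  should not be over-interpreted.
* Typing by diameter assumes PX and MX diameter ranges do not overlap
  within a section; real sections with a continuous size gradient would
  need the positional information the synthetic layouts make redundant.
* `K_h` estimation assumes the trace reaches steady state within the
  discarded window; traces with slower transients need a smaller
  `window_fraction`.
* Resistivity is reported as `1/K_h` without length normalisation; if a
  per-length convention is wanted, divide by `L` explicitly.
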