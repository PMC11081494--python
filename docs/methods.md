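# Methods

This note documents the models and conventions the package implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish about real data.

## Coordinates and angles

All geometry lives in a right-handed (AP, DV) frame in micrometres: AP = +x
toward the posterior, DV = +y away from the ventral midline. Pixel (row,
col) centres map to x = (col + 0.5)·pixel_size, y = (row + 0.5)·pixel_size.
Undirected angles (interface orientations, cell long axes) are reported in
degrees from AP in [0, 90]; directed axis angles (ellipse long axis,
bipolarity phase) in [0, 180). An interface is "DV-oriented" when its
orientation is strictly greater than 45° from AP; ties at exactly 45° count
as AP-oriented.

## Mesh model and tracking

A movie is an ordered list of frames; each frame holds cells (simple
polygons with stable track ids), interfaces (straight vertex-to-vertex
junctions between cell pairs), and vertices (points where ≥ 3 cells meet).
From label images, interfaces are extracted from 4-connected pixel adjacency
and vertices from 2×2 pixel blocks containing ≥ 3 distinct labels; each
interface also carries the two per-cell 1-pixel boundary lines used for
fluorescence quantification. Frame-to-frame linking assigns each cell to the
previous-frame cell of maximal pixel overlap, ties broken by smaller
centroid displacement; unmatched cells open new tracks.

Cell typing uses midline proximity in units of cell rows: rows are bands of
|DV position| one median cell diameter wide; rows closer than the configured
mesoderm half-width are mesoderm, the next row mesectoderm, the rest
ectoderm (half-width ≈ 9 rows for a wild-type-like mesoderm of ~18 cells,
4–5 for a twist-like one). A manual override table is applied last; there is
no automatic mitosis detector. "Distance from mesectoderm" is the distance
from the mean |DV| of the first ectodermal row at a reference time (30 min
by default), assigned per track.

Track quality is filtered on four criteria — minimum track length, area
bounds, |d ln A/dt| bound, and velocity relative to the *median* of the
neighbours (the median makes the filter insensitive to one mistracked
neighbour). Thresholds are configuration; the defaults (4 frames,
10–600 µm², 0.5 pp/min, 10 µm/min) are deliberately loose so that only
gross tracking failures are removed. Removal counts are logged per
criterion. Undefined values propagate as NaN, never as zero, into all
summaries.

## Strain-rate decomposition

Rates of change use a centred window: x'(t) = (x[t+2] − x[t−2]) / elapsed
minutes, i.e. 1 minute either side at the 30-s frame interval, NaN where the
window is truncated.

**Tissue strain rate.** Centroid velocities of the focal cell and its
first-ring neighbours (central differences across the window) are fit with
an unweighted linear field v = L x + c; the tensor is sym(L). Cells with
fewer than three usable neighbours are undefined. The first ring is the
smallest domain that is still "local" tissue; second-ring variants change
little on smooth flows but blur spatial gradients.

**Cell-shape strain rate.** The best mapping of the cell's shape across the
window. Where boundary-vertex correspondence exists (mesh-native tracks),
the estimator is the least-squares affine map F of index-matched boundary
vertices from t−2 to t+2, and the rate is sym(log F)/elapsed — exact for
affine motion and exactly zero for rigid rotation. Without correspondence
(label-image tracks), the fallback maps the cell's area-normalised
second-moment tensor S(t−2) onto S(t+2) through the unique
symmetric-positive-definite F with F S₀ F = S₁ and takes log F / elapsed.
The fallback cannot separate rotation from shear — for a rigidly rotating
anisotropic cell it reports a spurious off-diagonal rate ≈ rotation-rate ×
eccentricity, which is why the boundary-mapping estimator is primary. Both
agree exactly on rotation-free deformations.

**Intercalation strain rate** is defined as tissue minus cell-shape, so the
decomposition identity is exact by construction; its content is in the two
measured terms.

**Shape metrics.** The equivalent ellipse has semi-axes 2√λ of the
second-moment eigenvalues. Cell orientation is the acute long-axis angle
from AP (undefined for isotropic cells). Axial shape elongation is
e·(−cos 2θ) with e = (a−b)/(a+b) and θ the directed long-axis angle: the
unique smooth form, up to interior scaling, that is +1/−1 in the strong
DV/AP limits, 0 for isotropic cells and at 45°, antisymmetric under 90°
rotation. A misalignment of the polarity axis by φ costs at most
100·(1 − cos φ) percent of any projected rate — 3.4% at φ = 15°.

## T1 detection and productivity

Contact series per cell pair come from the per-frame interface sets; state
runs shorter than 2 frames (1 min) are reverted to suppress segmentation
flickers near 4-way vertices. A T1 is a contact loss whose quartet — the two
common neighbours of the losing pair at the last contact frame — gains
contact within a short search window; the swap time is the midpoint between
the last old-contact and first new-contact frames, which also covers
transient 4-way-vertex frames. Events with incomplete quartets (field edge,
rosettes) are discarded.

Productivity is a continuous function of the gaining-pair centroid angle θ:
−cos 2θ, matching +1/0/−1 at 90°/45°/0° and equal to the strain projection
factor, which is what makes exchange rates directly comparable to
intercalation strain rates; a linear-in-angle alternative through the same
anchors is available as a configuration option. Raw and productive exchange
rates divide the count (or the productivity sum) per time bin by the mean
number of DV-oriented interfaces and the bin width in minutes.

Time-to-swap alignment re-indexes the losing interface's history by t −
t_swap (negative before the swap) and the gaining interface's future
(positive after); proportional rates are absolute rates over current length;
ensembles report mean ± SE per lag. Shrinkage pools default to 0–30 min and
growth to 0–20 min of synchronised time, both configurable.

## Myosin II quantification

**Normalisation.** Per frame, pixels at or below the frame's 5th percentile
are set to zero (threshold-zeroing, implemented literally, not subtraction);
then all frames are scaled by the single factor 200 / P98.5(reference
frame), clipping at 255 — the 200–255 band is headroom for a tail of bright
pixels. Zeroing precedes the stretch; since the stretch is monotone the
order only matters for the factor itself. The map is idempotent and
order-preserving below the ceiling.

**Channel registration.** When the fluorescence channel lags the membrane
channel, junction pixels are displaced by offset_fraction (channel offset /
frame interval) of their predicted inter-frame flow — the focal cell's
centroid displacement plus, optionally, its shape strain applied about the
centroid — and the image is sampled bilinearly at the displaced positions.

**Junctional pools.** A junction is measured on the two 1-pixel lines either
side of the vertex-to-vertex segment (for label-backed frames, the two
per-cell boundary pixel lines), averaged; pixels within 2 px of a vertex
(evaluated from both the sub-pixel vertex point and its pixel centre) form
the vertex pool; the remaining pixels of each cell are the nonjunctional
pool. Interfaces with no surviving pixels are undefined.

**Bipolarity.** Each cell's interface densities are fit with the period-2
harmonic M + A·cos 2(ψ − φ) against junction orientation ψ, by weighted
least squares with weights equal to the interfaces' angular extents about
the centroid measured on the *unstretched* outline (boundary mapped by
S^(−1/2) of the det-normalised second-moment tensor). Unstretching through
the weights removes the coverage bias of elongated cells; fitting at the
physical orientations keeps the amplitude unbiased (a piecewise-constant
360-point resample plus DFT would attenuate hexagon amplitudes by
sin 60°/60° ≈ 0.83). Cells with fewer than three defined interfaces are
undefined. Phase 90° means enrichment on DV-oriented junctions — intensity
peaks at the cell's anterior and posterior faces — and the AP projection
A·cos 2(φ − 90°) is positive exactly in that planar-polarised configuration.

## Synchronisation and statistics

**Synchronisation** is two-stage per genotype: each movie is offset so its
mean AP-projected tissue strain rate first reaches 0.01 pp/min sustained for
≥ 2 min (the small positive threshold rides over fluctuations around onset;
the persistence rule is this package's definition of "sustained"); then a
single genotype shift places the zero crossing of the genotype-average curve
at t = 0. Movies never reaching the threshold are flagged unsynchronisable
and excluded.

**Genotype comparison** runs per 30-s bin on synchronised time. The default
is a cell-level mixed model (random intercept per embryo, REML) testing the
genotype fixed effect with a t reference on n_embryos − 2 degrees of freedom
— the contrast is estimated *across embryos*, so a normal Wald reference is
anticonservative for cohorts of a few embryos (measured type-I ≈ 0.03 at
α = 0.01), while the between-embryo t reference is calibrated (≈ 0.01).
When the variance fit hits the boundary, or with < 3 embryos or single
observations per embryo, the test falls back to the pooled t-test on embryo
means, which is the exact balanced-design equivalent. No multiple-testing
correction is applied across bins; significance is reported per bin.
Ribbon summaries report cross-embryo mean ± SE; the 3-bin centred moving
average exists only on display copies — tests always run on unsmoothed
values. Because AP position is not registered across movies, cross-movie AP
comparisons go through a central window: [anterior bound, anterior bound +
100 µm].

## Synthetic embryos

The generator's defaults are the study conditions. The default scene is a
~200 × 115 µm field of ~12-µm cells (≈ 180 cells), 30-s frames from −15 to
+30 min of extension onset, ventral midline at the field's y = 0 edge.
Tessellations are Voronoi diagrams of a jittered triangular lattice
(jitter s.d. 0.2 diameters); flows are prescribed analytic velocity fields
whose exact strain tensors are recorded as ground truth:

- *DV pull* (mesoderm-invagination surrogate): E_yy = rate·exp(−|y|/50 µm),
  rate 0.03 pp/min at the midline, active −13 to +7 min;
- *AP pull* (extension engine): E_xx ramping linearly from 0 to 0.04 pp/min
  across the field toward the posterior, active 0 to +20 min;
- wild-type-like = both; twist-like = AP pull only. Embryo-to-embryo
  variability: rate factors ~N(1, 0.05), onset shifts ~N(0, 1 min).

Scripted T1s pick interior, clearly DV-oriented junctions with disjoint
quartets; the losing junction shrinks linearly over 4 min to a 4-way vertex,
topology swaps, and the new perpendicular junction grows at 1 µm/min.
Simultaneous swaps sharing a cell are rejected; any cell inversion aborts
with a diagnostic.

Rendering paints each junction as the two 1-px cortical lines at
0.25 µm/px — the sampling regime of spinning-disc imaging at the
adherens-junction plane, where junctions are many pixels long — with
intensity base + mean of the two cells' A·cos 2(ψ − φ) contributions,
Gaussian noise (s.d. 8 on the 8-bit scale), and quantisation. Per-cell
amplitude and phase are smooth tissue-scale fields (amplitude 40 ± 20 f.i.,
phase 90 ± 15°) plus small cell jitter (s.d. 2 f.i. / 3°): planar polarity
in this tissue is driven by shared positional signals, so neighbours are
strongly correlated — and because shared junctions physically average the
two abutting cortices (as does the two-line measurement), a generator with
cell-independent polarity would make faithful per-cell recovery impossible
for any estimator, not just this one.

## What the synthetic validation shows — and does not

Passing the closure suite establishes that the estimators recover prescribed
kinematics to ≈ numerical precision on clean meshes, that event detection is
exact against scripted topology changes, that the fluorescence chain is
unbiased against its own rendering model, and that the per-bin test is
calibrated under a Gaussian two-level null. Real movies add segmentation
error, curved-surface projection artefacts, bleaching, mitoses and
out-of-plane movement, none of which the generator emulates; the quality
filter and flicker suppression address mild forms of these, but accuracy on
real data is bounded by segmentation quality, not by these algorithms.
Problem sizes in the test suite (≈ 150–200-cell fields, 3 embryos per
genotype, 1,000 null bins) are the package's choice of desk-scale validation
conditions.

## Numerical choices

Vertex advection uses RK4 with 4 substeps per frame. SPD roots/logs go
through symmetric eigendecomposition; general 2×2 logs through
`scipy.linalg.logm` (real part). The harmonic fit needs ≥ 3 interfaces; the
equivalent-ellipse orientation is flagged undefined below eccentricity
1e−9. Linking ties break by centroid distance; row-banding uses the median
cell diameter per frame. Reruns are bit-reproducible given seeds; every
pipeline run writes a manifest with the package version, config hash, and
per-movie seeds.

## Known limitations

- The label-image path has no manual-correction loop; gross segmentation
  errors must be filtered, not fixed.
- The moment-tensor fallback for cell-shape strain conflates rotation with
  shear for anisotropic cells (documented above); supply vertex
  correspondence when rotation is expected.
- Rosettes (≥ 5-cell vertices) are not resolved into sequential T1s; events
  with ambiguous quartets are dropped and logged.
- The flat-field ("domed intensity") correction hook for real microscope
  data is not implemented; normalisation assumes a flat illumination field.
- Curved-surface extraction from 3D stacks is out of scope: inputs are
  planar; when given a z-stack the fluorescence path applies only the
  ±2 µm maximum-intensity projection pre-step.
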