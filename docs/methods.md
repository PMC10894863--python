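# Methods

## Quantitative features

**Emphysema index (EI / %LAA-950).** The percentage of lung voxels strictly
below −950 HU on inspiratory CT, per region (whole lung, right, left, five
lobes). "Below" is strict: a voxel at exactly −950 HU is not
low-attenuation. The lung mask used for densitometry has airway voxels
(lumen and wall) carved out, so the air-filled bronchial lumen is not
mistaken for emphysema. HU are clamped to [−1100, 3100] on load; the
densitometric threshold presumes calibrated HU, so the pipeline makes no
attempt at kernel or dose harmonization.

**Emphysema size (D-slope).** Low-attenuation voxels are grouped into 3-D
connected components (26-connectivity by default; 6 available for
sensitivity analysis). A component of volume V mm³ is assigned the
equivalent-sphere diameter (6V/π)^(1/3). For each distinct observed
diameter d, the cumulative count of clusters with diameter ≥ d is computed,
and the slope of an unweighted least-squares line through
(log₁₀ d, log₁₀ N(≥d)) is reported as a positive number. Clusters below a
minimum diameter — conventionally twice the voxel spacing — are excluded as
unresolvable; single-voxel components are indistinguishable from noise at
CT resolution. On an exact discrete power law the estimator is exact (the
{1 mm × 3584, 2 mm × 448, 4 mm × 56, 8 mm × 8} set yields 3.0 to machine
precision). On continuous samples it is noisy; see *Estimator
characteristics* below.

**Airway wall thickness (Pi10).** Each airway site (centre, axis,
generation) is measured on the plane perpendicular to the axis, resampled
at 0.1 mm by trilinear interpolation — a tenfold magnification relative to
sub-millimetre CT. From the lumen centre, 64 rays are cast; on each ray the
inner wall edge is the first point where attenuation rises above halfway
between the lumen minimum and the wall peak, and the outer edge is the
first point past the peak falling below halfway between the peak and the
parenchymal floor (estimated as the profile minimum within 6 mm past the
peak). The wall peak is located inside a 5 mm window after the first rise so
that a neighbouring structure cannot capture it. Rays without a detectable
wall are dropped; a site fails if more than 25% of rays fail (a homogeneous
volume therefore fails cleanly). This half-maximum rule is an approximation
of the integral-based edge operators used by commercial airway tools; its
accuracy depends on the edges being blurred over roughly a voxel, which is
what CT partial volume produces (on crisp binary test objects it is
systematically biased — hence the phantom rasterizes airway walls with
supersampled partial-volume mixing). The internal perimeter Pi is the
perimeter of the inner-edge polygon; the wall area WA is the shoelace area
between outer and inner polygons. Pi10 is the value at Pi = 10 mm of the
OLS line of √WA on Pi over measurements in generations 3–8. Airway
centreline detection on real CT is out of scope: sites come from the
phantom truth or a user-supplied site table.

**Peripheral vessels (VN<5 mm²).** The subpleural surface at depth t
(default 12 mm) is the iso-surface of the Euclidean distance transform of
the lung mask: shell voxels are lung voxels with distance ≥ t having a
6-neighbour at < t. The surface area is measured with marching cubes on
the distance field, which is orientation-unbiased — raw shell-voxel
counting is off by the mean maximal normal component (≈ 0.83) depending on
local surface orientation. Vessel crossings are 26-connected components of
the vessel mask intersected with the shell; a crossing's area is its voxel
count times the squared mean in-plane spacing, and only crossings strictly
under 5 mm² count. VN is the count per cm² of surface; the per-area
normalization is a documented interpretation choice that makes the
quantity scale-free. Regional surfaces inherit area in proportion to their
share of shell voxels, and a crossing belongs to the region holding its
centroid. Vessel segmentation on real CT is an input, not a capability.

## Retrieval

Feature vectors are complete 22-tuples, all finite and non-negative. The
per-feature normalizer is the 95th percentile over the database, with
linear interpolation between order statistics; a feature constant at zero
gets normalizer 1 (warning) so its normalized values stay zero. Normalized
values are not clipped at 1. Per category the distance is cosine distance
between the category sub-vectors; a zero-norm sub-vector is at distance 0
from another zero sub-vector and 1 from anything else. The combined
distance is the unweighted mean of the four category distances — the four
phenotype axes are treated as equally informative; a concatenated-vector
cosine mode is exposed for comparison (`mode="concat"`). Ties break
lexicographically by scan id. Queries are searched against the full index
(their own baseline pair included); self-exclusion applies only when the
query itself is an index member. The index serializes to JSON; floats
round-trip bit-exact through the shortest-repr encoding.

## Evaluation protocol

Paired-query accuracy is the fraction of queries whose baseline appears in
the top k (k = 1, 3, 5), with Wilson score 95% intervals. Subgroup analysis
splits queries at the median of a feature (strictly above vs at-or-below;
an even number of distinct values gives an exact 50/50 split) and compares
hit rates with Fisher's exact test. The result carries the two-sided p, the
one-sided (upper-tail) p, and the plain chi-square p: for the canonical
18/25-vs-12/25 table these are 0.148, 0.074 and 0.083 respectively — a
published value of 0.09 for this table corresponds to the one-sided exact
test (or chi-square), not to the two-sided Fisher.

Reader scores (ordinal 1–5, two readers, five ranks per query) are
summarized per reader, per rank, and pooled: percent scoring ≥ 4, mean, and
95% CIs from a query-clustered bootstrap (whole queries resampled with
replacement, 1000 resamples, seeded; the SE is the bootstrap SD of the
mean). The clustered bootstrap replaces a GEE model fit: it targets the
same within-query correlation while leaving fewer modelling choices open.
Wilson CIs here and elsewhere are a deliberate, reproducible choice; no
attempt is made to reproduce published interval constructions whose method
is unstated.

Agreement: weighted Cohen's kappa with linear weights |i−j|/(c−1) by
default (quadratic available) over the sorted union of observed categories
(an explicit category list can be passed), CI by query-clustered bootstrap;
and ICC(2,1) — two-way random effects, absolute agreement, single measures
— from the ANOVA mean squares with the Satterthwaite/F-based interval.
Zero between-unit variance yields ICC 0 with a warning rather than NaN.

## The phantom

The generator emulates the *measurement geometry* of an obstructive-lung-
disease CT, not its texture: two ellipsoidal lungs of Gaussian parenchyma
(default N(−850, 30) HU) at 0.7 mm isotropic spacing, split into five
"lobes" by height.

* *Emphysema*: non-overlapping −1024 HU spheres with diameters from a
  truncated Pareto (default exponent 3.5 on 3–20 mm), packed by rejection
  sampling until a target volume fraction (default 12%, the scale of a
  moderate-emphysema cohort mean EI) is reached. Sphere surfaces are kept
  more than √3·spacing apart so rasterized spheres can never be
  26-connected — the realized cluster count equals the packed count
  exactly. Candidate centres are drawn only from voxels deep enough in the
  lung and ≥ 4 mm clear of airways and vessels; a retry cap turns
  infeasible packings into a clean error.
* *Airways*: one straight tube per generation (defaults: generations 3–8,
  radii 3.0→1.3 mm, walls 1.6→1.3 mm — thickened walls typical of airway
  disease, analytic Pi10 ≈ 4.4), placed on a ring sized so adjacent outer
  walls keep ≥ 4 mm of parenchyma between them. Lumen (−1000 HU) and wall
  (0 HU) are rasterized with 4× supersampled partial-volume mixing.
* *Vessels*: +100 HU cylinders aimed radially outward (default 40
  sub-threshold per lung with 1–3.5 mm² sections, plus 2 oversize 10 mm²
  vessels the counter must exclude), spanning depths ≈ 18→6 mm so each
  crosses the 12 mm surface exactly once. The cylinder is confined to the
  first contiguous in-lung ray segment (a ray exiting the medial surface
  would otherwise re-enter the other lung and deposit spurious crossings),
  and a 6-connected core line is painted along the axis — a thin voxelized
  cylinder can have diagonal gaps, and only a 6-connected path is
  guaranteed to intersect a 6-neighbour-defined iso-shell. Crossings are
  kept 3 mm clear of lobe boundaries so their region is unambiguous.

Ground truth is computed from the realized voxel grid, not the analytic
spec: true EI is the voxel-counted LAA fraction of the generated volume,
true cluster diameters come from per-sphere voxel counts, true Pi10 from
the analytic per-tube (Pi, WA) via the same OLS, and true vessel counts
from the constructed crossings. Recovery tests can therefore demand
exactness (EI, VN) rather than discretization-limited agreement.

What the phantom does **not** emulate: CT noise correlation and kernels,
breathing/cardiac artefacts, real airway branching and curvature, vessel
trees, lobe fissures, or any anatomical covariance between the four
phenotype axes. Passing phantom tests therefore validates the geometry and
arithmetic of the quantifiers, not their robustness to real-scanner
conditions.

The tabular generators are separate: `generate_paired_feature_table` draws
22-feature vectors from plausible marginals (whole-lung EI ≈ N(12.2, 13.1)
clipped at 0.1, D-slope ≈ N(5.1, 1.5), Pi10 ≈ N(4.0, 0.8),
VN ≈ N(0.6, 0.1); lobar values jitter lognormally around the whole-lung
value, and regional aggregates are recomputed from the lobes), then adds
truncated-at-zero Gaussian longitudinal noise to make each follow-up
(default per-category SDs 1.0 / 0.2 / 0.15 / 0.03 — small against
between-patient spread, emulating stable disease over ~3 years).
`generate_reader_ratings` gives each retrieved scan a latent similarity
decreasing in retrieval distance (and maximal for the query's own pair);
a concordance parameter in [0, 1] interpolates between independent readers
(concordance 0, kappa ≈ 0) and identical readers (concordance 1,
kappa = 1).

## Estimator characteristics and problem sizes

The D-slope estimator on continuous truncated-Pareto samples has two
systematic behaviours, mapped by simulation with an independent sampling
oracle. First, the truncated distribution's cumulative curve bends down
near the maximum diameter; the unweighted fit at distinct observed
diameters picks this bend up as a positive bias that grows as the range
ratio dmax/dmin shrinks (≈ +0.5 at ratio 4, ≈ +0.05 at ratio 10). Second,
voxel quantization collapses the many small-diameter samples onto few
distinct values, shifting fit weight to the sparse, high-leverage tail;
holes at least 4–5 voxels across keep this in check. Even so the estimator
retains an SD of roughly 0.1 at ~3000 clusters that shrinks only slowly
with sample size. The exponent-recovery check therefore runs on a dedicated
emphysema-only phantom (`emphysema_recovery_spec`: 5–50 mm holes at 1.0 mm
spacing, 15% fraction, ~3000 clusters, ~20 s to generate) where the bias is
negligible; a recovered value within ±0.2 of the generating exponent is
expected for most seeds but not guaranteed for every one — the fixture seed
is fixed for reproducibility.

Other problem sizes: the default imaging phantom (two ≈ 36×40×48 mm
semi-axis lungs at 0.7 mm, ≈ 7.6M voxels) builds in ≈ 7 s and quantifies in
≈ 3 s; the synthetic database mirrors a 550-scan index with 50 held-out
paired queries; reader-statistics bootstraps use 1000 resamples (200 in the
acceptance script). The annulus accuracy check uses 0.5 mm voxels, where
the half-maximum rule measures an r=2 mm, w=1 mm annulus to +0.6% (Pi) and
+1.1% (WA).

## Numerical conventions

Grids are indexed (x, y, z) with physical mm coordinates from spacing and
origin (LPS); alignment tolerance is 1e-6 mm. Percentiles use linear
interpolation between order statistics. OLS fits use `numpy.polyfit`.
Degenerate inputs raise typed errors rather than returning NaN:
insufficient distinct diameters or perimeters, empty regions or surfaces,
misaligned grids, infeasible packings, undefined kappa. Retrieval distances
are clipped to [0, 1] against floating-point cosine overshoot. All
stochastic components take explicit seeds and are bit-reproducible given
one.
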