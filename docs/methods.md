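# Methods

This note records the models, conventions, and numerical choices behind
`placenta3d`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Anatomical model and coordinate normalization

An implantation site is modeled as a **half dome**: the decidua is the
shell between an inner cap fitted to the junctional-zone outer edge (the
placental border) and an outer cap fitted to the myometrium outer edge,
restricted to the antimesometrial side of a cutoff plane. The frame is
fitted from labelled landmarks only:

- **Boundary caps.** Both surfaces are spherical caps with a shared
  center, fitted jointly by nonlinear least squares on the radial
  residuals (algebraic sphere fit as initialisation). A triaxial
  axis-aligned ellipsoid per surface is available via
  `boundary_model="ellipsoid"`. Spheres are the default because the
  anatomy is dome-like and nothing in a landmark export justifies more
  degrees of freedom; the fit report carries the max and RMS residual so
  a poor fit is visible.
- **Dome axis** = unit vector from the centroid of the
  luminal-epithelium landmarks (mesometrial side) through the centroid of
  the junctional-zone landmarks. Front/back landmarks fix azimuth zero
  (front direction projected orthogonal to the axis); the polar
  coordinate runs 0 at the apex to 1 at the equator.
- **Depth** of a point is the linear ray parameter
  d = (r − r_jz) / (r_myo − r_jz) along its ray from the cap center:
  0 on the placental border, 1 on the outer myometrium. Depth continues
  past 1 into the myometrium on the same parameterization (no
  re-normalization by myometrial thickness), keeping one continuous axis
  for classification; points beyond `d_max_allowed` (default 1.5) are
  flagged `outside` and excluded from densities but reported. A point at
  exactly d = 1 is myometrial (closed lower bound), matching the reading
  that an invader "within the myometrium" includes its inner face.
- **Mesometrial exclusion** is a plane through the luminal-epithelium
  centroid normal to the axis; spots on the mesometrial side are removed
  during filtering, because the CK8 signal there cannot be attributed to
  trophoblasts. The true exclusion region in imaging software is a
  hand-traced mask; a plane is the reproducible geometric surrogate.
- **Volume floor** default 100 µm³ (inclusive: a spot exactly at the
  floor is kept). The floor models the light-sheet size-detection limit;
  the exact threshold is instrument-dependent and config-exposed. Missing
  volume columns degrade to a logged no-op.

Because both boundary models are rotation-invariant around the fitted
center and all constructions use only relative geometry, a joint rigid
transform of spots and landmarks leaves every normalized coordinate
unchanged (asserted to 1e−6 in the tests).

## Density overlap

Artery and trophoblast channels are compared in a **normalized dome
embedding**: each in-domain point maps to `unit_direction × (1 + depth)`,
so the placental border becomes the unit hemisphere and the myometrium
outer surface radius 2. This preserves angular structure while removing
absolute size differences between sites.

The density estimator is a Gaussian product-kernel KDE evaluated on a
regular grid (default 50×50×50 spanning the data bounding box plus 3
bandwidths). Implementation: linear (cloud-in-cell) binning followed by
separable Gaussian filtering of the grid — identical to the direct kernel
sum up to bin discretization, and fast enough that a full bootstrap
(thousands of grid evaluations) is tractable. After optional masking to
the half-dome support, the grid is renormalized so Σ values × voxel = 1;
mass smoothed past the grid edge is thereby folded back.

- **Bandwidth**: per-axis Scott's rule, h_j = sd_j · n^(−1/7), computed
  from the channel being estimated. Using each channel's own spread (the
  standard KDE convention) matters for the overlap statistic: a bandwidth
  pooled across both channels is inflated along their separation axis by
  the between-channel distance, which by the closed-form Gaussian overlap
  (below) adds avoidable smoothing bias to BC. A degenerate axis (zero
  spread in a bootstrap resample) falls back on the largest
  non-degenerate axis bandwidth, so resampling smooths rather than
  crashes.
- **Bhattacharyya coefficient**: BC = Σ √(p_i q_i) × voxel volume on a
  shared grid (a Riemann sum — the simplest faithful numerical
  integration), clipped to [0, 1], exactly symmetric. For two
  equal-covariance isotropic normals the closed form is
  BC = exp(−Δ²/(8σ²)); the pipeline estimate is checked against it at
  σ = 0.1, Δ = 0.2 (BC = e^(−1/2) ≈ 0.6065) within ±0.03.
- **Bootstrap**: each replicate independently resamples both channels
  with replacement at their original sizes and recomputes both KDEs
  (bandwidth re-derived from the resample) and BC on one fixed grid;
  the median and percentile 2.5/97.5 quantiles are reported, and the seed
  is recorded in every result. Spots are the resampling unit — the most
  direct reading of bootstrapping a point pattern; site-level resampling
  would answer a different (between-site) question. BC is computed per
  implantation site and only then summarized across sites, matching
  per-site reporting.

Known estimator properties, documented so downstream users do not
misread them as bugs: (i) the kernel-smoothing bias of BC is upward for
overlapping unimodal densities and the resampling-noise bias is downward
(√ is concave), so bootstrap replicate medians sit slightly below the
point estimate — for identical channels the point BC is exactly 1 while
replicate medians are ~0.97–0.99 at n = 10³; (ii) the L1 risk of a 3D
KDE decays slowly (n^(−2/7)); at n = 5000 the optimal-bandwidth L1
distance to the generating density is ≈ 0.13, which is what the test
asserts against (< 0.15). The bootstrap-CI calibration study in the
acceptance tests uses 2000 points per channel — the operating scale of
the pipeline's channels (thousands of detections per site) — with
n_boot = 200 and 100 simulated datasets; observed coverage of the
closed-form BC is ≥ 88/100.

## Localization, artery metrics, and virtual sections

- **Classification** is exhaustive and mutually exclusive over in-domain
  trophoblasts: region from the depth flag, artery adjacency from the
  minimum raw-µm distance to the artery geometry (traced centerlines
  resampled at 10 µm when available, otherwise artery spots).
  `r_adj` defaults to 20 µm, about one to two trophoblast diameters —
  "within/surrounding an artery" has no standard metric definition, so
  the radius is config-exposed and recorded in every output.
- **Branch counting**: an artery enters the decidua where a centerline
  edge crosses d = 1 inward (parent ≥ 1, child < 1); a path that
  oscillates across the boundary counts once (no ancestor crossing), a
  myometrial bifurcation descending twice counts twice.
- **Envelopment**: fraction of an artery's decidual centerline samples
  (10 µm arc-length spacing; point-to-sample distances are accurate to
  step/2) with a trophoblast within `r_env` (20 µm). "Enveloped through
  most of its length" is read literally as coverage ≥ 0.5. Arteries with
  no decidual segment leave the denominator with a note.
- **Placental connection**: a tree counts when a terminal node's depth is
  within `tolerance` (25 µm) of the placental border along its own ray.
- **Virtual sections** emulate cryosection quantification: slabs of
  70 µm (the cryosection thickness) at offsets {−240…+240} µm around the
  midline plane (the plane holding the dome axis and the front–back
  axis), at least 3 non-empty sections required for a mean — mirroring
  the minimum-three-sections convention. In-slab objects are projected
  into the plane and their relative 2D depth computed against the fitted
  border and myometrium surfaces intersected with the slab: depth = (min
  distance to the border set) / (directed Hausdorff distance from the
  myometrium set to the border set), clipped at 1 with a clip count. The
  discrepancy ratio is the 3D maximum depth over the mean per-section 2D
  maximum. The 2D convention measures chords in the section plane rather
  than rays through the dome center, so a per-section maximum can exceed
  the 3D maximum by up to ~2% for off-midline slabs; tests bound the
  subset property with that documented allowance.

## Statistics

Omnibus and pairwise tests wrap scipy/statsmodels implementations;
Dunn's rank-based post hoc (z statistics on mean ranks with tie
correction) is implemented in-package because no installed library
provides it. "KS with Dunn post hoc" is realized as pairwise two-sample
KS with Bonferroni (there is no multi-group KS omnibus; the omnibus slot
reports Kruskal–Wallis). Fisher's exact two-sided p sums all tables with
the observed margins whose probability does not exceed the observed one;
the test suite checks it against a full integer-arithmetic enumeration
for every 2×2 table with total ≤ 40. Odds-ratio CIs are Wald on the log
scale with Haldane–Anscombe 0.5-correction for zero cells (flagged in
the output). ΔΔCt uses the arithmetic mean ΔCt of the reference group
(fold = 2^−ΔΔCt), making the reference geometric-mean fold exactly 1.

## Synthetic generator

The generator emulates the measured structure of implantation sites, not
their imaging. Geometry defaults (placental-border radius 900 µm,
myometrium 1500 µm, outer extent 1800 µm) are plausible mid-gestation
scales, exposed in config; nothing downstream depends on their absolute
values because the analysis normalizes them away. Arteries are helical
centerlines (coil radius 60 µm, pitch 150 µm — a minimal "loose spiral")
descending from random myometrial entry directions toward the apex; the
helix radius is constant, so |position| is monotone along the path and
each tree crosses d = 1 exactly once, making the branch-count oracle
exact. A configured fraction of trees extends to the placental border
(connected), the rest stop a quarter to half way through the decidua.

Trophoblast categories are drawn per point from a multinomial over
{myometrial m, perivascular p_env, interstitial 1−m−p_env}, so the
reported localization splits are preset directly (control 75/25/0,
knockout 10/70/20 with 75% of myometrial invaders artery-targeted).
Interstitial depths follow Beta(α, β) scaled to (0, d_cap); d_cap = 0.95
encodes "invasion nearly 90% of the way through the decidua" as a
support bound rather than a mean. Azimuth is von Mises with
concentration κ (0 = isotropic control; the knockout preset uses κ = 4
centered off-midline, emulating the peripherally biased invasion).
Perivascular points snap to a uniformly chosen decidual centerline
sample plus an isotropic offset ≤ r_env, with eligible samples
restricted to d ∈ [0.06, 0.94] (and myometrial targets to
d ∈ [1.05, 1.42]) so the snap offset cannot flip a point's region and
ground-truth labels stay exact; classifier and generator share one
resampling routine, so adjacency ground truth and recovered labels agree
by construction away from chance coincidences (≤ ~0.5% of interstitial
points fall within r_adj of an artery by volume ratio). The
`eligible_artery_fraction` knob restricts which arteries the perivascular
points decorate: the control preset uses 0.75 so the enveloped-artery
fraction lands in the observed 50–75% band, and tests recover a 0.6
setting to ±0.1 over 20 seeds. Volumes are log-normal around 500 µm³
with a 5% contaminant fraction below the volume floor and a 2%
mesometrial-artifact fraction, exercising both filter rules with exact
expected counts. Landmarks are jittered (10 µm default) samples of the
true surfaces, and the whole site receives a random rigid pose so no
analysis can rely on axis alignment.

What the generator does **not** emulate: imaging noise and segmentation
errors beyond the volume contaminants, non-spherical anatomy (fitting
residuals on real sites will exceed the synthetic ones), within-artery
radius variation in spot density, spatial correlation between
trophoblasts, and any biophysics of migration. Passing tests therefore
demonstrate correctness of the measurement pipeline under its geometric
assumptions, not robustness to real-tissue deviations from them.

## Problem sizes and determinism

Defaults were chosen so the full test suite and the acceptance script
run comfortably on one CPU: sites of 3000 trophoblasts and 16 arteries,
50³ density grids, bootstrap n = 1000 by default but 200 in the
calibration study and the acceptance script, Monte-Carlo checks at 10–20
seeds. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; sub-seeds derive from a `SeedSequence`, and
every stochastic result records its seed. Re-running any pipeline stage
with identical inputs, config, and seed is bit-identical.

## Known limitations

- The half-dome parameterization is a declared convention; if the true
  normalization of a given dataset anchored its axis differently, depths
  near the equator shift slightly (the boundary surfaces, being fitted,
  do not).
- Sphere/ellipsoid caps cannot follow locally concave anatomy; the
  residual report is the guard rail.
- Percentile bootstrap CIs for the overlap statistic undercover at small
  channel sizes (hundreds of points), where the resampling-noise bias of
  BC is large relative to the CI width; at the pipeline's operating
  scale (thousands) calibration is within the tested band.
- Point-to-sample distances overestimate point-to-curve distances by up
  to half the resampling step (5 µm at defaults).
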