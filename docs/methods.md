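# Methods

## The dispersion statistic

Given a set of nuclear centres in µm, the statistic is computed in four
steps: (1) Delaunay triangulation (scipy's Qhull wrapper; exactly
zero-area simplices from collinear boundary runs are discarded, and a fully
collinear or < 3-point input is a degenerate-input error); (2) per-triangle
regularity q = 4√3·A/(l₁²+l₂²+l₃²), a standard scale-free triangle quality
index that equals 1 only for equilateral triangles; (3) the normalisation
constant is the mean area of triangles with q ≥ `regularity_threshold`
(default 0.95); (4) the score is the mean of area/constant over all
retained triangles.

Two choices in this chain were genuinely open and are fixed as follows:

- **What counts as "regular".** The premise — cobblestone sheets triangulate
  into near-equilateral triangles — names a concept without an operational
  rule. We define it through the q-index with an exposed threshold. At 0.95
  a pristine lattice's interior triangles (q = 1) qualify and even mild
  shape distortion disqualifies; lowering the threshold admits more
  triangles into the normalisation and damps the score's response.
- **Hull slivers.** Convex-hull edge triangles can be huge or degenerate in
  sparse fields. The default keeps every triangle (least interpretive);
  `max_edge` (a µm cutoff on the longest edge, ~3× the median edge is a
  reasonable value) drops them opt-in, and the number removed is logged.

If no triangle reaches the threshold the median of all areas is used
instead and the result carries a `flagged` marker plus a logged warning —
the score is then comparative only within equally-flagged fields.

Properties relied on by the tests: the score is exactly 1 on a zero-jitter
triangular lattice (every triangle, including the isoceles ones along the
staggered hull edge, has area s²√3/4); it is invariant to translation,
rotation and uniform scaling because both numerator and normalisation scale
with area; and for ≤ 8 points the triangulation is checked against a
brute-force empty-circumcircle enumeration. Cocircular degeneracies (e.g. a
perfect square) admit two valid triangulations; either is accepted, and the
score is identical for the square case.

## Synthetic sheet generator

The generator emulates the study conditions the pipeline targets, with
ground truth retained at every step:

- **Lattice** — triangular (hexagonal-packing) lattice, edge `spacing`
  (default 20 µm, a typical epithelial inter-nuclear distance), perturbed by
  isotropic Gaussian jitter (default 1 µm). Triangular rather than square
  packing makes the score-1 baseline exact.
- **Dynamics** — per frame each nucleus takes a `drift_rate` step along the
  unit vector from the *initial* cloud centroid to its current position,
  plus isotropic Gaussian diffusion (`diffusion_sd`). The fixed anchor makes
  the drift field independent of the diffusion history and gives the exact
  closed form r(k) = r(0) + k·drift for the noise-free case, used directly
  in tests. Imaging defaults are 10-min frames, 120 frames (n_frames counts
  frame 0). Real nuclear motion has no published generative model here;
  drift+diffusion is a test-harness assumption, adequate for exercising the
  metrics but not a claim about cell mechanics.
- **Rendering** — nuclei are isotropic 2-D Gaussian spots (sd `spot_sigma`
  px, default 2) evaluated at pixel centres, plus additive Gaussian camera
  noise, clipped at zero; written as 16-bit TIFF. Pixel (i, j) has centre
  (j+0.5, i+0.5); detection reports centroids under the same convention, so
  generator and detector coordinates compare directly.
- **Wound masks** — a vertical cell-free band closing linearly,
  width max(0, w₀ − k·closure).
- **Expression** — per-gene baseline log2 level ~ N(7, 1.5) (arbitrary
  units typical of normalised array intensities), plus log2(planted fold
  change) in designated conditions, plus N(0, noise_sd²) per sample in log2
  space; noiseless matrices reproduce planted fold changes exactly.

All generators are pure functions of `SimConfig`: sub-streams for lattice
jitter, motion, per-frame camera noise and expression derive from the
single seed through fixed offsets, so identical configs are bit-identical
and stages cannot perturb one another's randomness.

What the generator does **not** model: nuclear texture and shape, division
and death (tracks are total), photobleaching, drift of the field of view,
touching nuclei, 3-D structure. Passing tests therefore demonstrate
correctness of the measurement chain under separable spots and persistent
cells, not robustness to dense or dividing cultures.

## Detection, linking, pair metrics

Detection is classical particle analysis: Gaussian smoothing (sd 1 px),
Otsu or fixed threshold, 4-connected labelling, an **inclusive** area
window [min_area, max_area] px², intensity-weighted centroids. Otsu keeps
detection invariant to positive intensity rescaling. Touching-nucleus
splitting (watershed) is out of scope in v1.

Linking is greedy mutual-nearest-neighbour between consecutive frames,
gated at `max_disp` µm; unmatched points end or start tracks, and argmin
ties resolve to the lowest point index, making the assignment
deterministic. A global assignment solver would handle denser motion but is
unnecessary in the well-separated regime the assay operates in (per-frame
step below half the minimum separation, where mutual-NN recovery is exact).

Neighbouring pairs at frame 0 are mutual nearest neighbours within
`max_pair_dist`, with equidistant neighbours admitted as ties followed by
greedy disjoint matching closest-first — so symmetric configurations pair
off completely — truncated to `n_pairs` (default 15). A user-supplied pair
list can replace the automatic rule (the manual-choice workflow). The pair
distance ratio divides the distance at the frame nearest `t_eval` (default
400 min; ties snap to the earlier frame) by the frame-0 distance; pairs
missing near `t_eval` are skipped with a warning, and a zero initial
distance is an error.

## Wound gap and expression screen

Gap length is the mean over scanlines (perpendicular to the wound axis) of
the longest cell-free run, which ignores interior holes in the sheet; the
gap ratio divides two conditions' gap lengths at the frame nearest `t_eval`
(default 480 min = 8 h). Whether the original assay measured one width or
an average is unstated; the scanline mean is the documented choice here.

Fold changes are ratios of linear-scale condition means (single-sample
conditions reduce to plain ratios); classification uses strict
inequalities — up only if FC > 2, down only if FC < 0.5, FC exactly at a
threshold is unchanged — and the two-contrast Venn step partitions genes
above the stricter 4-fold cutoff into exclusive and shared sets.
Platform normalisation, probe summarisation and GO enrichment are
explicitly out of scope: the screen starts from a normalised matrix.

## Statistics

The pooled-variance (Student's) two-sample t is the default, Welch behind a
flag. ANOVA is computed from raw sums of squares; Tukey post hoc uses the
studentized-range distribution with the Tukey–Kramer standard error for
unbalanced groups (exact HSD when balanced), evaluated numerically by scipy
(documented agreement with reference implementations to 1e-6). Degenerate
inputs get explicit conventions instead of NaN: zero pooled variance with
equal means → p = 1, with unequal means → p = 0, all logged. Summaries are
mean ± sample SD (n−1); SD is flagged undefined at n = 1. Stars: * < 0.05,
** < 0.01, *** < 0.001.

The suite verifies type-I calibration empirically: under a 3-group, n = 10
null, the ANOVA rejects at α = 0.05 in 5% ± 1% of 10,000 simulations.

## Problem sizes and numerical notes

Tests and the acceptance script run on deliberately small instances —
lattices of 4×4 to 12×12 cells, 4–42 frames, 160–512 px fields, 20-seed
drift sweeps, 50-seed tracking sweeps, 10,000-replicate calibration — sizes
at which every property they assert (exactness, invariance, ordering,
calibration) is already fully expressed. Tolerances: score identities and
invariances at 1e-9 (float accumulation over ~200 triangles); oracle
agreement for t/F at 1e-8 and Tukey at 1e-6 (numerical studentized-range
CDF); detection RMSE bound 0.5 px under noiseless separable spots.

## Known limitations

Dense or overlapping nuclei violate the detection assumptions; linking has
no gap closing or division handling; the wound module requires binary masks
(phase-contrast segmentation is upstream of this package); the dispersion
score's normalisation becomes unstable when a field contains almost no
regular triangles (the flagged fallback exists for exactly that case).
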