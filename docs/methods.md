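# Methods

This note documents the models behind `mitodyn`, the parameters that
matter, the design choices made where the procedure was genuinely open, and
what the synthetic generators do and do not emulate.

## Segmentation

An `ImageStack` is a non-negative scalar field on a (z, y, x) voxel grid
with physical voxel sizes in μm. The segmentation pipeline is:

1. **Bleach correction.** Photobleaching makes later frames dimmer.
   Each frame is rescaled multiplicatively so its global mean equals frame
   1's mean. This is rank-preserving within each frame, so thresholds
   chosen on frame 1 keep their meaning throughout the series. A frame
   with zero mean cannot be rescaled and is an error.
2. **Hysteresis thresholding.** Foreground = every voxel with intensity
   ≥ `low` connected to at least one voxel ≥ `high`. Both comparisons are
   inclusive (≥). Connectivity defaults to 26-neighbour in 3D
   (8-neighbour in 2D) and is configurable; the implementation labels the
   low mask with `scipy.ndimage.label` and keeps components that touch the
   high mask, which is exactly the flood-fill definition (the test suite
   verifies this against an independent flood-fill oracle).
   Thresholds are user inputs; `auto_thresholds` provides a heuristic
   (`high` = Otsu on the frame, `low` = 0.5·high) for exploration only.
3. **Measurement.** Per-object voxel count, volume (= count × voxel
   volume), centroid in μm (voxel centers at `(i + 0.5)·h`), and the
   fragmented flag: volume **strictly below** 0.05 μm³. A volume exactly
   at the threshold is *not* fragmented. Mitochondrial content is
   `100 · Σ volumes / cell volume`; the cell volume is a supplied number,
   since cell outlines come from independent markers and are out of scope.

No deconvolution is performed; the simulator can emit low-blur data, and
real data should be deconvolved upstream if needed.

## Overlap tracking

Objects in adjacent frames are linked when their voxel masks share at
least `min_overlap` voxels (default 1). Voxel overlap was chosen over
fitted-sphere overlap because it is exact and parameter-free;
`min_overlap` can emulate sphere slack. Track ids are the connected
components of the graph on (frame, object) nodes with link edges;
unlinked objects form singleton tracks, and a split's parent and children
share one track id.

Events are read off link degrees per transition (indexed by the left
frame, 1-based): out-degree ≥ 2 at *t* → one fission; in-degree ≥ 2 at
*t + 1* → one fusion. One-to-one links are identity; unlinked objects are
deaths/births, not events. A simultaneous split-and-merge at one
transition decomposes into its in-/out-degree events; no composite event
is inferred. There is no gap closing: a disappearance is a death even if
a similar object reappears later. These conventions make the count
identity `N(t+1) − N(t) = Σ(children−1) − Σ(parents−1) + births − deaths`
an exact theorem, which the tests check by exhaustive enumeration of
small bipartite link graphs.

## Window-capped dynamics statistics

Tracking covers the first 10 time points in three windows (1–4, 4–7,
7–10); consecutive windows share exactly their boundary time point, so
the 9 transitions partition as 1–3 | 4–6 | 7–9. Per track and window at
most one event is counted. When several events fall in one window the
earliest transition wins, and at a tied transition fission is counted
before fusion — this tie-break makes "maximum counted events = number of
windows" (3 by default) an exact property of the counting rule rather
than an approximation; raw multiplicities are retained for diagnostics.

Track classes from capped counts: balanced (fissions = fusions ≥ 1),
fission-dominant, fusion-dominant, quiescent (no counted events).
Reported class percentages are over non-quiescent tracks, with the
quiescent tally stated separately — the three-class percentages then sum
to 100. The balanced class generalizes "one fission and one fusion" to
any equal nonzero counts.

The fission preference index is `(F − f)/(F + f)` ∈ [−1, 1] (undefined
and excluded when F + f = 0); a raw-difference mode exists.

The Δ-fragmented series is `Δ_k = F_{k+1} − F_k` on per-frame fragmented
counts; ΣΔ telescopes to last − first. `trend_slope` fits an OLS line to
a series (or to the point-wise average of per-cell series) against its
index. Two readings are useful and both are exposed through the same
operation: the trendline *of the Δ series* (the plotted convention for
per-transition fluctuation), and the slope *of the count series itself*,
which is the net fission tendency. The sign-recovery property in the
test suite uses the count series: under constant per-object rates, a
fusion-biased scene has a negative but shrinking Δ (the fragment pool
depletes), so the slope of Δ does not carry the net sign, while the slope
of the count series does.

Chi-squared comparisons are Pearson tests of homogeneity
(`scipy.stats.chi2_contingency`), no continuity correction for tables
larger than 2×2, Yates optional for 2×2; zero row/column margins are
rejected.

## TEM-style 2D morphometry

W and H of a profile are the length and width of its minimal-width
enclosing rectangle: H is the minimum caliper (Feret) width over convex
hull edge directions, W the extent perpendicular to the minimizing
direction. This is rotation-robust and gives an axis-aligned w×h
rectangle exactly (w, h); the maximum Feret diameter (which for a
rectangle is the diagonal) is available separately. Measurements use the
pixel *corner* points, so a 20×10 pixel rectangle at 0.1 μm/px reads
2.0 × 1.0 μm. An axis-aligned bounding-box mode exists for comparison
with simpler tools.

Classification anchors at the reference (young) sample's mean area A\*
and mean ratio R\*, which are frozen before any comparison and never
re-derived from the query sample. Shipped defaults: A\* = 0.11 μm²,
R\* = 2.34. Rules: elongated ⇔ area > A\* and ratio > R\*; medium ⇔
area > A\* and ratio ≤ R\*; fragmented ⇔ area ≤ A\* (a pure area
criterion). Boundary equalities fall to the "smaller" class,
deterministically. Orientation bias of thin sections is not modeled
beyond the generator's dispersion parameters.

## Clonal-mosaic statistics

Per germarium, `r = (prog_A/GSC_A)/(prog_B/GSC_B)`. The default
orientation puts the marker-negative (marked-clone) lineage in the
numerator so r < 1 means the marked clone divides slower; the orientation
flag swaps roles, mapping r → 1/r, and every output labels the convention
used. Germaria lacking a lineage, or whose denominator lineage shows zero
progeny, are excluded and logged with the reason — never coerced to 0 or
∞. Aggregation defaults to the mean of per-germarium ratios ± SEM
(matching per-germarium bar plots); a pooled-count mode is available.
Maintenance at week *w* is the percentage of germaria retaining ≥ 1
marker-negative GSC; clone composition splits clone-bearing germaria into
partial (mixed GSC genotypes) and full (all marker-negative), summing
to 100%.

## Synthetic generators

**Scenes.** Mitochondria are axis-aligned ellipsoids on a 9.6 μm cube
(96³ voxels at 0.1 μm isotropic) — a GSC-scale volume. Defaults: 69
initial objects (a young-GSC count at the start of recording), 10
analysed frames (the stretch over which counts stay steady before
bleaching artifacts dominate), mean semi-axes (0.35, 0.28, 0.22) μm so
typical volumes (~0.09 μm³) sit above the 0.05 μm³ cut while fission
products straddle it. Motion is an independent Gaussian step per frame
(default 0.04 μm/axis — small relative to object size, as expected at
~2 s frame intervals, keeping overlap tracking feasible) with reflecting
boundaries, so objects never leave the grid. Initial placement is a
jittered grid with spacing large relative to object extent, keeping
objects well separated.

Events are either scheduled (transition, kind, target ids) or stochastic
(per-object per-transition probabilities; stochastic fusions pair marked
objects by proximity). A fission splits the parent volume by a fraction
drawn uniformly from [0.3, 0.7] (configurable), placing the two children
side by side inside the parent's footprint with a small surface gap so
they resolve as two objects while both overlap the parent's former mask.
Scheduled fusion partners are placed as adjacent "doublets" sharing one
random walk until they fuse; the fused child is elongated along the
fusion axis to cover both parent centers. Volume is conserved exactly at
every event, and the ground truth satisfies the count-conservation
identity by construction (asserted at generation time). All randomness
derives from the config seed.

**Rendering.** Voxels inside any ellipsoid get the foreground level times
`exp(−b·(k−1))` for frame k (photobleaching), background elsewhere; then
optional Gaussian blur and Poisson shot noise, seeded from the scene seed
and frame index. This is deliberately not a PSF-accurate optical model —
no anisotropic light-sheet PSF, no deconvolution artifacts — so passing
tests demonstrate the correctness of the measurement machinery, not
robustness to real optics.

**2D populations.** (area, ratio) records with Gamma-distributed areas
and 1 + Gamma ratios, parameterized by mean and SD so the configured
means are exact and zero dispersion degenerates to the means. Defaults
reproduce the young reference sample (0.11 ± 0.11 μm², 2.34 ± 1.9,
n = 177).

**Mosaic germaria.** Default 500 germaria, 2 GSCs per lineage, weekly
loss hazard 0.025 per GSC (≈ 93% single-lineage retention over 3 weeks,
the control-level turnover), 3 observation weeks. Progeny per surviving
GSC is the configured rate (default 6 fusome-counted progeny units) plus
a small rounded Gaussian jitter (variance `progeny_dispersion`, default
1.0). The near-regular count model reflects cell-cycle-clocked GSC
divisions, and matters statistically: the mean of per-germarium ratios is
biased upward by roughly the squared coefficient of variation of the
denominator, so Poisson-dispersed counts at realistic rates would push a
genuinely symmetric mosaic to ~1.05–1.08, contradicting the mock-mosaic
expectation of ≈ 1.0. With the default jitter the null simulation gives
≈ 1.01–1.03 ± 0.01 at n = 500. Raising `progeny_dispersion` restores
over-dispersed counts for sensitivity analyses.

## Numerical and problem-size choices

- Default test scenes are 50–69 objects × 10 frames on 96³ grids; the
  full suite and the acceptance script each run in well under two minutes
  on one CPU. These sizes make every property checkable exactly
  (enumeration, flood fill, closed forms) while remaining representative
  of the per-cell object counts in the application.
- Centroid matching between detected and true objects (for scoring)
  uses nearest centers with a 1 μm gate — safe because generated objects
  are separated by several μm.
- Frames and transitions are 1-based in every user-facing table; voxel
  indices are 0-based internally.
- CSV output: comma-separated UTF-8, mandatory header, floats at 6
  significant digits; id tuples "|"-joined.

## Known limitations

- The optical model is deliberately simple (uniform foreground, isotropic
  blur, Poisson noise); performance on real lattice light-sheet data will
  depend on deconvolution quality and is not claimed.
- Ellipsoids are axis-aligned; orientation dynamics and non-ellipsoidal
  (tubular, branched) mitochondria are not simulated, so network-like
  morphologies that would challenge overlap tracking are untested.
- No gap closing or re-identification: occlusion-like dropouts fragment
  tracks.
- The three-class track typology and the capped counting rule are tied
  to the window scheme; different schemes change the class denominators.
- Clonal statistics treat germaria as independent and ignore apoptosis
  (none was the relevant loss route) and fecundity.
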