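# Methods

This note documents the models, conventions and numerical choices behind
`mitomorph`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The morphometry protocol

The morphology arm reproduces a fixed single-cell analysis protocol for
TMRM-stained fluorescence micrographs:

1. **Background subtraction** — rolling-ball-style background removal,
   implemented as grayscale opening with a disk structuring element
   (default radius 50 px). Opening with a disk produces the same
   background estimate as the classical rolling ball for flat
   backgrounds and is straightforward to verify against a brute-force
   oracle. For radii above 10 px the disk uses scikit-image's sequence
   decomposition, a fast and close approximation of the exact footprint.
2. **Median filter** — 3×3 by default (the protocol names the filter but
   not its size); mirror boundary handling.
3. **CLAHE** — contrast-limited adaptive histogram equalization, tile
   64 px, clip limit 0.01. The input is normalized by its own min–max
   before equalization: normalizing by the full bit-depth range would
   collapse dim 16-bit data into a couple of histogram bins and
   destabilize the downstream threshold. The output is rescaled to the
   bit-depth range.
4. **Otsu threshold** — between-class-variance maximization over a
   256-bin histogram with integer-aligned bin width
   `ceil((max − min + 1)/256)`, strictly-above foreground convention.
   For 8-bit images every integer intensity gets its own bin, so the
   threshold coincides exactly with an exhaustive integer search. The
   step order is part of the protocol and is not reconfigurable.

From the binary mask:

* **Components** are labeled with 8-connectivity; per-component area
  (px and µm², at the default calibration of 23.4 px/µm) and the
  moments-ellipse **aspect ratio** (major/minor; 1 for a point, ∞ for a
  zero-width line) come from scikit-image region properties. The
  **mitochondrial footprint** is the summed area of all components.
* The **skeleton** is the Zhang thinning of the mask, with a
  tip-regrowth step (below).
* The **skeleton graph** classifies skeleton pixels by 8-connected
  neighbor count: endpoints (1 neighbor), junction pixels (>2), slab
  (2). Adjacent junction pixels merge into a single junction node, so a
  fork counts one junction regardless of how many pixels the crossing
  occupies. Branches are maximal paths between nodes; their geometric
  length is 1 per orthogonal and √2 per diagonal step. A closed ring
  yields one closed branch with no nodes; a single isolated skeleton
  pixel yields a degenerate one-branch component with length one pixel
  equivalent (flagged `degenerate`).
* The **two-class filter**: a component is a *network* iff it has more
  than one branch and at least one junction, an *individual*
  mitochondrion iff it has exactly one branch, no junction and at least
  one endpoint (the degenerate single-pixel "drop" also counts as
  individual). Closed rings ("donuts") match neither rule and are
  tallied as unclassified with reason `loop` — the filter is two-class
  and strict. The partition is always exhaustive:
  n_networks + n_individuals + n_unclassified equals the component
  count.
* **Per-cell aggregation** uses medians, because within-cell length
  distributions are skewed: median network branch length, median
  individual length (an individual's length is its skeleton branch
  length, keeping one length definition across classes; shape is
  covered separately by the aspect ratio), the individual:network
  *count* ratio, and connectivity = total junctions in networks /
  number of networks. Empty object sets propagate as missing values
  (NaN), never silent zeros.

### Skeleton length conventions

Pixel-level thinning introduces two systematic biases that matter when
branch lengths are compared with a known centerline:

* **End erosion.** Zhang thinning retracts open branch ends by roughly
  one tube radius. Tips are therefore regrown along the
  distance-transform ridge of the mask: a tube's medial ridge ends
  exactly at the centerline end (independent of how wide the
  segmentation drew the tube), so each tip is extended along its local
  direction while the distance transform stays within 1 unit of the
  interior ridge value. Extensions stay inside the mask and never touch
  other skeleton pixels, so topology is unchanged.
* **Junction-cluster geometry.** Traced paths stop at the edge of a
  merged junction-pixel cluster, and thinning can displace the
  pixel-level fork along an arm. Branches conceptually meet at the
  junction *point*, which is localized as the least-squares intersection
  of the arm centerlines (lines fitted to the first path pixels of each
  attached branch, falling back to the cluster centroid when the system
  is ill-conditioned); each attached branch adds its anchor-to-point
  distance.

With these conventions, branch lengths on noise-free synthetic scenes
are recovered to within ±2 px for over 99% of branches; the residual
worst case (~2.3 px) comes from the ±0.5 px quantization of the junction
point on diagonal forks, compounded with the step-metric convention.

### Known limitation: threshold bistability on near-binary scenes

On noise-free synthetic scenes the CLAHE-equalized histogram leaves the
Otsu criterion almost flat across a range of thresholds. On a small
fraction of scenes (about 1 in 10–20) the optimum lands one notch lower
and the mask gains a one-pixel halo of the PSF ramp around every tube.
For thin tubes (radius 2 px) that ring is 25–30% of the object area, so
the per-scene footprint error is bimodal: ≲1% on most scenes, ~25–30%
on the rare ring-including scenes. This is a genuine property of the
fixed CLAHE→Otsu chain on near-binary images, not of the estimator; on
noisy (realistic) images the histogram is smooth and the threshold is
stable.

## The synthetic-scene generator

The generator emulates single-cell micrographs of TMRM-stained
mitochondria with exact ground truth, standing in for patient fibroblast
images that are not publicly available.

* **Networks** grow as self-avoiding lattice walks on the 8-connected
  pixel grid with per-step branching (default probability 0.03 per
  step, at most 4 junctions per network). Branches are straight between
  junctions and forks are perpendicular: thinning smooths sharp lattice
  corners and displaces acute forks, so this geometry keeps the
  rasterized centerline exactly recoverable — the generator's purpose
  is exact ground truth, not organic texture. Every branch keeps a
  clearance band (2·radius + 6 px) from non-adjacent parts of the tree
  so tubes never touch or blur together.
* **Individuals** are straight rods along compass directions (so the
  step-metric length of the rasterized centerline equals the drawn
  length exactly) with lengths from `branch_length_range` (default
  1–3 µm, matching the scale of reported branch lengths), plus optional
  single-pixel "drops" that rasterize to disks (aspect ratio ≈ 1).
* **Loops** ("donuts", an abnormal stress-associated form) are
  rasterized circles, recorded as class `loop` — deliberately neither
  network nor individual, mirroring the strict two-class filter.
* **Rendering**: centerlines dilated to `tube_radius` (default 2 px),
  object amplitude 400 over a background of 100 (16-bit scale),
  optional per-object brightness jitter, isotropic Gaussian PSF
  (σ = 1 px), then Poisson shot noise (scale 1.0) plus additive
  Gaussian read noise (σ = 10) — a standard fluorescence camera model.
  Defaults give an SNR of roughly 15–20, plausible for confocal TMRM
  imaging; the study the generator emulates reports no SNR, so these
  are plausibility choices, not fits.
* Placement is rejection sampling with bounded retries; failure raises
  an error naming the crowding parameters. Identical specs (including
  the seed) give bit-identical scenes.

What passing recovery tests do **not** show about real data: real
mitochondrial networks have curved branches, heterogeneous tube widths,
3-D structure projected to 2-D, organelle texture, and out-of-focus
light. The generator validates the measurement chain, not the biology.

## Kinetics

* **ROS production rate**: ordinary least-squares line over the trace
  (default window: the whole recording; frames 5 s apart), slope
  reported per minute, then expressed as percent of the pooled control
  mean (controls map to exactly 100%).
* **Membrane-potential proxy (TMRM/FCCP)**: the pre-uncoupler plateau
  minus the post-uncoupler plateau, both estimated as means of 5 frames
  (the last frames before FCCP addition and the final frames of the
  recording). A plain per-frame maximum would be biased upward by
  roughly 2.3 noise standard deviations on a 60-frame plateau
  (extreme-value statistics), so plateau means are used; near-zero and
  negative differences are flagged (`no_drop`, `negative_delta`), never
  clipped.

## Statistics

The workflow: Shapiro–Wilk normality gate per group (warn, don't block);
one-way ANOVA over cell lines or two-way line × condition (type-II);
Tukey pairwise comparisons judged against a Bonferroni-adjusted alpha of
0.05 / C(k, 2) — stacking Bonferroni on top of Tukey's own adjustment is
unusually conservative, but it is the protocol being reproduced and is
kept deliberately; the comparison-family size is an explicit input,
never inferred. Before/after-stress contrasts use an unpaired two-sided
Student's t-test at α = 0.05. ANCOVA fits
`metric ~ line + age + sex + age:sex`; when a line has a single donor,
age is confounded with the line factor — the fit still runs, but a
`CollinearityWarning` is raised and the report carries a `confounded`
flag, because a silent answer would be misleading. Fold changes are
group mean / reference mean, rounded half-up to one decimal.

Donor-level hierarchical modeling is out of scope: with one donor per
line it is unidentifiable.

## Pipeline

One config (YAML) drives synthesis/ingest → preprocessing →
morphometrics → kinetics → statistics. Stages communicate only through
CSV/JSON contracts; each stage writes a manifest with the config hash,
seed and package version, and reruns with the same config and seed are
byte-identical. Unreadable images are skipped with a logged reason; the
morphology stage fails only if every input fails; a missing control
group fails the statistics stage with a named error.

## Problem sizes

The test suite and acceptance script use: 100 random 32×32 masks for the
oracle comparisons; 20 noise-free 512×512 scenes at default conditions
for parameter recovery; 9 default-noise scenes (384×384/320×320) for
classification; 500 seeded traces for slope recovery and 200 for the
TMRM delta; 10,000 null replicates per test for type-I calibration.
These sizes make every Monte-Carlo band narrow relative to the asserted
tolerances while keeping a full run in the low minutes on one CPU.
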