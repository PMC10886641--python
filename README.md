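# mitomorph

Quantitative mitochondrial-network morphometry, ROS kinetics and
membrane-potential quantification for single-cell fluorescence
micrographs — with a synthetic-scene generator that provides exact
ground truth for every stage.

## What it does and for whom

Mitochondria form a dynamic network (MN) whose balance of fusion and
fission shifts in disease and under oxidative stress. Cell biologists
quantify this from potential-sensitive-dye (TMRM) micrographs of single
cells: the image is segmented, skeletonized, and decomposed into a
skeleton graph whose components are filtered into *networks* (more than
one branch and at least one junction) and *individual* mitochondria
(exactly one branch, no junction). `mitomorph` implements that protocol
end to end, plus the kinetic and statistical layers that usually
accompany it:

* **Morphometry** — fixed preprocessing chain (rolling-ball background
  subtraction, median filter, CLAHE, Otsu threshold), 8-connected
  component analysis, topological skeletonization and skeleton-graph
  decomposition, the two-class network/individual filter, and the
  per-cell parameters: mitochondrial footprint (µm²), median network
  branch length, individual:network ratio, median individual length,
  connectivity (mean junctions per network) and the aspect ratio of
  individual mitochondria. Calibration defaults to 23.4 px/µm.
* **Kinetics** — ROS production rate as the OLS slope of a fluorescence
  time series (percent of pooled control = 100%), and the ΔΨm proxy
  from TMRM/FCCP recordings (pre-uncoupler plateau minus post-FCCP
  plateau).
* **Statistics** — Shapiro–Wilk normality gate, one-/two-way ANOVA with
  Tukey comparisons against a Bonferroni-adjusted alpha
  (α = 0.05 / C(k,2); 0.005 for five groups), unpaired t-tests for
  before/after-stress contrasts, ANCOVA with donor age and sex as
  covariates (with explicit confounding warnings), and half-up-rounded
  fold changes.
* **Synthesis** — seeded scenes of branched tubular networks, rods,
  spherical "drops" and donut loops with exact centerline ground truth,
  and linear-drift / plateau-then-drop traces, so every stage can be
  validated against known truth.

The core steps are scikit-learn-style estimators
(`MicrographBinarizer`, `MitoNetworkAnalyzer`, `RateFitter`) with thin
functional wrappers, composed by a batch pipeline and a CLI.

## Worked example

```python
from mitomorph import (SceneSpec, generate_scene, preprocess_micrograph,
                       MitoNetworkAnalyzer)
from mitomorph.stats import fold_change, bonferroni_alpha

spec = SceneSpec(image_size=(384, 384), n_networks=2, n_individuals=6, seed=7)
img, truth_mask, truth = generate_scene(spec)       # synthetic TMRM image
mask = preprocess_micrograph(img)                   # fixed 4-step chain
m = MitoNetworkAnalyzer().analyze(mask, cell_id="demo").morphometrics
for k, v in m.as_dict().items():
    print(f"{k}: {v}")
```

prints

```
cell_id: demo
footprint_um2: 5.39666885820732
median_network_branch_len_um: 2.141359336089673
individual_to_network_ratio: 3.0
median_individual_len_um: 1.5674217747719528
mean_junctions_per_network: 1.0
median_individual_aspect_ratio: 7.757218187884915
n_networks: 2
n_individuals: 6
n_unclassified: 0
```

— the two generated networks and six rods are recovered and classified
exactly; the rods' elongated shape shows in the aspect ratio, and the
count ratio 6/2 = 3.0. The statistics layer reproduces published-style
arithmetic, e.g. group means 6.1 and 7.6 versus a control of 2.9 give
fold changes of 2.1 and 2.6, and the per-comparison alpha for all pairs
of five groups is 0.005:

```python
print(fold_change({"Control": 2.9, "PINK1": 6.1, "PinkParkin": 7.6}, "Control"))
print(bonferroni_alpha(5))   # 0.005
```

## Command line

```bash
mitomorph synth          -o scenes --seed 1      # scenes + ground truth
mitomorph run-all        -c config.yml           # full pipeline
mitomorph analyze-images -c config.yml           # morphology arm only
mitomorph analyze-traces -c config.yml           # kinetics arm only
mitomorph stats          -c config.yml           # statistics layer
```

One YAML config drives everything (see `mitomorph.pipeline` for the
schema); every output directory carries a manifest with the config hash
and seed, and reruns are byte-identical.

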