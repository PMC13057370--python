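# Methods note

This note records the modelling choices behind `temflow`: what each stage
assumes, why the defaults are what they are, and where the package knowingly
simplifies. Units are given with every parameter; all defaults are package
choices and can be overridden through the public APIs.

## Imaging model and preprocessing

A *field* is a set of co-registered 2-D 16-bit channels at a fixed pixel
pitch (default 0.65 µm/px, a typical 200× confocal configuration). The green
channel carries the cytoplasmic T-cell label, the red channel the endothelial
monolayer; all segmentation runs on green only, red is carried for context.

- **Background subtraction** — grayscale top-hat: the background estimate is
  a morphological opening with a disc of radius 50 px (≈ 32 µm), i.e. larger
  than any single cell, so illumination trends vanish while compact bright
  objects pass unchanged. This is the same family of operation as ImageJ's
  rolling-ball subtraction; a true paraboloid ball is not implemented because
  the disc opening is equivalent at these scales and much simpler to reason
  about. The disc uses a sequence decomposition so the radius-50 opening
  stays fast.
- **8-bit conversion** — linear map of the [P0, P99.9] intensity window onto
  [0, 255] with half-up rounding. Leaving the top 0.1 % of pixels saturated
  mirrors acquisition practice and anchors the dynamic range; rounding is
  explicitly half-up so the mapping is bit-stable across platforms.

## Segmentation

1. **Threshold** — Li's minimum-cross-entropy method by default. Otsu is
   available but assumes a roughly balanced bimodal histogram; fluorescence
   fields are sparse (a few percent foreground), where Otsu can ride up into
   the signal and drop dim cells. Li sits reliably between the noise floor
   and the dimmest cells on both synthetic and conventional fluorescence
   content. A *contrast guard* requires the chosen threshold to exceed the
   background median by 3 robust standard deviations (MAD × 1.4826);
   otherwise the field is declared empty instead of letting an automatic
   method bisect pure noise.
2. **Refinement** — fill holes, grayscale opening with a radius-1 disc
   (removes 1-px protrusions and bridges), remove regions under 20 px
   (≈ 8.5 µm² at the default pitch — well under any T cell, but above debris
   specks). The operation is idempotent.
3. **Watershed split** — Euclidean distance transform, Gaussian-smoothed at
   σ = 1 px; seeds are h-maxima with a minimum depth of 2.5 px, merged when
   closer than 7 px; flooding uses watershed lines, and the ridge pixels go
   to background before 4-connected relabelling. The depth and merge radius
   are calibrated so that genuinely overlapping cell pairs split along the
   perpendicular bisector while single elongated (peanut-shaped) cells do
   not fragment.
4. **Region filter** — keep regions with Area ≥ 20 px and Circ ≥ 0.10. The
   circularity bound removes fibrous debris and segmentation slivers; real
   cells, even strongly elongated transmigrated ones, stay well above it.

## Morphometry

The feature set and naming follow ImageJ's *Analyze Particles* so tables are
interchangeable with ImageJ workflows: Area, StdDev, X, Y, Perim, Circ,
Solidity, Major, Minor, AR, Round, Feret, MinFeret, IntDen, RawIntDen.
Numerical choices:

- **Perimeter** — marching-squares contour at the 0.5 level, smoothed with a
  closed moving average of window 5. Raw marching squares overestimates
  curved boundaries (disc Circ ≈ 0.89) and Crofton underestimates corners
  (square Circ ≈ 0.88 instead of π/4 with the 4-direction variant); the
  smoothed contour gives disc Circ ≈ 0.996 and square Circ ≈ 0.79 ≈ π/4
  simultaneously. Circularity 4πA/P² is capped at 1.
- **Ellipse axes** — full axes of the moment-equivalent ellipse, 4√λ of the
  second-moment matrix with the +1/12 px² pixel-integration correction per
  coordinate, matching ImageJ's fitted ellipse.
- **Feret diameters** — rotating calipers on the convex hull of the pixel
  *corners* (each pixel contributes its four corners), so a 1-px-wide line
  has MinFeret 1, not 0.
- Regions touching the image border are flagged (`border`), never silently
  dropped; the caller decides.

## Classifier

A multilayer perceptron: input (15 features, standardized with statistics
fitted on the training rows only) → dense 64 → 32 → 16 (ReLU) → 1 sigmoid
unit for the binary attached/in-process vs transmigrated task (3 softmax
units for the legacy 3-class task). Adam at learning rate 10⁻³, batch 32, up
to 200 epochs with early stopping (patience 10) on an internal 10 %
validation fold; on training sets too small to stratify that fold, early
stopping is disabled and the full epoch budget runs. The decision rule is
P(transmigrated) ≥ 0.5.

Training is delegated to scikit-learn's `MLPClassifier`; prediction runs
through the package's own forward pass on the stored weight tensors, so a
model reloaded from its JSON file replays predictions bit-exactly and the
persistence format is plain text.

- **Relevance** — the product of the weight matrices through the network
  gives each input's net signed pull on the output unit (connection-weight
  product, Olden method). Positive relevance pushes toward "transmigrated".
  Permutation importance over a labelled table is reported alongside as an
  independent magnitude check. For multiclass models the sign is undefined
  and only magnitudes are reported, flagged as such.
- **Between-group analysis (BGA)** — features are z-scored, the principal
  axes of the size-weighted group centroids define the ordination, and the
  between-group variance fraction of the scores summarizes separability
  (≈ p/n at chance for p features and n samples; → 1 for well-separated
  groups). At most g − 1 axes are kept for g groups, since the centroid
  matrix has no more rank than that.

## Synthetic data

The scene generator exists to make the pipeline testable at desk scale with
exact ground truth; it emulates the *statistics the pipeline is sensitive
to*, not cell biology:

- cells are radial-Fourier-perturbed ellipse polygons; "attached" cells are
  compact (elongation 1.0–1.3, brighter), "transmigrated" cells elongated
  and irregular (elongation 1.8–3.5, boundary irregularity 0.22, dimmer) —
  the qualitative morphology contrast of the assay;
- Poisson shot noise (gain 4) plus Gaussian read noise on a flat background
  (level 1200 ± 250 counts); quantile-scaled saturation (defaults 2.5 %
  green, 0.5 % red) reproduces clipped-pixel tails; 1–4 px debris specks
  fall under the area filter by construction; a configurable fraction of
  cells (default 10 %) is placed touching a neighbour to exercise the
  watershed; the red channel is a smooth blotch texture, not a monolayer
  model.
- It does **not** emulate optics (no PSF convolution), uneven illumination,
  focus drift, photobleaching, or endothelial junction structure.

The feature-table sampler draws per-class Gaussians over the 15 features
around empirically plausible baselines. The default class shift (elongation
features up, roundness features down for "transmigrated", with a Mahalanobis
separation of ≈ 3.9) is *moderate by design*: a default MLP reaches ~95 %
held-out accuracy, comfortably clear of chance but away from the trivial
100 % regime, so classifier tests remain discriminating. Features are
sampled independently per class; real morphometric features are correlated
(Area–Perim, AR–Round), which this sampler ignores — acceptable because it
feeds classifier mechanics, not biology claims.

## Spatial statistics

Voronoi cells are made bounded *exactly* by mirroring all sites across the
four field edges before triangulating: each original site's region is then
finite and its clip to the field is the true bounded Voronoi cell, so clipped
areas tile the field to floating-point precision. Inverse cell area is the
local density; a site is "dense" above 2× the median density, and clusters
are connected components (shared Voronoi edges) of at least 3 dense sites.
Density at the rim of a clump is diluted by the empty space beyond it, so
detected clusters are cores — a property of Voronoi density estimates, not a
bug.

## Pipeline

`run_pipeline` resolves a `RunConfig` (JSON-serializable, unknown keys
rejected), processes every field in isolation (one failing field does not
stop the rest; failures are recorded in the manifest and raised at the end),
and writes per-field feature and spatial tables, an aggregate per-field
category-count report, and a manifest containing the package version and the
full resolved configuration. Outputs contain no timestamps; identical config
and seed reproduce byte-identical data files. Group-level inferential
statistics are deliberately out of scope — the aggregate table is the input
to external statistics tooling.

## Limitations

- Validated on synthetic scenes; real acquisitions with dense monolayers,
  out-of-focus cells or strong vignetting will need threshold/radius tuning.
- The binary classifier learns the morphology contrast present in its
  training table; models trained on the synthetic sampler should be
  retrained on measured features before use on real data.
- Per-cell z-position is not modelled: the attached-vs-transmigrated call is
  purely morphological, as in the source assay, and inherits its ambiguity
  for cells mid-transmigration.
- The watershed seed depth (2.5 px) trades split sensitivity against
  fragmentation of elongated cells; heavily overlapping clusters (> 2 cells)
  may still merge.
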