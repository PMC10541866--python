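# Methods

This note documents the models, conventions and numerical choices behind
`texturenet`, and what the synthetic phantoms do and do not establish.

## Texture model

The co-occurrence matrix of an ROI is computed isotropically in 3D: for a
distance *d*, the neighbourhood of a reference voxel is the hollow cubic
shell of Chebyshev radius *d* (24d² + 2 offsets). The shell — rather than
the filled cube — is used so that the five distances 1–5 probe disjoint
spatial scales instead of nested ones. Ordered gray-level pairs are
accumulated over the full, negation-closed shell, which makes the matrix
symmetric by construction without a separate symmetrization pass. Voxels
outside the image grid or outside the ROI are simply skipped: no padding, no
wrapping, so border voxels contribute fewer pairs.

**Quantization** is uniform over the in-ROI min–max range (per-ROI scope;
a per-volume scope can be emulated by passing a whole-volume mask to
`quantize`). Per-ROI binning maximizes within-ROI contrast information and
makes features invariant to region-wise affine intensity changes — which is
also why the phantom generator manipulates texture through noise amplitude
and spatial autocorrelation rather than mean intensity: a pure mean shift is
removed by the quantizer and would be an empty test. The in-mask maximum
maps to the top level G−1; a constant ROI maps to level 0 everywhere and
yields the degenerate single-cell GLCM p(0,0) = 1.

Default G = 32 gray levels balances gray-level information against matrix
sparsity: larger G inflates the zero fraction of the G×G matrix, and the
per-(region, distance) sparsity report written by the extraction stage is
the diagnostic to check when changing it.

### Feature conventions

* All entropies use log base 2 with 0·log 0 = 0. The base only scales the
  entropy features and is removed by the downstream min–max normalization.
* *Variance* (sum of squares) is centered on the grand gray-level mean
  μ = (μ_x + μ_y)/2 and averages the row and column second moments, so it is
  transpose-invariant for any input; for the symmetric matrices the pipeline
  produces, this coincides with the plain definition.
* *Sum variance* is centered on the sum average (the modern convention).
  The historical definition centered it on the sum entropy — widely regarded
  as a typographical accident — and remains available via
  `features(m, sum_variance_legacy=True)`.
* *Correlation* is defined as 0 when σ_x σ_y = 0 (constant ROI), keeping
  feature vectors finite.
* The difference distribution is over |i−j| (G bins).
* Feature normalization is per column **within one subject**, so each
  subject's network is self-contained and cross-subject intensity scaling is
  irrelevant; a cohort-wide scope (pooling all subjects' regions before
  scaling) is available via `feature_norm_scope: cohort`.

## Network model

Raw similarity is s = 1/(1 + d) with d the Euclidean distance between
55-vectors. The bounded form keeps identical-texture pairs finite; the
subsequent off-diagonal min–max normalization maps onto [0, 1] exactly as a
literal inverse distance would (the two are monotonically related), and the
literal 1/max(d, ε) variant is available via `similarity_variant: inverse`.
If every pairwise similarity is equal the network is degenerate and all
weights are set to 0 with a warning. Graphs stay fully weighted — no
thresholding or binarization.

Weighted measure conventions (stated in every run log):

* **ST** — row sum of the weight matrix.
* **BC** — Brandes' algorithm with edge length ℓ = 1/w (absent edges where
  w = 0), fractional counting over equal-length shortest paths,
  unnormalized counts.
* **EC** — non-negative leading eigenvector of w, scaled so the maximum
  entry is 1 for cross-subject comparability; computed by power iteration on
  w + I (tolerance 1e−10), a spectral shift that guarantees convergence on
  bipartite-like spectra without changing eigenvectors.
* **CC** — Onnela's geometric-mean form on ŵ = w / max(w); 0 for degree < 2.
* **LE** — global efficiency (mean inverse shortest-path length, ℓ = 1/ŵ) of
  the subgraph induced by the node's neighbours; 0 for degree < 2. Weights
  are max-normalized first, mirroring the CC convention, so that EC, CC and
  LE are all invariant to a global rescaling of the weights while ST scales
  linearly. For pipeline matrices this normalization is a no-op (their
  maximum is already 1 by construction).

With min–max-normalized weights all five measures land in convenient
ranges: EC, CC, LE ∈ [0, 1], ST ∈ [0, R−1], BC ≥ 0.

## Region selection

A region is analyzed iff it has **more than** 900 voxels, or belongs to a
homologous pair of which at least one member has **more than** 1000 voxels —
in which case *both* members are kept, even a small one (the pair rule
exists precisely to rescue the smaller homolog). Boundary counts of exactly
900/1000 fail; the thresholds refer to the voxel counts of the parcellation
actually supplied. Selection is idempotent, and regions listed in the table
but absent from the volume get count 0, a logged warning, and are dropped.

## Cohort studies

* **Edge comparison.** The grand mean is over *all* off-diagonal edges of
  the whole network (per-edge means over subjects; the per-edge mean of
  means equals the pooled mean). The baseline SD defaults to the SD over
  per-edge means; the pooled subject×edge SD is also computed and reported,
  since the two differ and either could be a sensible yardstick.
  "Greater than mean" is strict; "1 SD greater" means mean + 1·SD, strict.
* **ANCOVA.** Ordinary least squares per (region, measure);
  `metric ~ sex + age + brain_volume + intracranial_volume` for the sex
  study and `metric ~ age + sex + brain_volume + intracranial_volume` for
  the age study. Significance of the term of interest is the partial
  (Type III) F-test — identical to the squared t-test for a single-df term.
  Bonferroni multiplies by the number of regions, applied within each
  measure family (5 families); a global 5×R family can be obtained by
  multiplying the reported raw p-values accordingly. The reported R² is the
  full-model R²; the per-term coefficient is also reported so a partial R²
  can be derived. A `zero_fraction` diagnostic per (region, measure) lets
  users discount fits dominated by zeros — betweenness in weak-hub regions
  is the typical offender, since its distribution is mostly exact zeros and
  a linear model on it is not meaningful. A constant outcome (e.g. BC
  identically zero) yields p = 1, R² = 0 rather than an error.
* **Region deviation.** Per measure, (region mean − global mean)/global SD
  with the global moments pooled over all subject×region values (SD over
  region means available via `sd_mode`), flagged when |deviation| > 1.5.
  Deviations are shift-invariant and average to zero across regions.

## Synthetic phantoms

`PhantomSpec` lays regions out as an exact grid of cuboids — chosen for
precise voxel-count control, which exercises the 900/1000 selection rule at
its boundaries. Each region is filled with
`base + sd · smooth(noise, σ)` where the Gaussian noise field is re-scaled
to unit variance after smoothing, so `sd` is the actual intensity SD and the
smoothing length σ controls spatial autocorrelation (texture coarseness)
independently of amplitude. Sex and age effects are injected
multiplicatively into the noise amplitude
(`sd · (1 + offset·male) · (1 + slope·(age − 40))`), which moves
contrast/variance-type features and thus propagates through the similarity
network to the graph measures.

Cohort covariates: sex ~ Bernoulli(0.5); ages piecewise-uniform over the
bins 18–30/31–45/46–60/61–75/76–90 with weights 281/209/194/63/13
(a young-skewed healthy-volunteer profile); intracranial volume
N(1450, 100²) cm³ + 130 cm³ male offset; brain volume 0.85·ICV plus
independent noise and a mild age decline. Everything derives from a single
seed; cohorts are bitwise reproducible.

For statistical calibration of the ANCOVA studies (null rejection rates,
power, slope recovery), node-metric tables are simulated directly with
`simulate_metric_cohort` — thousands of region-measure tests at image
resolution would add nothing to what the metric-level null establishes,
since the ANCOVA layer only sees the metric tables. Image-level phantoms are
used where the texture chain itself is under test (planted-module recovery,
contrast ordering, determinism).

**What passing phantoms do not show:** phantoms have piecewise-stationary
Gaussian textures, sharp cuboid region boundaries, no anatomy, no partial
volume, no bias field, no interpolation artifacts from spatial
normalization. Results on them validate the *computations*, not the
biological claims; effect sizes recovered from phantoms say nothing about
effect sizes in real cohorts.

## Numerical choices and degenerate inputs

* GLCM counts are accumulated as integers and normalized once, so symmetry
  is exact and Σp = 1 to 1e−9 is a hard invariant.
* An ROI with no valid voxel pairs yields an all-zero GLCM flagged
  degenerate; feature extraction on it raises rather than emitting NaNs.
* Tie-breaks in shortest paths are irrelevant to BC (fractional counting)
  and to LE/efficiency (only path lengths enter).
* Stage caching keys on a SHA-256 of input bytes + configuration; any
  change to either invalidates the stage.
* Default problem sizes in the validation suite (8-region phantoms of
  1000-voxel regions, cohorts of 5–50 subjects for image-level checks,
  150–300 subjects for metric-level statistics) were chosen as the smallest
  sizes at which the respective statistical checks have comfortable margins.

## Known limitations

* Only two-level sex factors are supported in the factor ANCOVA.
* The age model is linear; age–metric relationships that saturate or bend
  will show depressed R² (a nonlinear fit is out of scope).
* No thresholded/binary network analysis and no global graph measures
  (small-worldness, modularity).
* Intensity and label volumes must share a grid exactly; no resampling is
  performed.
* Betweenness on dense similarity networks is frequently zero for most
  nodes; treat BC-based inferences with the `zero_fraction` diagnostic.
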