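# texturenet

Texture-based structural brain networks from parcellated 3D images.

Most brain-network studies derive edges from functional dynamics (fMRI, EEG)
or fibre tracts (DTI). `texturenet` instead builds a network for each subject
from the *texture* of a structural image: every parcel of a co-registered
parcellation becomes a node, and two nodes are linked strongly when their
gray-level co-occurrence statistics are similar. The package provides the
complete chain — texture feature extraction, network construction, weighted
graph measures, and cohort statistics — plus a synthetic phantom generator so
the whole pipeline can be validated without any MRI data. It is intended for
neuroimaging researchers exploring structural covariance networks based on
image texture rather than cortical thickness or gray-matter volume.

## Method

For each region of interest (ROI) **r** in a labeled volume:

1. **Quantization.** In-ROI intensities are binned to *G* = 32 gray levels
   over the ROI's min–max range.
2. **Isotropic 3D GLCM.** For each distance *d* = 1…5 voxels, the gray-level
   co-occurrence matrix P_d(i, j) counts ordered pairs of levels at offsets
   on the cubic (Chebyshev) shell of radius *d* — all 24d² + 2 directions
   pooled, so no direction is privileged. Only voxel pairs fully inside the
   ROI (and the grid) count; the matrix is symmetric and normalized to sum 1.
3. **Texture features.** From each GLCM, 11 Haralick statistics: uniformity
   Σp², contrast Σ(i−j)²p, correlation, variance, homogeneity Σp/(1+(i−j)²),
   entropy −Σp log₂ p, sum average, sum variance, sum entropy, difference
   variance, difference entropy. Five distances × 11 features give a
   55-component vector per region, min–max normalized per feature across the
   subject's regions.
4. **Network.** Edge weight w(r, s) from the Euclidean distance d(r, s)
   between feature vectors via s = 1/(1 + d), min–max normalized to [0, 1]:
   similar textures ⇒ strong links.
5. **Graph measures.** Per node: strength (ST), betweenness centrality (BC,
   edge lengths 1/w), eigenvector centrality (EC, scaled to max 1), Onnela
   weighted clustering coefficient (CC), and weighted local efficiency (LE).

Regions enter the analysis only if they have > 900 voxels, or belong to a
homologous left/right pair of which one member has > 1000 voxels (both
members are then kept).

Cohort studies on the per-subject networks:

* **edge comparison** — are the internal edges of a candidate sub-network
  (e.g. a functional network's regions) stronger than the grand mean edge?
* **sex ANCOVA** — metric ~ sex, adjusted for age, brain volume and
  intracranial volume; Bonferroni over regions.
* **age ANCOVA** — metric ~ age, adjusted for sex and the volumes; reports
  the model R² and slope sign.
* **region deviation** — each region's metric versus the global mean, in
  global-SD units, flagged beyond 1.5.

## Worked example

Eight 1000-voxel cuboid regions in two texture modules — regions 1–4 share a
smooth (long-autocorrelation) texture, regions 5–8 a rough one:

```python
import numpy as np
from texturenet import (PhantomSpec, simulate_cohort, similarity_matrix,
                        normalize_features, node_metrics)
from texturenet.pipeline import extract_features

spec = PhantomSpec(layout=(2, 2, 2), region_shape=(10, 10, 10),
                   smoothing={1: 2.5, 2: 2.5, 3: 2.5, 4: 2.5,
                              5: 0.0, 6: 0.0, 7: 0.0, 8: 0.0},
                   homolog_pairs=[(1, 2), (3, 4)], seed=42)
cohort = simulate_cohort(spec, 6)
fm, _ = extract_features(cohort.volumes[0], cohort.labels, cohort.region_table)
print(np.round(fm.values["d1_contrast"].to_numpy(), 2).tolist())
conn = similarity_matrix(normalize_features(fm))
print(node_metrics(conn).table.round(3).to_string(index=False))
```

prints

```
[6.34, 4.45, 7.19, 5.33, 35.93, 34.35, 52.34, 44.89]
 label_id    ST  BC    EC    CC    LE
        1 1.059 6.0 0.326 0.139 0.228
        2 1.221 0.0 0.414 0.150 0.223
        3 0.491 0.0 0.132 0.089 0.216
        4 1.244 0.0 0.400 0.150 0.223
        5 2.095 2.0 1.000 0.180 0.180
        6 1.983 0.0 0.970 0.229 0.216
        7 1.357 0.0 0.624 0.156 0.215
        8 1.869 6.0 0.834 0.185 0.190
```

The short-range contrast separates the two modules by a factor of ~7 (rough
regions 5–8 have d=1 contrast ≈ 35–52 versus ≈ 4–7 for the smoothed ones),
and the rough-texture module carries the highest strength and eigenvector
centrality because its members link tightly to one another (e.g. the
connectivity entry for regions 5–6 is 1.0, the network maximum).

## Command line

```bash
texturenet phantom  --config run.yaml --n-subjects 20   # synthetic cohort
texturenet run      --config run.yaml                   # extract→network→metrics→studies
```

Stage outputs are TSV (features, connectivity, metrics, study tables) plus a
`run_log.txt` recording every configuration value in force; stages are
cached by a content hash of inputs + config.

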