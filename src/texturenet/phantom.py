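"""Synthetic parcellated phantoms and cohorts.

The phantom emulates the inputs of the texture-network pipeline without any
MRI data: a cuboid parcellation (exact voxel-count control for the region
size rule), per-region Gaussian noise textures whose spatial autocorrelation
(smoothing length) and amplitude differ between region "modules", and a
cohort design with sex, age and head-size covariates.

Texture is manipulated through noise amplitude and smoothing length rather
than mean intensity, because per-ROI quantization removes pure mean shifts;
sex and age effects are injected multiplicatively into the noise amplitude,
so they show up in contrast/variance-type features and propagate to the
similarity network.

Ages are drawn from a piecewise-uniform distribution skewed toward young
adults (bins 18–30, 31–45, 46–60, 61–75, 76–90 with weights
281/209/194/63/13), emulating a typical healthy-volunteer cohort.

`simulate_metric_cohort` generates node-metric tables directly (bypassing
images) for statistical calibration of the ANCOVA studies, where thousands
of region-measure tests are needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .network import METRIC_NAMES, NodeMetricTable
from .studies import CohortDesign
from .volumes import IntensityVolume, LabelVolume, RegionTable

AGE_BINS = [(18, 30), (31, 45), (46, 60), (61, 75), (76, 90)]
AGE_WEIGHTS = np.array([281, 209, 194, 63, 13], dtype=float)
AGE_REFERENCE = 40.0


@dataclass
class PhantomSpec:
    """Layout and texture parameters of a synthetic cohort.

    ``layout`` arranges regions on a grid of cuboids: e.g. (2, 2, 2) cuboids
    of ``region_shape`` (10, 10, 10) gives 8 regions of 1000 voxels.
    Per-region parameters are cycled from the module definitions: regions in
    the same module share (base, noise_sd, smoothing).
    """

    layout: tuple[int, int, int] = (2, 2, 2)
    region_shape: tuple[int, int, int] = (10, 10, 10)
    base: dict[int, float] = field(default_factory=dict)  # label -> mean intensity
    noise_sd: dict[int, float] = field(default_factory=dict)  # label -> amplitude
    smoothing: dict[int, float] = field(default_factory=dict)  # label -> sigma, voxels
    modules: dict[int, str] = field(default_factory=dict)  # label -> module name
    sex_noise_offset: dict[int, float] = field(default_factory=dict)  # label -> frac
    age_noise_slope: dict[int, float] = field(default_factory=dict)  # label -> frac/yr
    homolog_pairs: list[tuple[int, int]] = field(default_factory=list)
    default_base: float = 100.0
    default_noise_sd: float = 10.0
    default_smoothing: float = 0.0
    seed: int = 0

    @property
    def n_regions(self) -> int:
        return int(np.prod(self.layout))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(l * r for l, r in zip(self.layout, self.region_shape))

    def region_params(self, label: int, sex_male: int, age: float) -> tuple[float, float, float]:
        """(base, effective noise SD, smoothing sigma) for one subject/region."""
        base = self.base.get(label, self.default_base)
        sd = self.noise_sd.get(label, self.default_noise_sd)
        sigma = self.smoothing.get(label, self.default_smoothing)
        sd *= 1.0 + self.sex_noise_offset.get(label, 0.0) * sex_male
        sd *= 1.0 + self.age_noise_slope.get(label, 0.0) * (age - AGE_REFERENCE)
        return base, max(sd, 0.0), sigma


def make_label_volume(spec: PhantomSpec) -> tuple[LabelVolume, RegionTable]:
    """Cuboid parcellation with labels 1..R on the spec's grid."""
    shape = spec.grid_shape
    data = np.zeros(shape, dtype=np.int32)
    rx, ry, rz = spec.region_shape
    label = 0
    for ix, iy, iz in itertools.product(*(range(n) for n in spec.layout)):
        label += 1
        data[ix * rx : (ix + 1) * rx, iy * ry : (iy + 1) * ry, iz * rz : (iz + 1) * rz] = label
    labels = LabelVolume(data=data)

    homolog = {}
    for a, b in spec.homolog_pairs:
        homolog[a] = b
        homolog[b] = a
    rows = [
        {
            "label_id": lab,
            "name": f"region_{lab:02d}",
            "homolog_id": homolog.get(lab, np.nan),
            "voxel_count": 0,
        }
        for lab in range(1, spec.n_regions + 1)
    ]
    table = RegionTable(pd.DataFrame(rows)).with_counts(labels)
    return labels, table


def _textured_field(
    shape: tuple[int, int, int], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise field with autocorrelation length sigma."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=sigma, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise


def simulate_subject(
    spec: PhantomSpec,
    labels: LabelVolume,
    sex_male: int,
    age: float,
    rng: np.random.Generator,
) -> IntensityVolume:
    """One subject's intensity volume: per-region textured noise around a base."""
    data = np.zeros(spec.grid_shape, dtype=np.float64)
    for lab in range(1, spec.n_regions + 1):
        mask = labels.data == lab
        base, sd, sigma = spec.region_params(lab, sex_male, age)
        field_ = _textured_field(spec.grid_shape, sigma, rng)
        data[mask] = base + sd * field_[mask]
    return IntensityVolume(data=data)


def _draw_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    probs = AGE_WEIGHTS / AGE_WEIGHTS.sum()
    bins = rng.choice(len(AGE_BINS), size=n, p=probs)
    lo = np.array([b[0] for b in AGE_BINS], dtype=float)
    hi = np.array([b[1] for b in AGE_BINS], dtype=float)
    return lo[bins] + rng.random(n) * (hi[bins] - lo[bins])


def draw_design(rng: np.random.Generator, n: int) -> CohortDesign:
    """Cohort design: sex ~ Bernoulli(0.5), skewed ages, sex-correlated volumes.

    Volumes are in cm³: intracranial volume ~ N(1450, 100²) plus a +130 male
    offset; brain volume tracks ICV with independent noise.
    """
    sex_male = rng.integers(0, 2, size=n)
    age = _draw_ages(rng, n)
    icv = rng.normal(1450.0, 100.0, size=n) + 130.0 * sex_male
    bv = 0.85 * icv + rng.normal(0.0, 30.0, size=n) - 1.2 * (age - AGE_REFERENCE)
    df = pd.DataFrame(
        {
            "subject": [f"sub-{i:04d}" for i in range(n)],
            "sex": np.where(sex_male == 1, "M", "F"),
            "age": age,
            "brain_volume": bv,
            "intracranial_volume": icv,
        }
    )
    return CohortDesign(df)


@dataclass
class PhantomCohort:
    """Subjects sharing one label volume, with their design table."""

    labels: LabelVolume
    region_table: RegionTable
    volumes: list[IntensityVolume]
    design: CohortDesign
    spec: PhantomSpec


def simulate_cohort(spec: PhantomSpec, n: int) -> PhantomCohort:
    """n subjects with the spec's parcellation, textures, and injected effects."""
    if n < 2:
        raise ValueError("cohort needs at least 2 subjects")
    rng = np.random.default_rng(spec.seed)
    labels, table = make_label_volume(spec)
    design = draw_design(rng, n)
    volumes = []
    for row in design.table.itertuples():
        male = 1 if row.sex == "M" else 0
        volumes.append(simulate_subject(spec, labels, male, float(row.age), rng))
    return PhantomCohort(
        labels=labels, region_table=table, volumes=volumes, design=design, spec=spec
    )


def simulate_metric_cohort(
    n_subjects: int,
    n_regions: int,
    seed: int,
    noise_sd: float = 1.0,
    age_slope: dict[tuple[int, str], float] | None = None,
    sex_effect_sd: dict[tuple[int, str], float] | None = None,
    covariate_effects: bool = True,
) -> tuple[list[NodeMetricTable], CohortDesign]:
    """Node-metric tables generated directly, for ANCOVA calibration.

    Each (region, measure) metric is baseline + optional covariate
    contributions + Gaussian noise. ``age_slope`` maps (label, measure) to a
    slope in metric units per year; ``sex_effect_sd`` maps (label, measure)
    to a male-minus-female offset expressed in units of that region-measure's
    pooled SD under the null (so 1.0 injects a one-pooled-SD group shift).
    """
    rng = np.random.default_rng(seed)
    design = draw_design(rng, n_subjects)
    age = design.table["age"].to_numpy()
    male = (design.table["sex"] == "M").to_numpy(dtype=float)
    bv = design.table["brain_volume"].to_numpy()
    icv = design.table["intracranial_volume"].to_numpy()
    age_slope = age_slope or {}
    sex_effect_sd = sex_effect_sd or {}

    values = {}  # (label, measure) -> per-subject values
    for lab in range(1, n_regions + 1):
        for meas in METRIC_NAMES:
            y = 1.0 + rng.normal(0.0, noise_sd, size=n_subjects)
            if covariate_effects:
                # mild head-size and age dependence common to both sexes
                y = y + 0.002 * (bv - 1230.0) + 0.001 * (icv - 1510.0)
            slope = age_slope.get((lab, meas), 0.0)
            y = y + slope * age
            eff = sex_effect_sd.get((lab, meas), 0.0)
            if eff != 0.0:
                pooled = float(y.std(ddof=0))
                y = y + eff * pooled * male
            values[(lab, meas)] = y

    metrics = []
    for i, subj in enumerate(design.table["subject"]):
        df = pd.DataFrame({"label_id": np.arange(1, n_regions + 1)})
        for meas in METRIC_NAMES:
            df[meas] = [values[(lab, meas)][i] for lab in range(1, n_regions + 1)]
        metrics.append(NodeMetricTable(table=df, subject_id=str(subj)))
    return metrics, design
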