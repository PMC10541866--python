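"""Haralick texture parameters from a GLCM and per-region feature vectors.

Eleven scalar statistics are computed from each normalized co-occurrence
matrix p(i, j): uniformity (angular second moment), contrast, correlation,
variance (sum of squares), homogeneity (inverse difference moment), entropy,
sum average, sum variance, sum entropy, difference variance, and difference
entropy. All entropies use log base 2 with the convention 0*log 0 = 0;
the downstream min–max normalization makes the base immaterial.

With five GLCMs per region (distances 1–5 voxels) this gives a 55-component
feature vector per region, ordered (d=1..5) x (11 features). Feature columns
are min–max scaled to [0, 1] across the regions of one subject so that each
subject's similarity network is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .glcm import GLCMatrix

FEATURE_NAMES = [
    "uniformity",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
]

DISTANCES = (1, 2, 3, 4, 5)

#: column names of the 55-feature vector, "d{1..5}_{feature}"
FEATURE_COLUMNS = [f"d{d}_{f}" for d in DISTANCES for f in FEATURE_NAMES]


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass
class GLCMarginals:
    """Marginal distributions of a GLCM: rows/columns, i+j and |i-j|."""

    p_x: np.ndarray
    p_y: np.ndarray
    p_sum: np.ndarray  # distribution of i+j over [0, 2G-2]
    p_diff: np.ndarray  # distribution of |i-j| over [0, G-1]

    @classmethod
    def from_glcm(cls, p: np.ndarray) -> "GLCMarginals":
        G = p.shape[0]
        i = np.arange(G)
        p_x = p.sum(axis=1)
        p_y = p.sum(axis=0)
        s = i[:, None] + i[None, :]
        d = np.abs(i[:, None] - i[None, :])
        p_sum = np.bincount(s.ravel(), weights=p.ravel(), minlength=2 * G - 1)
        p_diff = np.bincount(d.ravel(), weights=p.ravel(), minlength=G)
        return cls(p_x=p_x, p_y=p_y, p_sum=p_sum, p_diff=p_diff)

    @property
    def mu_x(self) -> float:
        return float(np.arange(len(self.p_x)) @ self.p_x)

    @property
    def mu_y(self) -> float:
        return float(np.arange(len(self.p_y)) @ self.p_y)

    @property
    def sigma_x(self) -> float:
        i = np.arange(len(self.p_x))
        return float(np.sqrt((i - self.mu_x) ** 2 @ self.p_x))

    @property
    def sigma_y(self) -> float:
        j = np.arange(len(self.p_y))
        return float(np.sqrt((j - self.mu_y) ** 2 @ self.p_y))


def features(m: GLCMatrix, sum_variance_legacy: bool = False) -> dict[str, float]:
    """The 11 texture parameters of a normalized GLCM, as an ordered dict.

    ``sum_variance_legacy`` switches sum variance to the historical centering
    on sum entropy instead of the modern centering on sum average.
    Correlation is defined as 0 for a degenerate (constant-level) matrix.
    """
    if m.degenerate:
        raise ValueError("degenerate GLCM (raw_count = 0) has no features")
    p = m.p
    G = p.shape[0]
    i = np.arange(G)
    marg = GLCMarginals.from_glcm(p)
    mu_x, mu_y = marg.mu_x, marg.mu_y
    sigma_x, sigma_y = marg.sigma_x, marg.sigma_y

    ii = i[:, None]
    jj = i[None, :]
    diff2 = (ii - jj) ** 2

    uniformity = float((p**2).sum())
    contrast = float((diff2 * p).sum())
    denom = sigma_x * sigma_y
    if denom > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / denom)
    else:
        correlation = 0.0
    # overall gray-level mean; equals mu_x = mu_y for symmetric matrices.
    # averaging the row/column second moments keeps the statistic
    # transpose-invariant even for asymmetric input
    mu = (mu_x + mu_y) / 2.0
    variance = float(
        0.5 * ((((ii - mu) ** 2) * p).sum() + (((jj - mu) ** 2) * p).sum())
    )
    homogeneity = float((p / (1.0 + diff2)).sum())
    entropy = _entropy(p)

    k_sum = np.arange(2 * G - 1)
    sum_average = float(k_sum @ marg.p_sum)
    sum_entropy = _entropy(marg.p_sum)
    center = sum_entropy if sum_variance_legacy else sum_average
    sum_variance = float((k_sum - center) ** 2 @ marg.p_sum)

    k_diff = np.arange(G)
    mu_diff = float(k_diff @ marg.p_diff)
    difference_variance = float((k_diff - mu_diff) ** 2 @ marg.p_diff)
    difference_entropy = _entropy(marg.p_diff)

    return {
        "uniformity": uniformity,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "homogeneity": homogeneity,
        "entropy": entropy,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
    }


def feature_vector(glcms: list[GLCMatrix] | dict[int, GLCMatrix]) -> np.ndarray:
    """Concatenate the 11 features over distances 1..5 into a 55-vector.

    The order is fixed by each GLCM's distance attribute, not by argument
    position. All five distances must be present, for the same region.
    """
    if isinstance(glcms, dict):
        by_d = {int(k): v for k, v in glcms.items()}
    else:
        by_d = {m.d: m for m in glcms}
    missing = [d for d in DISTANCES if d not in by_d]
    if missing:
        raise ValueError(f"missing GLCM distance(s): {missing}")
    labels = {m.label_id for m in by_d.values()}
    if len(labels) > 1:
        raise ValueError(f"GLCMs from mixed regions: {sorted(labels, key=str)}")
    out = []
    for d in DISTANCES:
        f = features(by_d[d])
        out.extend(f[name] for name in FEATURE_NAMES)
    vec = np.asarray(out, dtype=np.float64)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value")
    return vec


@dataclass
class FeatureMatrix:
    """Regions x 55 texture features for one subject."""

    values: pd.DataFrame  # index = region label_id, columns = FEATURE_COLUMNS
    subject_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != FEATURE_COLUMNS:
            raise ValueError("feature matrix columns must be the 55 named features")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate region labels")

    @property
    def region_labels(self) -> list[int]:
        return [int(x) for x in self.values.index]

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.insert(0, "label_id", df.index)
        df.insert(0, "subject", self.subject_id)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        subject = str(df["subject"].iloc[0]) if len(df) else ""
        df = df.set_index(df["label_id"].astype(int))
        df.index.name = None
        return cls(values=df[FEATURE_COLUMNS], subject_id=subject, normalized=True)


def normalize_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min–max scale each feature column to [0, 1] across the subject's regions.

    Constant columns map to 0.
    """
    if len(matrix.values) < 2:
        raise ValueError("need at least 2 regions to normalize")
    vals = matrix.values.to_numpy(dtype=np.float64)
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    out = np.zeros_like(vals)
    nz = span > 0
    out[:, nz] = (vals[:, nz] - lo[nz]) / span[nz]
    df = pd.DataFrame(out, index=matrix.values.index, columns=FEATURE_COLUMNS)
    return FeatureMatrix(values=df, subject_id=matrix.subject_id, normalized=True)
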