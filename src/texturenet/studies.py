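"""Cohort-level analyses of texture networks.

Four studies operate on per-subject connectivity matrices and node-metric
tables:

1. **Edge comparison** — for a named set of regions (e.g. a functional
   network), count how many of its N(N-1)/2 internal edges have a mean
   similarity (over subjects) greater than the grand mean of all edges, and
   greater than the grand mean plus one standard deviation.
2. **Sex ANCOVA** — per (region, measure), a linear model of the metric on
   sex with age, brain volume and intracranial volume as covariates;
   sex significance by partial F-test, Bonferroni-corrected over regions.
3. **Age ANCOVA** — same with age as the variable of interest and sex as a
   covariate; reports the full-model R² and the slope sign.
4. **Region deviation** — per measure, each region's deviation from the
   global mean in units of the global standard deviation, flagged beyond a
   threshold (default 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .network import METRIC_NAMES, ConnectivityMatrix, NodeMetricTable

COVARIATES_SEX = ["age", "brain_volume", "intracranial_volume"]
COVARIATES_AGE = ["sex", "brain_volume", "intracranial_volume"]


@dataclass
class CohortDesign:
    """Per-subject design: id, sex (two-level), age, brain and intracranial volume."""

    table: pd.DataFrame

    REQUIRED = ["subject", "sex", "age", "brain_volume", "intracranial_volume"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing column(s): {missing}")
        df = self.table[self.REQUIRED].copy()
        if df.isna().any().any():
            raise ValueError("design table has missing values")
        if (df["age"] <= 0).any():
            raise ValueError("ages must be positive")
        if (df[["brain_volume", "intracranial_volume"]] <= 0).any().any():
            raise ValueError("volumes must be positive")
        df["subject"] = df["subject"].astype(str)
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class FunctionalNetworkSpec:
    """A named list of region labels forming a candidate sub-network."""

    name: str
    labels: list[int]

    def __post_init__(self) -> None:
        self.labels = [int(x) for x in self.labels]
        if len(self.labels) < 2:
            raise ValueError("functional network needs at least 2 regions")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in functional network")

    @property
    def possible_connections(self) -> int:
        n = len(self.labels)
        return n * (n - 1) // 2


def read_network_specs(path: str | Path) -> list[FunctionalNetworkSpec]:
    """Read functional-network specs from TSV (network_name, label_id)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, grp in df.groupby("network_name", sort=False):
        out.append(FunctionalNetworkSpec(name=str(name), labels=grp["label_id"].tolist()))
    return out


@dataclass
class EdgeComparisonResult:
    network: str
    possible_connections: int
    n_greater_than_mean: int
    pct_greater: float
    n_greater_1sd: int
    pct_greater_1sd: float
    grand_mean: float
    grand_sd: float
    grand_sd_pooled: float

    def as_row(self) -> dict:
        return {
            "network": self.network,
            "possible_connections": self.possible_connections,
            "greater_than_mean": self.n_greater_than_mean,
            "greater_than_mean_pct": self.pct_greater,
            "greater_1sd": self.n_greater_1sd,
            "greater_1sd_pct": self.pct_greater_1sd,
        }


def _stack_edges(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, list[int]]:
    labels = matrices[0].region_labels
    for m in matrices[1:]:
        if m.region_labels != labels:
            raise ValueError("connectivity matrices have differing region sets")
    return np.stack([m.w for m in matrices]), labels


def edge_comparison(
    matrices: list[ConnectivityMatrix],
    spec: FunctionalNetworkSpec,
    sd_mode: str = "edge_means",
) -> EdgeComparisonResult:
    """Compare a region set's internal edges against the whole-network baseline.

    The grand mean is taken over all off-diagonal edges (every region pair)
    and subjects; per-edge means over subjects are then compared with it.
    The baseline SD is over the per-edge means (``sd_mode="edge_means"``,
    default) or over all subject x edge values (``sd_mode="pooled"``); both
    are reported.
    """
    stack, labels = _stack_edges(matrices)
    missing = [l for l in spec.labels if l not in labels]
    if missing:
        raise ValueError(f"spec region(s) missing from matrices: {missing}")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    edge_values = stack[:, iu[0], iu[1]]  # subjects x edges
    edge_means = edge_values.mean(axis=0)
    grand_mean = float(edge_means.mean())  # == pooled mean
    sd_edge_means = float(edge_means.std(ddof=0))
    sd_pooled = float(edge_values.std(ddof=0))
    grand_sd = sd_edge_means if sd_mode == "edge_means" else sd_pooled

    idx = {lab: k for k, lab in enumerate(labels)}
    sel = np.zeros(n, dtype=bool)
    sel[[idx[l] for l in spec.labels]] = True
    in_spec = sel[iu[0]] & sel[iu[1]]
    spec_means = edge_means[in_spec]
    assert len(spec_means) == spec.possible_connections

    n_gt = int((spec_means > grand_mean).sum())
    n_gt_1sd = int((spec_means > grand_mean + grand_sd).sum())
    poss = spec.possible_connections
    return EdgeComparisonResult(
        network=spec.name,
        possible_connections=poss,
        n_greater_than_mean=n_gt,
        pct_greater=100.0 * n_gt / poss,
        n_greater_1sd=n_gt_1sd,
        pct_greater_1sd=100.0 * n_gt_1sd / poss,
        grand_mean=grand_mean,
        grand_sd=grand_sd,
        grand_sd_pooled=sd_pooled,
    )


@dataclass
class AncovaResult:
    """Per (region, measure) ANCOVA results."""

    table: pd.DataFrame  # label_id, measure, p_value, p_bonferroni, r_squared,
    #                      direction, zero_fraction
    factor: str = ""

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _metrics_long(metrics: list[NodeMetricTable]) -> pd.DataFrame:
    frames = []
    for t in metrics:
        df = t.table.copy()
        df.insert(0, "subject", t.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _merged(metrics: list[NodeMetricTable], design: CohortDesign) -> pd.DataFrame:
    long = _metrics_long(metrics)
    subjects_m = set(long["subject"])
    subjects_d = set(design.table["subject"])
    if subjects_m != subjects_d:
        raise ValueError(
            "metrics and design subject sets differ: "
            f"only-metrics={sorted(subjects_m - subjects_d)[:5]}, "
            f"only-design={sorted(subjects_d - subjects_m)[:5]}"
        )
    return long.merge(design.table, on="subject", validate="many_to_one")


def _sex_codes(col: pd.Series) -> np.ndarray:
    levels = sorted(col.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"sex must have exactly 2 levels, got {levels}")
    return (col.astype(str) == levels[1]).to_numpy(dtype=float)


def _ancova_one(
    y: np.ndarray, x_interest: np.ndarray, covariates: np.ndarray
) -> tuple[float, float, float]:
    """OLS y ~ x + covariates; returns (p of x by partial F, full-model R2, coef)."""
    if np.ptp(y) == 0:
        # constant outcome (e.g. betweenness identically zero): no effect testable
        return 1.0, 0.0, 0.0
    X = sm.add_constant(np.column_stack([x_interest, covariates]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    # partial (Type III) F-test of the single-df term of interest; equals the
    # squared t-test for a one-column term
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    ftest = fit.f_test(contrast)
    return float(ftest.pvalue), float(fit.rsquared), float(fit.params[1])


def _run_ancova(
    merged: pd.DataFrame, interest: str, covariate_names: list[str], factor_label: str
) -> AncovaResult:
    rows = []
    labels = sorted(merged["label_id"].unique())
    n_regions = len(labels)
    for measure in METRIC_NAMES:
        for lab in labels:
            sub = merged.loc[merged["label_id"] == lab]
            y = sub[measure].to_numpy(dtype=float)
            cols = []
            for c in [interest] + covariate_names:
                cols.append(_sex_codes(sub[c]) if c == "sex" else sub[c].to_numpy(dtype=float))
            p, r2, coef = _ancova_one(y, cols[0], np.column_stack(cols[1:]))
            rows.append(
                {
                    "label_id": lab,
                    "measure": measure,
                    "p_value": p,
                    "p_bonferroni": min(1.0, p * n_regions),
                    "r_squared": r2,
                    "coef": coef,
                    "direction": int(np.sign(coef)),
                    "zero_fraction": float((y == 0).mean()),
                }
            )
    return AncovaResult(table=pd.DataFrame(rows), factor=factor_label)


def ancova_factor(
    metrics: list[NodeMetricTable], design: CohortDesign, factor: str = "sex"
) -> AncovaResult:
    """Per (region, measure) ANCOVA of the metric on a two-level factor.

    Model: metric ~ factor + age + brain_volume + intracranial_volume.
    Bonferroni family = number of regions, applied within each measure.
    ``direction`` is the sign of the adjusted difference (second sorted sex
    level minus first).
    """
    if factor != "sex":
        raise ValueError("only the sex factor is supported")
    merged = _merged(metrics, design)
    return _run_ancova(merged, "sex", COVARIATES_SEX, "sex")


def ancova_age(metrics: list[NodeMetricTable], design: CohortDesign) -> AncovaResult:
    """Per (region, measure) ANCOVA of the metric on age.

    Model: metric ~ age + sex + brain_volume + intracranial_volume.
    Reports the full-model R² and the age slope sign.
    """
    merged = _merged(metrics, design)
    return _run_ancova(merged, "age", COVARIATES_AGE, "age")


@dataclass
class DeviationResult:
    """Region deviations from the global mean, in global-SD units, per measure."""

    table: pd.DataFrame  # label_id, measure, deviation, flagged
    threshold: float = 1.5

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def region_deviation(
    metrics: list[NodeMetricTable], threshold: float = 1.5, sd_mode: str = "pooled"
) -> DeviationResult:
    """Per measure: (region mean - global mean) / global SD, flagged beyond threshold.

    Region means are over subjects; the global mean and SD are over all
    subject x region values (``sd_mode="pooled"``, default) or the SD over
    the region means (``sd_mode="region_means"``).
    """
    long = _metrics_long(metrics)
    if long["label_id"].nunique() < 2:
        raise ValueError("need at least 2 regions")
    rows = []
    for measure in METRIC_NAMES:
        vals = long[measure].to_numpy(dtype=float)
        region_means = long.groupby("label_id")[measure].mean()
        global_mean = float(vals.mean())
        sd = float(vals.std(ddof=0)) if sd_mode == "pooled" else float(region_means.std(ddof=0))
        if sd == 0:
            raise ValueError(f"zero global SD for measure {measure}")
        for lab, rmean in region_means.items():
            dev = (float(rmean) - global_mean) / sd
            rows.append(
                {
                    "label_id": lab,
                    "measure": measure,
                    "deviation": dev,
                    "flagged": bool(abs(dev) > threshold),
                }
            )
    return DeviationResult(table=pd.DataFrame(rows), threshold=threshold)
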