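"""Pipeline orchestration: phantom -> extract -> network -> metrics -> studies.

Directory convention (all plain text or NIfTI):

* input: ``labels.nii.gz``, ``regions.tsv``, ``design.tsv``,
  ``sub-*.nii.gz`` intensity volumes, optionally ``networks.tsv``
  (columns network_name, label_id);
* output: ``features/<subject>.tsv``, ``connectivity/<subject>.tsv``,
  ``metrics/<subject>.tsv``, ``studies/*.tsv``, plus ``config.yaml``,
  ``run_log.txt`` and per-stage cache manifests.

Stages are cached by a content hash of their inputs and the configuration:
a re-run with identical inputs skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import glcm as glcm_mod
from . import studies as studies_mod
from .config import RunConfig
from .haralick import (
    FEATURE_COLUMNS,
    FeatureMatrix,
    feature_vector,
)
from .network import ConnectivityMatrix, NodeMetricTable, node_metrics, similarity_matrix
from .phantom import PhantomSpec, simulate_cohort
from .studies import CohortDesign, read_network_specs
from .volumes import (
    IntensityVolume,
    LabelVolume,
    RegionTable,
    read_labels,
    read_volume,
    roi_mask,
    select_regions,
    write_volume,
)

log = logging.getLogger(__name__)


def _hash_paths(paths: list[Path], extra: str = "") -> str:
    h = hashlib.sha256(extra.encode())
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


def _stage_fresh(stage_dir: Path, key: str) -> bool:
    manifest = stage_dir / ".manifest.json"
    if manifest.exists():
        try:
            return json.loads(manifest.read_text())["key"] == key
        except (json.JSONDecodeError, KeyError):
            return False
    return False


def _mark_stage(stage_dir: Path, key: str) -> None:
    (stage_dir / ".manifest.json").write_text(json.dumps({"key": key}))


def extract_features(
    volume: IntensityVolume,
    labels: LabelVolume,
    table: RegionTable,
    config: RunConfig | None = None,
    subject_id: str = "",
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Raw (un-normalized) 55-feature matrix for one subject, plus a sparsity report.

    Regions are taken as given in ``table`` (selection is applied upstream).
    Each region's intensities are quantized per-ROI and its five GLCMs
    computed over the configured distances.
    """
    config = config or RunConfig()
    if volume.data.shape != labels.data.shape:
        raise ValueError("intensity and label volumes are on different grids")
    rows = []
    sparsity_rows = []
    for lab in table.label_ids:
        mask = roi_mask(labels, lab, table)
        if mask.voxel_count == 0:
            raise ValueError(f"region {lab} has no voxels in the label volume")
        # crop to the ROI bounding box: co-occurrences never cross the mask
        idx = np.nonzero(mask.data)
        dmax = max(config.distances)
        sl = tuple(
            slice(max(0, int(a.min()) - dmax), int(a.max()) + 1 + dmax) for a in idx
        )
        sub_vol = IntensityVolume(volume.data[sl])
        sub_mask = type(mask)(data=mask.data[sl], label_id=lab)
        q = glcm_mod.quantize(sub_vol, sub_mask, G=config.gray_levels)
        glcms = []
        for d in config.distances:
            m = glcm_mod.compute_glcm(q, sub_mask, d, label_id=lab)
            glcms.append(m)
            sparsity_rows.append(
                {
                    "label_id": lab,
                    "d": d,
                    "G": config.gray_levels,
                    "sparsity": glcm_mod.sparsity(m),
                    "raw_count": m.raw_count,
                }
            )
        rows.append(dict(zip(FEATURE_COLUMNS, feature_vector(glcms))) | {"label_id": lab})
    df = pd.DataFrame(rows).set_index("label_id")
    df.index.name = None
    fm = FeatureMatrix(values=df[FEATURE_COLUMNS], subject_id=subject_id)
    return fm, pd.DataFrame(sparsity_rows)


def normalize_cohort(matrices: list[FeatureMatrix]) -> list[FeatureMatrix]:
    """Min–max scale feature columns over the pooled rows of all subjects."""
    stacked = np.vstack([m.values.to_numpy(dtype=float) for m in matrices])
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    out = []
    for m in matrices:
        vals = (m.values.to_numpy(dtype=float) - lo) / span
        vals[:, hi == lo] = 0.0
        df = pd.DataFrame(vals, index=m.values.index, columns=FEATURE_COLUMNS)
        out.append(FeatureMatrix(values=df, subject_id=m.subject_id, normalized=True))
    return out


def _load_inputs(config: RunConfig) -> tuple[LabelVolume, RegionTable, CohortDesign, list[Path]]:
    in_dir = Path(config.input_dir)
    labels_path = in_dir / "labels.nii.gz"
    regions_path = in_dir / "regions.tsv"
    design_path = in_dir / "design.tsv"
    for p in (labels_path, regions_path, design_path):
        if not p.exists():
            raise FileNotFoundError(
                f"missing input {p.name} in {in_dir}; expected labels.nii.gz, "
                "regions.tsv, design.tsv and sub-*.nii.gz volumes"
            )
    vol_paths = sorted(in_dir.glob("sub-*.nii.gz"))
    if not vol_paths:
        raise FileNotFoundError(f"no subject volumes (sub-*.nii.gz) in {in_dir}")
    labels = read_labels(labels_path)
    table = RegionTable.from_tsv(regions_path).with_counts(labels)
    design = CohortDesign.from_tsv(design_path)
    return labels, table, design, vol_paths


def run_phantom(config: RunConfig, spec: PhantomSpec | None = None, n: int = 10) -> Path:
    """Generate a phantom cohort into the input directory."""
    spec = spec or PhantomSpec(seed=config.seed)
    out = Path(config.input_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(spec, n)
    write_volume(cohort.labels, out / "labels.nii.gz")
    cohort.region_table.to_tsv(out / "regions.tsv")
    cohort.design.to_tsv(out / "design.tsv")
    for subj, vol in zip(cohort.design.table["subject"], cohort.volumes):
        write_volume(vol, out / f"{subj}.nii.gz")
    log.info("phantom cohort of %d subjects written to %s", n, out)
    return out


def run_extract(config: RunConfig) -> Path:
    """Extract normalized feature matrices for every subject."""
    labels, table, design, vol_paths = _load_inputs(config)
    selected = select_regions(table, config.min_solo, config.min_pair)
    if len(selected) == 0:
        raise ValueError("no regions survive size selection")
    out_dir = Path(config.output_dir)
    feat_dir = out_dir / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    key = _hash_paths(vol_paths, extra=config.content_hash())
    if _stage_fresh(feat_dir, key):
        log.info("features up to date, skipping extraction")
        return feat_dir
    config.to_yaml(out_dir / "config.yaml")

    raw = []
    sparsity_frames = []
    for p in vol_paths:
        subject = p.name.replace(".nii.gz", "")
        vol = read_volume(p)
        fm, sparsity = extract_features(vol, labels, selected, config, subject_id=subject)
        raw.append(fm)
        sparsity.insert(0, "subject", subject)
        sparsity_frames.append(sparsity)
    if config.feature_norm_scope == "cohort":
        norm = normalize_cohort(raw)
    else:
        from .haralick import normalize_features

        norm = [normalize_features(m) for m in raw]
    for fm in norm:
        fm.to_tsv(feat_dir / f"{fm.subject_id}.tsv")
    pd.concat(sparsity_frames, ignore_index=True).to_csv(
        out_dir / "sparsity.tsv", sep="\t", index=False, float_format="%.6g"
    )
    _mark_stage(feat_dir, key)
    return feat_dir


def run_network(config: RunConfig) -> Path:
    """Build per-subject connectivity matrices from feature TSVs."""
    out_dir = Path(config.output_dir)
    feat_dir = out_dir / "features"
    paths = sorted(feat_dir.glob("sub-*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no feature matrices in {feat_dir}; run extract first")
    conn_dir = out_dir / "connectivity"
    conn_dir.mkdir(parents=True, exist_ok=True)
    key = _hash_paths(paths, extra=config.content_hash())
    if _stage_fresh(conn_dir, key):
        return conn_dir
    for p in paths:
        fm = FeatureMatrix.from_tsv(p)
        conn = similarity_matrix(fm, variant=config.similarity_variant)
        conn.to_tsv(conn_dir / p.name)
    _mark_stage(conn_dir, key)
    return conn_dir


def run_metrics(config: RunConfig) -> Path:
    """Compute the five node measures for every subject's network."""
    out_dir = Path(config.output_dir)
    conn_dir = out_dir / "connectivity"
    paths = sorted(conn_dir.glob("sub-*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no connectivity matrices in {conn_dir}; run network first")
    met_dir = out_dir / "metrics"
    met_dir.mkdir(parents=True, exist_ok=True)
    key = _hash_paths(paths, extra=config.content_hash())
    if _stage_fresh(met_dir, key):
        return met_dir
    for p in paths:
        subject = p.name.replace(".tsv", "")
        conn = ConnectivityMatrix.from_tsv(p, subject_id=subject)
        node_metrics(conn).to_tsv(met_dir / p.name)
    _mark_stage(met_dir, key)
    return met_dir


def _load_metric_tables(met_dir: Path) -> list[NodeMetricTable]:
    out = []
    for p in sorted(met_dir.glob("sub-*.tsv")):
        df = pd.read_csv(p, sep="\t")
        subject = str(df["subject"].iloc[0])
        out.append(NodeMetricTable(table=df.drop(columns="subject"), subject_id=subject))
    return out


def run_studies(config: RunConfig) -> Path:
    """Run the four cohort analyses and write their result tables."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    conn_dir = out_dir / "connectivity"
    met_dir = out_dir / "metrics"
    design_path = in_dir / "design.tsv"
    design = CohortDesign.from_tsv(design_path)
    matrices = [
        ConnectivityMatrix.from_tsv(p, subject_id=p.name.replace(".tsv", ""))
        for p in sorted(conn_dir.glob("sub-*.tsv"))
    ]
    metrics = _load_metric_tables(met_dir)
    if not matrices or not metrics:
        raise FileNotFoundError("connectivity/metrics outputs missing; run earlier stages")
    studies_dir = out_dir / "studies"
    studies_dir.mkdir(parents=True, exist_ok=True)

    lines = [f"config_hash: {config.content_hash()}"]
    lines += [f"{k}: {v}" for k, v in sorted(config.to_dict().items())]

    # study 1: functional-network edge comparison (optional networks.tsv)
    networks_path = in_dir / "networks.tsv"
    if networks_path.exists():
        specs = read_network_specs(networks_path)
        rows = [
            studies_mod.edge_comparison(matrices, s, sd_mode=config.edge_sd_mode).as_row()
            for s in specs
        ]
        pd.DataFrame(rows).to_csv(
            studies_dir / "edge_comparison.tsv", sep="\t", index=False, float_format="%.6g"
        )
        lines.append("study1: edge_comparison.tsv written")
    else:
        lines.append("study1: skipped (no networks.tsv)")

    # studies 2-3: sex and age ANCOVA
    sex_res = studies_mod.ancova_factor(metrics, design, factor="sex")
    sex_res.to_tsv(studies_dir / "ancova_sex.tsv")
    age_res = studies_mod.ancova_age(metrics, design)
    age_res.to_tsv(studies_dir / "ancova_age.tsv")
    lines.append("study2: ancova_sex.tsv written (covariates: age, brain_volume, "
                 "intracranial_volume; partial F; Bonferroni over regions per measure)")
    lines.append("study3: ancova_age.tsv written (covariates: sex, brain_volume, "
                 "intracranial_volume; full-model R^2)")

    # study 4: region deviation
    dev = studies_mod.region_deviation(
        metrics, threshold=config.deviation_threshold, sd_mode=config.deviation_sd_mode
    )
    dev.to_tsv(studies_dir / "region_deviation.tsv")
    lines.append(f"study4: region_deviation.tsv written (threshold {config.deviation_threshold})")

    lines.append("weighted-measure conventions: BC/LE lengths 1/w; CC Onnela; EC max-normalized")
    (studies_dir / "run_log.txt").write_text("\n".join(lines) + "\n")
    return studies_dir


def run_all(config: RunConfig) -> Path:
    run_extract(config)
    run_network(config)
    run_metrics(config)
    return run_studies(config)
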