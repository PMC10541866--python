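"""Volume and region-table handling.

Intensity volumes are 3D scalar grids (T1-like contrast, arbitrary units);
label volumes carry an integer parcellation on the same grid (0 = background).
Each labelled parcel is one network node. Regions enter the analysis only if
they pass a size rule: a region must exceed ``min_solo`` voxels on its own, or
belong to a homologous (left/right) pair of which at least one member exceeds
``min_pair`` voxels — in which case both members are kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REGION_TABLE_COLUMNS = ["label_id", "name", "homolog_id", "voxel_count"]


@dataclass
class IntensityVolume:
    """A 3D scalar image with voxel size metadata (mm per axis)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D integer parcellation; label 0 is background."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label volume, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("labels must be integers")
            self.data = rounded.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels_present(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]


@dataclass
class ROIMask:
    """Boolean mask of one region, tagged with the label it came from."""

    data: np.ndarray
    label_id: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class RegionTable:
    """Region metadata: label ids, names, homolog pairing, voxel counts.

    The homolog relation must be symmetric: if region a names b as its
    homolog, b must name a.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "voxel_count" not in df.columns:
            df["voxel_count"] = 0
        df = df[REGION_TABLE_COLUMNS]
        df["label_id"] = df["label_id"].astype(int)
        df["voxel_count"] = df["voxel_count"].astype(int)
        if df["label_id"].duplicated().any():
            raise ValueError("duplicate label ids in region table")
        if (df["label_id"] <= 0).any():
            raise ValueError("label ids must be positive")
        self.table = df.reset_index(drop=True)
        self._check_homologs()

    def _check_homologs(self) -> None:
        homolog = self._homolog_map()
        for a, b in homolog.items():
            if b not in homolog or homolog[b] != a:
                raise ValueError(f"homolog relation not symmetric: {a} -> {b}")

    def _homolog_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for row in self.table.itertuples():
            if pd.notna(row.homolog_id):
                out[int(row.label_id)] = int(row.homolog_id)
        return out

    @property
    def label_ids(self) -> list[int]:
        return self.table["label_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, label_id: int) -> bool:
        return int(label_id) in set(self.label_ids)

    def voxel_count(self, label_id: int) -> int:
        row = self.table.loc[self.table["label_id"] == int(label_id)]
        if row.empty:
            raise KeyError(f"unknown label id {label_id}")
        return int(row["voxel_count"].iloc[0])

    def name(self, label_id: int) -> str:
        row = self.table.loc[self.table["label_id"] == int(label_id)]
        if row.empty:
            raise KeyError(f"unknown label id {label_id}")
        return str(row["name"].iloc[0])

    def with_counts(self, labels: LabelVolume) -> "RegionTable":
        """Return a copy with voxel counts recomputed from a label volume."""
        data = labels.data
        counts = np.bincount(data.ravel(), minlength=int(data.max()) + 2)
        df = self.table.copy()
        df["voxel_count"] = [
            int(counts[lid]) if lid < len(counts) else 0 for lid in df["label_id"]
        ]
        missing = df.loc[df["voxel_count"] == 0, "label_id"].tolist()
        if missing:
            log.warning("regions absent from label volume (voxel_count 0): %s", missing)
        return RegionTable(df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionTable":
        df = pd.read_csv(path, sep="\t")
        if "voxel_count" not in df.columns:
            df["voxel_count"] = 0
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a 3D NIfTI intensity volume.

    Raises FileNotFoundError for missing files and ValueError for non-3D
    images.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D volume, got {img.ndim}D: {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(data=data, voxel_size=voxel_size)


def read_labels(path: str | Path) -> LabelVolume:
    """Read a 3D NIfTI label (parcellation) volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D label volume, got {img.ndim}D: {path}")
    data = np.asarray(img.get_fdata())
    return LabelVolume(data=np.rint(data).astype(np.int32))


def write_volume(volume: IntensityVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal affine from the voxel size."""
    if isinstance(volume, IntensityVolume):
        data = volume.data
        zooms = volume.voxel_size
    else:
        data = volume.data.astype(np.int32)
        zooms = (1.0, 1.0, 1.0)
    affine = np.diag(list(zooms) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def roi_mask(labels: LabelVolume, label_id: int, table: RegionTable | None = None) -> ROIMask:
    """Boolean mask of the voxels carrying ``label_id``.

    If a region table is given, the label must be listed in it; a label that
    is listed but absent from the volume yields an empty mask, not an error.
    """
    label_id = int(label_id)
    if table is not None and label_id not in table:
        raise KeyError(f"unknown label id {label_id}")
    return ROIMask(data=labels.data == label_id, label_id=label_id)


def select_regions(
    table: RegionTable, min_solo: int = 900, min_pair: int = 1000
) -> RegionTable:
    """Apply the region-size selection rule.

    Keep region r iff voxel_count(r) > min_solo (strict), OR r has a homolog h
    and max(voxel_count(r), voxel_count(h)) > min_pair — both members of a
    qualifying pair are kept, even if one is small.
    """
    df = table.table
    counts = dict(zip(df["label_id"], df["voxel_count"]))
    homolog = table._homolog_map()
    keep = []
    for row in df.itertuples():
        lid = int(row.label_id)
        ok = counts[lid] > min_solo
        if not ok and lid in homolog:
            ok = max(counts[lid], counts.get(homolog[lid], 0)) > min_pair
        keep.append(ok)
    dropped = df.loc[[not k for k in keep], "label_id"].tolist()
    if dropped:
        log.info("regions dropped by size selection: %s", dropped)
    out = df.loc[keep].copy()
    # prune homolog pointers to dropped partners so the relation stays symmetric
    kept_ids = set(out["label_id"])
    out["homolog_id"] = [
        h if pd.notna(h) and int(h) in kept_ids else np.nan for h in out["homolog_id"]
    ]
    return RegionTable(out)
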