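"""Volume I/O, geometry and ROI-mask primitives.

All spatial data in the package live on regular 3-D grids with a simple
axis-aligned world frame: ``world = origin + index * spacing`` (mm), voxel
indices 0-based.  Volumes round-trip through NIfTI-1 via nibabel; label
tables are TSV with columns ``label_id`` and ``name``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised for unsupported or malformed volume inputs."""


@dataclass(frozen=True)
class Geometry:
    """Grid shape plus the affine-free world mapping (spacing, origin) in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise FormatError(f"grid shape must be 3-D with dims >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise FormatError(f"spacing components must be finite and > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def index_grid_world(self) -> np.ndarray:
        """World coordinates (mm) of every voxel, shape ``shape + (3,)``."""
        idx = np.indices(self.shape, dtype=float)
        return np.stack(
            [self.origin[a] + idx[a] * self.spacing[a] for a in range(3)], axis=-1
        )


@dataclass
class Volume:
    """A 3-D scalar grid with its geometry.

    Carries image intensities as well as derived voxelwise maps (Jacobians,
    grey-matter density, t/p/weight maps).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D scalar grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite values")
        # route geometry validation through Geometry
        g = Geometry(self.data.shape, tuple(self.spacing), tuple(self.origin))
        self.spacing = g.spacing
        self.origin = g.origin

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.data.shape, self.spacing, self.origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.geometry.voxel_volume_mm3

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data), self.spacing, self.origin)


@dataclass
class LabelVolume:
    """Integer label grid plus a table mapping label id -> structure name."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"expected a 3-D label grid, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise FormatError("label grid is not integer-valued")
            self.labels = np.round(self.labels).astype(np.int32)
        g = Geometry(self.labels.shape, tuple(self.spacing), tuple(self.origin))
        self.spacing = g.spacing
        self.origin = g.origin
        self.table = {int(k): str(v) for k, v in dict(self.table).items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.table)
        if missing:
            raise FormatError(f"label ids {sorted(missing)} missing from the label table")

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.labels.shape, self.spacing, self.origin)

    def with_labels(self, labels: np.ndarray) -> "LabelVolume":
        return LabelVolume(np.asarray(labels), self.spacing, self.origin, dict(self.table))


@dataclass(frozen=True)
class ROIDefinition:
    """A named composite region: a set of atlas label ids."""

    name: str
    label_ids: frozenset[int]
    laterality: str = "bilateral"  # left | right | bilateral

    def __post_init__(self) -> None:
        object.__setattr__(self, "label_ids", frozenset(int(i) for i in self.label_ids))
        if not self.label_ids:
            raise ValueError(f"ROI {self.name!r} has no label ids")
        if self.laterality not in ("left", "right", "bilateral"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


VALID_GROUPS = ("C", "FTD", "AD", "SMCI", "PMCI")


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject: diagnostic group plus the classification covariates."""

    id: str
    group: str
    age: float
    sex: str  # male | female
    icv: float  # ml
    mmse: float | None = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male|female, got {self.sex!r}")
        if not self.age > 0:
            raise ValueError("age must be > 0")
        if not self.icv > 0:
            raise ValueError("icv must be > 0")


# ---------------------------------------------------------------------------
# NIfTI round-trip


def _geometry_from_img(img) -> Geometry:
    data_shape = img.shape
    if len(data_shape) == 4 and data_shape[3] == 1:
        data_shape = data_shape[:3]
    elif len(data_shape) != 3:
        raise FormatError(f"expected a 3-D volume, file has shape {data_shape}")
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    if any(s <= 0 for s in spacing):
        raise FormatError(f"non-positive voxel spacing in header: {spacing}")
    origin = tuple(float(x) for x in aff[:3, 3])
    return Geometry(tuple(int(s) for s in data_shape), spacing, origin)


def read_volume(path: str | Path) -> Volume:
    """Read a 3-D scalar NIfTI volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    geom = _geometry_from_img(img)
    data = np.asanyarray(img.dataobj, dtype=np.float64).reshape(geom.shape)
    return Volume(data, geom.spacing, geom.origin)


def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.geometry.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_label_volume(path: str | Path, table_path: str | Path | None = None) -> LabelVolume:
    """Read an integer label NIfTI; the table TSV defaults to ``<stem>_labels.tsv``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    geom = _geometry_from_img(img)
    labels = np.asanyarray(img.dataobj).reshape(geom.shape)
    if table_path is None:
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        table_path = path.parent / f"{stem}_labels.tsv"
    table = read_label_table(table_path) if Path(table_path).exists() else {}
    if not table:
        table = {int(i): f"label_{int(i)}" for i in np.unique(labels) if int(i) != 0}
    return LabelVolume(np.round(labels).astype(np.int32), geom.spacing, geom.origin, table)


def write_label_volume(lab: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(lab.labels, dtype=np.int16), lab.geometry.affine())
    img.header.set_zooms(lab.spacing)
    nib.save(img, str(path))
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    write_label_table(lab.table, path.parent / f"{stem}_labels.tsv")
    return path


def read_label_table(path: str | Path) -> dict[int, str]:
    table: dict[int, str] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        cols = line.split("\t")
        if i == 0 and cols[0].strip().lower() == "label_id":
            continue
        table[int(cols[0])] = cols[1].strip()
    return table


def write_label_table(table: Mapping[int, str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = ["label_id\tname"] + [f"{int(k)}\t{v}" for k, v in sorted(table.items())]
    path.write_text("\n".join(rows) + "\n")
    return path


# ---------------------------------------------------------------------------
# Masks and resampling


def make_roi_mask(atlas: LabelVolume, roi: ROIDefinition) -> Volume:
    """Binary mask: 1 where the atlas label belongs to the ROI's label set."""
    known = set(int(i) for i in np.unique(atlas.labels)) | set(atlas.table)
    unknown = set(roi.label_ids) - known
    if unknown:
        raise KeyError(
            f"ROI {roi.name!r} references unknown label id(s) {sorted(unknown)}"
        )
    mask = np.isin(atlas.labels, sorted(roi.label_ids)).astype(np.uint8)
    return Volume(mask, atlas.spacing, atlas.origin)


_RESAMPLE_ORDER = {"nearest": 0, "linear": 1}


def resample(vol: Volume, target: Geometry, mode: str = "linear") -> Volume:
    """Resample a volume onto a target grid through the shared world frame."""
    if mode not in _RESAMPLE_ORDER:
        raise ValueError(f"unsupported resampling mode {mode!r}")
    if vol.geometry == target:
        return Volume(vol.data.copy(), vol.spacing, vol.origin)
    idx = np.indices(target.shape, dtype=float)
    coords = [
        (target.origin[a] + idx[a] * target.spacing[a] - vol.origin[a]) / vol.spacing[a]
        for a in range(3)
    ]
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), coords, order=_RESAMPLE_ORDER[mode], mode="nearest"
    )
    return Volume(out, target.spacing, target.origin)


def resample_labels(lab: LabelVolume, target: Geometry) -> LabelVolume:
    """Nearest-neighbour label resampling preserving the label table."""
    vol = Volume(lab.labels.astype(np.float64), lab.spacing, lab.origin)
    out = resample(vol, target, mode="nearest")
    return LabelVolume(np.round(out.data).astype(np.int32), target.spacing, target.origin, dict(lab.table))


# ---------------------------------------------------------------------------
# Subject tables


def write_subject_table(records: Iterable[SubjectRecord], path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "id": r.id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "icv": r.icv,
            "mmse": "" if r.mmse is None else r.mmse,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    out = []
    for _, row in df.iterrows():
        mmse = row.get("mmse")
        mmse = None if mmse is None or (isinstance(mmse, float) and np.isnan(mmse)) or mmse == "" else float(mmse)
        out.append(
            SubjectRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                icv=float(row["icv"]),
                mmse=mmse,
            )
        )
    return out
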