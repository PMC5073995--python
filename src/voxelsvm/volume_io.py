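"""Volume and mask I/O, the subjects x voxels matrix, and normalizations.

The central exchange type is :class:`SubjectMatrix`: a real matrix with one
row per subject and one column per mask-interior voxel, together with the
ordered lattice coordinate each column maps to.  Columns enumerate mask
voxels in a fixed x-fastest scan order (x varies fastest, then y, then z) so
that column indices are reproducible across runs and machines.

Intensities are regional-cerebral-blood-flow-like: positive-valued, on an
arbitrary per-scan scale.  Two normalizations are provided:

* :func:`whole_brain_normalize` divides each subject's row by its own
  within-mask mean, removing global-scale differences between scans.
* :func:`minmax_scale` maps each feature affinely to [-1, 1] using training
  extremes only, the scaling convention expected by the SVM stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGeometry",
    "BrainMask",
    "SubjectMatrix",
    "load_mask",
    "load_cohort",
    "whole_brain_normalize",
    "minmax_scale",
    "write_cluster_map",
    "load_cluster_map",
]


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid shape, voxel size and voxel-to-world affine of a volume."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )

    @classmethod
    def from_affine(cls, shape: Sequence[int], affine: np.ndarray) -> "VolumeGeometry":
        affine = np.asarray(affine, dtype=float)
        vox = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        return cls(tuple(shape), vox, affine)

    @classmethod
    def default(
        cls, shape: Sequence[int], voxel_size_mm: float | Sequence[float] = 2.0
    ) -> "VolumeGeometry":
        """Axis-aligned geometry with the origin at the grid centre."""
        if np.isscalar(voxel_size_mm):
            voxel_size_mm = (voxel_size_mm,) * 3
        vox = tuple(float(v) for v in voxel_size_mm)
        affine = np.diag(list(vox) + [1.0])
        affine[:3, 3] = [-(s - 1) / 2 * v for s, v in zip(shape, vox)]
        return cls(tuple(shape), vox, affine)

    def matches(self, other: "VolumeGeometry", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_to_mm(self, coords: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world-mm coordinates via the affine."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        homo = np.hstack([coords, np.ones((coords.shape[0], 1))])
        return (self.affine @ homo.T).T[:, :3]


@dataclass(frozen=True)
class BrainMask:
    """Boolean interior indicator over a grid."""

    geometry: VolumeGeometry
    inside: np.ndarray

    def __post_init__(self) -> None:
        inside = np.asarray(self.inside, dtype=bool)
        if inside.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {inside.shape} != geometry shape {self.geometry.shape}"
            )
        if not inside.any():
            raise ValueError("mask has no interior voxels")
        object.__setattr__(self, "inside", inside)

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    def coords(self) -> np.ndarray:
        """Interior voxel coordinates, (n_inside, 3), x-fastest scan order."""
        flat = np.flatnonzero(self.inside.ravel(order="F"))
        return np.column_stack(
            np.unravel_index(flat, self.geometry.shape, order="F")
        ).astype(np.int64)


@dataclass
class SubjectMatrix:
    """Subjects x voxels matrix with per-column lattice coordinates.

    Rows are subjects, columns are voxels — the samples x features estimator
    convention.  ``coords[j]`` is the lattice coordinate of column ``j``.
    """

    values: np.ndarray
    coords: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    geometry: VolumeGeometry | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x voxels)")
        if self.coords.shape != (self.values.shape[1], 3):
            raise ValueError("coords must have one integer triple per column")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per row required")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject id per row required")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset_columns(self, columns: np.ndarray) -> "SubjectMatrix":
        columns = np.asarray(columns, dtype=np.int64)
        return SubjectMatrix(
            self.values[:, columns],
            self.coords[columns],
            self.labels,
            self.subject_ids,
            self.geometry,
        )


def _read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return data, VolumeGeometry.from_affine(data.shape, img.affine)


def load_mask(path: str | Path) -> BrainMask:
    """Load a binary brain mask from a NIfTI file (nonzero = interior)."""
    data, geom = _read_volume(path)
    return BrainMask(geom, data != 0)


def load_cohort(
    volume_paths: Sequence[str | Path] | None,
    mask_path: str | Path,
    label_table: str | Path,
) -> SubjectMatrix:
    """Read co-registered volumes into a subjects x voxels matrix.

    ``label_table`` is a CSV with columns ``subject_id``, ``path``, ``label``;
    rows of the returned matrix follow the table order.  When
    ``volume_paths`` is None, paths are taken from the table (relative paths
    resolved against the table's directory).  All volumes must share the
    mask's geometry; a mismatch is a hard error naming the offending file.
    """
    table = pd.read_csv(label_table)
    for col in ("subject_id", "path", "label"):
        if col not in table.columns:
            raise ValueError(f"label table is missing required column '{col}'")
    ids = table["subject_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate subject ids in label table: {dupes}")
    if table["label"].isna().any() or (table["label"].astype(str) == "").any():
        raise ValueError("missing label for at least one subject")

    if volume_paths is None:
        base = Path(label_table).parent
        volume_paths = [
            p if Path(p).is_absolute() else base / p for p in table["path"]
        ]
    volume_paths = [Path(p) for p in volume_paths]
    if len(volume_paths) != len(table):
        raise ValueError(
            f"{len(volume_paths)} volumes for {len(table)} labelled subjects: "
            "every subject needs exactly one volume"
        )

    mask = load_mask(mask_path)
    coords = mask.coords()
    inside_flat = np.flatnonzero(mask.inside.ravel(order="F"))

    rows = np.empty((len(volume_paths), len(coords)), dtype=float)
    for i, path in enumerate(volume_paths):
        data, geom = _read_volume(path)
        if not geom.matches(mask.geometry):
            raise ValueError(
                f"volume {path} geometry {geom.shape} does not match the mask"
            )
        row = data.ravel(order="F")[inside_flat]
        if not np.isfinite(row).all():
            raise ValueError(f"volume {path} has non-finite values inside the mask")
        rows[i] = row

    return SubjectMatrix(
        rows,
        coords,
        table["label"].astype(str).to_numpy(),
        ids.to_numpy(),
        mask.geometry,
    )


def whole_brain_normalize(m: SubjectMatrix) -> SubjectMatrix:
    """Divide each subject's row by its own within-mask mean.

    Removes global count differences between scans; every output row has
    mean 1.  Idempotent.  A non-positive row mean indicates a degenerate
    scan and is a hard error.
    """
    means = m.values.mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive within-mask mean for subjects {m.subject_ids[bad].tolist()}"
        )
    return SubjectMatrix(
        m.values / means[:, None], m.coords, m.labels, m.subject_ids, m.geometry
    )


def minmax_scale(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Affinely map each column to [-1, 1] using training extremes only.

    The map sends the training minimum to -1 and maximum to +1 and is
    applied unchanged to ``test`` (test values may fall outside [-1, 1];
    they are not clipped).  Columns constant on the training data map to 0
    everywhere.
    """
    train = np.asarray(train, dtype=float)
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)

    def apply(x: np.ndarray) -> np.ndarray:
        scaled = 2.0 * (x - lo) / safe_span - 1.0
        scaled[:, constant] = 0.0
        return scaled

    scaled_train = apply(train)
    scaled_test = apply(np.asarray(test, dtype=float)) if test is not None else None
    return scaled_train, scaled_test


def write_cluster_map(labeling, geometry: VolumeGeometry, out_path: str | Path) -> Path:
    """Write an integer NIfTI volume with each voxel's cluster id (0 elsewhere).

    ``labeling`` needs ``coords`` (n, 3) and ``cluster_id`` (n,) attributes;
    noise voxels (id 0) stay 0.  Round-trips through :func:`load_cluster_map`.
    """
    coords = np.asarray(labeling.coords, dtype=np.int64)
    ids = np.asarray(labeling.cluster_id, dtype=np.int32)
    vol = np.zeros(geometry.shape, dtype=np.int32)
    if coords.size:
        if (coords < 0).any() or (coords >= np.array(geometry.shape)).any():
            raise ValueError("labeled coordinate outside the volume geometry")
        vol[coords[:, 0], coords[:, 1], coords[:, 2]] = ids
    out_path = Path(out_path)
    nib.save(nib.Nifti1Image(vol, geometry.affine), str(out_path))
    return out_path


def load_cluster_map(path: str | Path):
    """Read a cluster-id volume back into a ClusterLabeling."""
    from .spatial import ClusterLabeling  # local import to avoid a cycle

    data, _ = _read_volume(path)
    data = np.rint(data).astype(np.int64)
    nz = np.flatnonzero((data != 0).ravel(order="F"))
    coords = np.column_stack(np.unravel_index(nz, data.shape, order="F"))
    ids = data[coords[:, 0], coords[:, 1], coords[:, 2]]
    return ClusterLabeling.from_labels(coords, ids)
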