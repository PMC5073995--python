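"""Cluster-level result reporting.

For each retained cluster: size, centroid (voxel and world mm), the
direction of the group effect (increased / decreased signal in the
positive class relative to controls, judged on the cluster-mean signal),
and the smallest per-voxel two-sided Wilcoxon rank-sum p-value inside the
cluster.  A rank test is used because voxel intensities are mostly
non-Gaussian at these sample sizes; the test is isolated in
:func:`_voxel_p` and straightforward to swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .spatial import ClusterLabeling
from .volume_io import SubjectMatrix, VolumeGeometry, _read_volume

__all__ = ["ClusterReportRow", "cluster_report", "attach_atlas_labels", "report_frame"]


@dataclass
class ClusterReportRow:
    cluster_id: int
    n_voxels: int
    centroid_vox: tuple[float, float, float]
    centroid_mm: tuple[float, float, float]
    direction: str
    min_p: float
    atlas_label: str | None = None


def _voxel_p(pos: np.ndarray, ctrl: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p for one voxel's group difference."""
    return float(ranksums(pos, ctrl).pvalue)


def cluster_report(
    m: SubjectMatrix,
    labeling: ClusterLabeling,
    best_voxels: np.ndarray,
    positive_class: str = "positive",
) -> list[ClusterReportRow]:
    """Per-cluster direction, extent, centroid and peak significance.

    ``best_voxels`` are column indices into ``m`` aligned with
    ``labeling.coords`` (the labeling of the selected voxel set, as stored
    on the best iteration's record).  Direction is the sign of
    (positive-class mean - control mean) of the cluster-mean signal.  Rows
    are sorted by cluster size, largest first.
    """
    best_voxels = np.asarray(best_voxels, dtype=np.int64)
    if len(best_voxels) != len(labeling.coords):
        raise ValueError("best_voxels must align with the labeling's coords")
    labels = np.asarray(m.labels).astype(str)
    is_pos = labels == str(positive_class)
    if not is_pos.any() or is_pos.all():
        raise ValueError("both classes required for a direction call")

    rows: list[ClusterReportRow] = []
    for cid in sorted(labeling.sizes):
        members = np.flatnonzero(labeling.cluster_id == cid)
        cols = best_voxels[members]
        cluster_mean = m.values[:, cols].mean(axis=1)
        diff = cluster_mean[is_pos].mean() - cluster_mean[~is_pos].mean()
        direction = "increased" if diff > 0 else "decreased"
        min_p = min(
            _voxel_p(m.values[is_pos, c], m.values[~is_pos, c]) for c in cols
        )
        centroid_vox = labeling.coords[members].mean(axis=0)
        if m.geometry is not None:
            centroid_mm = m.geometry.voxel_to_mm(centroid_vox)[0]
        else:
            centroid_mm = np.full(3, np.nan)
        rows.append(
            ClusterReportRow(
                cluster_id=int(cid),
                n_voxels=len(members),
                centroid_vox=tuple(float(x) for x in centroid_vox),
                centroid_mm=tuple(float(x) for x in centroid_mm),
                direction=direction,
                min_p=float(min_p),
            )
        )
    rows.sort(key=lambda r: (-r.n_voxels, r.cluster_id))
    return rows


def attach_atlas_labels(
    rows: list[ClusterReportRow],
    atlas_volume: str,
    atlas_names: str,
    geometry: VolumeGeometry | None = None,
) -> list[ClusterReportRow]:
    """Name each cluster by the atlas region containing its centroid voxel.

    ``atlas_volume`` is an integer-valued NIfTI parcellation on the same
    grid as the data; ``atlas_names`` a CSV with columns ``index`` and
    ``name``.  Centroids falling on atlas value 0 (or outside every listed
    region) are labelled "unlabeled".
    """
    data, atlas_geom = _read_volume(atlas_volume)
    if geometry is not None and not atlas_geom.matches(geometry):
        raise ValueError("atlas geometry does not match the data grid")
    names = pd.read_csv(atlas_names)
    for col in ("index", "name"):
        if col not in names.columns:
            raise ValueError(f"atlas names table is missing column '{col}'")
    lookup = dict(zip(names["index"].astype(int), names["name"].astype(str)))
    data = np.rint(data).astype(int)
    for row in rows:
        vox = tuple(int(round(c)) for c in row.centroid_vox)
        if all(0 <= v < s for v, s in zip(vox, data.shape)):
            row.atlas_label = lookup.get(int(data[vox]), "unlabeled")
        else:
            row.atlas_label = "unlabeled"
    return rows


def report_frame(rows: list[ClusterReportRow]) -> pd.DataFrame:
    """Tabular view of a cluster report (one row per cluster)."""
    return pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in rows],
            "n_voxels": [r.n_voxels for r in rows],
            "centroid_x_vox": [r.centroid_vox[0] for r in rows],
            "centroid_y_vox": [r.centroid_vox[1] for r in rows],
            "centroid_z_vox": [r.centroid_vox[2] for r in rows],
            "centroid_x_mm": [r.centroid_mm[0] for r in rows],
            "centroid_y_mm": [r.centroid_mm[1] for r in rows],
            "centroid_z_mm": [r.centroid_mm[2] for r in rows],
            "direction": [r.direction for r in rows],
            "min_p": [r.min_p for r in rows],
            "atlas_label": [r.atlas_label for r in rows],
        }
    )
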