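"""Post-beamforming source-cluster extraction.

Given voxelwise source-power and noise estimates, the Neural Activity Index
(NAI) is the per-voxel ratio of power to local noise.  The top percentile
of the (optionally atlas-masked) NAI distribution defines the
suprathreshold voxels, which DBSCAN groups into activity clusters: with
eps = 1.5 x grid spacing, face- and edge-adjacent voxels connect while
corner neighbours do not, and clusters need at least five voxels.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import DBSCAN

from .containers import SourceVolume, ValidationError, VoxelClusterSet


def compute_nai(power: SourceVolume, noise: SourceVolume) -> SourceVolume:
    """Voxelwise power / noise ratio (invariant to common rescaling)."""
    if power.dims != noise.dims:
        raise ValidationError(f"grid mismatch: power {power.dims} vs noise {noise.dims}")
    if np.any(noise.values <= 0):
        raise ValidationError("noise volume contains non-positive voxels; NAI undefined")
    return SourceVolume(
        values=power.values / noise.values,
        spacing=power.spacing,
        mask=power.mask,
    )


def top_percent_threshold(
    volume: SourceVolume,
    percent: float = 1.0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Voxels in the top ``percent`` of the (masked) value distribution.

    The threshold is the (100 - percent) linear-interpolation percentile of
    the masked values; voxels with value >= threshold are returned, so ties
    at the threshold are all included.  Returns ((K, 3) ijk indices sorted
    by voxel index, threshold).
    """
    if not 0 < percent <= 100:
        raise ValidationError("percent must lie in (0, 100]")
    if mask is None:
        mask = volume.mask if volume.mask is not None else np.ones(volume.dims, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.dims:
        raise ValidationError("mask shape must match the volume")
    n_masked = int(mask.sum())
    if n_masked == 0:
        raise ValidationError("mask selects no voxels")
    if n_masked < 100.0 / percent:
        raise ValidationError(
            f"mask selects {n_masked} voxels < 100/percent = {100.0 / percent:.0f}"
        )
    vals = volume.values[mask]
    threshold = float(np.percentile(vals, 100.0 - percent))
    if np.all(vals == vals[0]):
        warnings.warn("all masked voxels share one value; tie rule returns every voxel", stacklevel=2)
    keep = mask & (volume.values >= threshold)
    idx = np.argwhere(keep)
    return idx, threshold


def dbscan_clusters(
    voxel_indices: np.ndarray,
    spacing: float,
    eps: float | None = None,
    min_pts: int = 5,
    threshold: float | None = None,
) -> VoxelClusterSet:
    """Density clustering of suprathreshold voxels (Euclidean metric).

    Groups adjacent voxels — eps-connected components of the voxel-centre
    graph — and keeps components with at least ``min_pts`` voxels as
    clusters; smaller components and isolated voxels are noise.  With the
    default eps = 1.5 x grid spacing, face and edge neighbours connect
    while corner neighbours at sqrt(3) x spacing do not.  ``min_pts`` acts
    as the minimum cluster size (so a straight line of five adjacent
    voxels is a cluster), which on grid data also removes the classic
    DBSCAN border-point ambiguity: cluster membership is invariant to
    voxel input order.  Voxels are additionally pre-sorted by ijk index so
    the cluster numbering is deterministic.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if eps is None:
        eps = 1.5 * spacing
    voxel_indices = np.asarray(voxel_indices, dtype=int).reshape(-1, 3)
    if voxel_indices.shape[0] == 0:
        return VoxelClusterSet(clusters=[], noise=np.empty((0, 3), dtype=int),
                               eps=eps, min_pts=min_pts, threshold=threshold)
    order = np.lexsort((voxel_indices[:, 2], voxel_indices[:, 1], voxel_indices[:, 0]))
    vox = voxel_indices[order]
    coords = vox.astype(float) * spacing
    # min_samples=2: every voxel with a neighbour is core, so components of
    # the eps-graph come out whole; the size filter below applies min_pts
    labels = DBSCAN(eps=eps, min_samples=2, metric="euclidean").fit_predict(coords)
    clusters = []
    noise_parts = [vox[labels == -1]]
    for lab in sorted(set(labels) - {-1}):
        members = vox[labels == lab]
        if members.shape[0] >= min_pts:
            clusters.append(members)
        else:
            noise_parts.append(members)
    noise = np.vstack(noise_parts) if noise_parts else np.empty((0, 3), dtype=int)
    return VoxelClusterSet(clusters=clusters, noise=noise, eps=eps,
                           min_pts=min_pts, threshold=threshold)


def extract_clusters(
    nai: SourceVolume,
    percent: float = 1.0,
    mask: np.ndarray | None = None,
    eps: float | None = None,
    min_pts: int = 5,
) -> VoxelClusterSet:
    """Threshold an NAI volume at its top percentile and cluster the result."""
    idx, threshold = top_percent_threshold(nai, percent=percent, mask=mask)
    return dbscan_clusters(idx, spacing=nai.spacing, eps=eps, min_pts=min_pts,
                           threshold=threshold)
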