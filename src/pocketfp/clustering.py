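"""Ligand-pose clustering and representative-frame selection.

Frames are subsampled with a stride (default 10), aligned to the
reference frame on protein C-alpha atoms, and the pairwise RMSD matrix
of the ligand heavy atoms (no per-pair refit) is clustered by
average-linkage hierarchical clustering cut at a distance threshold.
The representative complex — the pose most often detected in the
analysed frames — is the medoid of the largest cluster: the member
frame with the minimum summed RMSD to all other members.  All ties are
broken toward the lowest frame index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structure_io import Trajectory
from .traj_stats import kabsch_superpose

__all__ = ["ClusterResult", "cluster_ligand_poses", "pairwise_pose_rmsd"]


@dataclass
class ClusterResult:
    frame_indices_analyzed: np.ndarray   # original frame numbers, after stride
    labels: np.ndarray                   # cluster id per analysed frame (1-based)
    cluster_sizes: dict[int, int]
    representative_frame: int            # original frame number
    cutoff: float
    stride: int

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def largest_cluster(self) -> int:
        # largest size; ties -> cluster containing the earliest frame
        best = None
        for lab, size in self.cluster_sizes.items():
            first = int(self.frame_indices_analyzed[self.labels == lab].min())
            key = (-size, first)
            if best is None or key < best[0]:
                best = (key, lab)
        return best[1]


def pairwise_pose_rmsd(
    traj: Trajectory,
    ligand_selection: np.ndarray,
    alignment_selection: np.ndarray,
    frame_indices: np.ndarray,
    reference_frame: int = 0,
) -> np.ndarray:
    """Condensed-form-friendly square matrix of ligand RMSD between all
    analysed frame pairs, after per-frame protein alignment to the
    reference frame (no per-pair refit)."""
    ref = traj.frames[reference_frame][alignment_selection]
    n_lig = len(ligand_selection)
    poses = np.empty((len(frame_indices), n_lig, 3))
    for k, fi in enumerate(frame_indices):
        R, t, _ = kabsch_superpose(traj.frames[fi][alignment_selection], ref)
        poses[k] = traj.frames[fi][ligand_selection] @ R.T + t
    flat = poses.reshape(len(frame_indices), -1)
    sq = np.sum(flat * flat, axis=1)
    g = flat @ flat.T
    d2 = (sq[:, None] + sq[None, :] - 2.0 * g) / n_lig
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.clip(d2, 0.0, None))


def cluster_ligand_poses(
    traj: Trajectory,
    stride: int = 10,
    cutoff: float = 2.0,
    ligand_selection: Optional[Sequence[int]] = None,
    alignment_selection: Optional[Sequence[int]] = None,
    method: str = "average",
) -> ClusterResult:
    """Cluster ligand poses over every ``stride``-th frame and pick the
    representative complex.

    A 5000-frame trajectory at the default stride of 10 analyses 500
    frames.  ``cutoff`` is the linkage distance threshold in Å.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride >= traj.n_frames:
        raise ValueError(
            f"stride {stride} leaves fewer than 2 of {traj.n_frames} frames"
        )
    frame_idx = np.arange(0, traj.n_frames, stride)
    if frame_idx.size < 2:
        raise ValueError("need at least 2 analysed frames after stride")

    if ligand_selection is None:
        lig = traj.topology.indices_where(
            lambda a: a.is_ligand and a.element.upper() not in ("H", "D")
        )
    else:
        lig = np.asarray(ligand_selection, dtype=int)
    if lig.size == 0:
        raise ValueError("empty ligand selection")
    if alignment_selection is None:
        align = traj.topology.calpha_indices
        if align.size == 0:
            align = traj.topology.protein_indices
        if align.size == 0:
            align = lig
    else:
        align = np.asarray(alignment_selection, dtype=int)

    dm = pairwise_pose_rmsd(traj, lig, align, frame_idx)
    z = linkage(squareform(dm, checks=False), method=method)
    labels = fcluster(z, t=cutoff, criterion="distance")

    sizes = {int(lab): int((labels == lab).sum()) for lab in np.unique(labels)}
    result = ClusterResult(
        frame_indices_analyzed=frame_idx, labels=labels,
        cluster_sizes=sizes, representative_frame=-1,
        cutoff=cutoff, stride=stride,
    )
    big = result.largest_cluster
    members = np.where(labels == big)[0]
    sub = dm[np.ix_(members, members)]
    summed = sub.sum(axis=1)
    # medoid; ties -> lowest original frame index (frame_idx is ascending)
    best = members[int(np.argmin(summed))]
    ties = members[np.isclose(summed, summed.min(), rtol=0, atol=1e-12)]
    best = int(ties.min())
    result.representative_frame = int(frame_idx[best])
    return result
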