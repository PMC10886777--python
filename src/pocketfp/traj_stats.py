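"""Superposition-based trajectory statistics: RMSD time series and
per-residue RMSF profiles.

Superposition uses the Kabsch algorithm (SVD of the cross-covariance
with a determinant correction, so reflections are excluded).  RMSD
series align every frame to the reference frame on an alignment
selection (protein C-alpha by default) and then measure RMSD over the
analysis selection without a second fit — so the ligand series measures
drift of the ligand in the pocket, i.e. ligand equilibration relative
to the protein.  RMSF is the root-mean-square fluctuation of each atom
about its mean position after the same alignment, reported per residue
at the C-alpha atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structure_io import Structure, Trajectory

__all__ = [
    "DegenerateGeometryError",
    "RMSDSeries",
    "RMSFProfile",
    "kabsch_superpose",
    "rmsd",
    "rmsd_series",
    "rmsf_profile",
]


class DegenerateGeometryError(ValueError):
    """Fewer than 3 points, or a (near-)collinear set: the optimal
    rotation is not uniquely defined."""


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equally sized point sets (Å)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``reference`` in the (weighted) least-squares sense.  ``R`` is a
    proper rotation (det +1); reflections are never returned.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    m0 = mobile - mc
    r0 = reference - rc

    # collinearity check on the reference spread
    s_ref = np.linalg.svd(r0 * np.sqrt(w)[:, None], compute_uv=False)
    if s_ref[1] < 1e-8 * max(s_ref[0], 1.0):
        raise DegenerateGeometryError("points are (near-)collinear")

    H = (w[:, None] * m0).T @ r0          # cross-covariance
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc

    fitted = m0 @ R.T
    res = float(np.sqrt(np.sum(w * np.sum((fitted - r0) ** 2, axis=1))))
    return R, t, res


@dataclass
class RMSDSeries:
    values: np.ndarray                 # Å, one per frame
    reference_frame: int
    selection: np.ndarray              # atom indices measured
    alignment_selection: np.ndarray    # atom indices fitted
    dt_ns: float = 0.02

    def times_ns(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt_ns


@dataclass
class RMSFProfile:
    per_residue: dict[tuple[str, int], float]   # (chain, resseq) -> Å at CA
    per_atom: np.ndarray                        # Å for every atom in basis
    atom_indices: np.ndarray
    atom_basis: str = "CA"


def _aligned_frames(
    traj: Trajectory,
    alignment_selection: np.ndarray,
    reference_frame: int,
) -> np.ndarray:
    """All frames rigid-fitted to the reference frame on the alignment
    selection; returns a full-coordinates copy."""
    ref = traj.frames[reference_frame][alignment_selection]
    out = np.empty_like(traj.frames)
    for fi in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.frames[fi][alignment_selection], ref)
        out[fi] = traj.frames[fi] @ R.T + t
    return out


def rmsd_series(
    traj: Trajectory,
    selection: Sequence[int],
    alignment_selection: Optional[Sequence[int]] = None,
    reference_frame: int = 0,
) -> RMSDSeries:
    """Per-frame RMSD of ``selection`` vs. the reference frame after
    aligning each frame on ``alignment_selection`` (defaults to protein
    C-alpha; falls back to ``selection`` itself if none exist).

    Protein mode: selection == alignment selection.  Ligand mode:
    selection = ligand heavy atoms, alignment = protein C-alpha, and no
    second fit is performed.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    if alignment_selection is None:
        align = traj.topology.calpha_indices
        if align.size == 0:
            align = sel
    else:
        align = np.asarray(alignment_selection, dtype=int)
    if align.size == 0:
        raise ValueError("empty alignment selection")

    aligned = _aligned_frames(traj, align, reference_frame)
    ref_sel = traj.frames[reference_frame][sel]
    values = np.array([rmsd(aligned[fi][sel], ref_sel)
                       for fi in range(traj.n_frames)])
    if set(sel.tolist()) <= set(align.tolist()):
        values[reference_frame] = 0.0  # exact by definition

    return RMSDSeries(
        values=values, reference_frame=reference_frame, selection=sel,
        alignment_selection=align, dt_ns=traj.dt_ns,
    )


def rmsf_profile(
    traj: Trajectory,
    alignment_selection: Optional[Sequence[int]] = None,
    reference: str = "frame0",
    atom_basis: str = "CA",
) -> RMSFProfile:
    """Per-atom RMSF about the mean structure after alignment, reported
    per residue at C-alpha (``atom_basis='all'`` reports every atom's
    residue entry as the mean over its atoms).

    ``reference`` is ``'frame0'`` (default) or ``'mean'`` (two-pass:
    align to frame 0, rebuild the mean, realign to it).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if alignment_selection is None:
        align = traj.topology.calpha_indices
        if align.size == 0:
            align = np.arange(traj.n_atoms)
    else:
        align = np.asarray(alignment_selection, dtype=int)
    aligned = _aligned_frames(traj, align, 0)
    if reference == "mean":
        mean_align = aligned.mean(axis=0)[align]
        ref = traj.frames[0].copy()
        ref[align] = mean_align
        tmp = Trajectory(traj.topology, aligned, dt_ns=traj.dt_ns)
        tmp.frames[0] = ref  # realign against the mean positions
        aligned = _aligned_frames(tmp, align, 0)
    elif reference != "frame0":
        raise ValueError("reference must be 'frame0' or 'mean'")

    mean = aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))

    topo: Structure = traj.topology
    if atom_basis == "CA":
        basis_idx = topo.calpha_indices
        per_res = {
            (topo.atoms[i].chain, topo.atoms[i].resseq): float(fluct[i])
            for i in basis_idx
        }
    elif atom_basis == "all":
        basis_idx = np.arange(traj.n_atoms)
        sums: dict[tuple, list] = {}
        for i in basis_idx:
            a = topo.atoms[i]
            sums.setdefault((a.chain, a.resseq), []).append(fluct[i])
        per_res = {k: float(np.mean(v)) for k, v in sums.items()}
    else:
        raise ValueError("atom_basis must be 'CA' or 'all'")
    return RMSFProfile(
        per_residue=per_res, per_atom=fluct[basis_idx],
        atom_indices=basis_idx, atom_basis=atom_basis,
    )
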