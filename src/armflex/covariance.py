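"""PCA of C-alpha displacement covariance, mode/PC overlap, and DCCM maps."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .structio import AtomSelection, StructureModel, Trajectory, TopologyError, fit_frames

__all__ = [
    "PcaResult",
    "CorrelationMap",
    "compute_pca",
    "mode_overlap",
    "dccm",
    "merge_ensemble",
]


@dataclasses.dataclass
class PcaResult:
    """Eigenpairs of the 3N x 3N displacement covariance, descending variance.

    PC numbering is 1-based: PC1 carries the largest variance.
    """

    eigenvalues: np.ndarray  # descending, length 3N
    components: np.ndarray  # (3N, 3N) columns, descending variance
    mean: np.ndarray  # (N, 3) fitted ensemble mean
    atom_indices: np.ndarray

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def explained_ratio(self, pc: int) -> float:
        return float(self.eigenvalues[pc - 1] / self.total_variance)

    def vector(self, pc: int) -> np.ndarray:
        return self.components[:, pc - 1]


def compute_pca(traj: Trajectory, sel: AtomSelection | None = None) -> PcaResult:
    """PCA of the displacement covariance after fitting frames to their mean."""
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = sel.indices if sel is not None else np.arange(traj.n_atoms)
    fitted, mean = fit_frames(traj.frames, idx)
    disp = (fitted[:, idx] - mean[idx]).reshape(traj.n_frames, -1)
    cov = disp.T @ disp / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return PcaResult(
        eigenvalues=np.maximum(evals[order], 0.0),
        components=evecs[:, order],
        mean=mean[idx],
        atom_indices=np.asarray(idx),
    )


def mode_overlap(v: np.ndarray, w: np.ndarray) -> float:
    """|cos| of the angle between two 3N-vectors — subspace overlap in [0, 1]."""
    v = np.asarray(v, float).ravel()
    w = np.asarray(w, float).ravel()
    if v.shape != w.shape:
        raise ValueError("vectors differ in dimension")
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("zero vector")
    return float(abs(v @ w) / (nv * nw))


@dataclasses.dataclass
class CorrelationMap:
    matrix: np.ndarray  # (n, n), symmetric, diagonal 1, entries in [-1, 1]
    labels: list  # residue labels for both axes
    zero_variance: np.ndarray  # bool mask of flagged static atoms

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("correlation map must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")
        if np.any(m > 1 + 1e-9) or np.any(m < -1 - 1e-9):
            raise ValueError("entries must lie in [-1, 1]")


def dccm(traj: Trajectory, sel: AtomSelection | None = None, zero_var_tol: float = 1e-12) -> CorrelationMap:
    """Normalized cross-correlations C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>).

    One row/column per selected atom (per residue for a C-alpha selection);
    atoms with displacement variance below tolerance are flagged and their
    off-diagonal entries set to 0.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    idx = sel.indices if sel is not None else np.arange(traj.n_atoms)
    fitted, mean = fit_frames(traj.frames, idx)
    disp = fitted[:, idx] - mean[idx]  # (T, n, 3)
    inner = np.einsum("tik,tjk->ij", disp, disp) / traj.n_frames
    var = np.diag(inner).copy()
    dead = var < zero_var_tol
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} atoms with ~zero variance; rows zeroed")
    denom = np.sqrt(np.outer(np.where(dead, 1.0, var), np.where(dead, 1.0, var)))
    C = inner / denom
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    labels = [
        f"{traj.topology.chain_ids[i]}:{int(traj.topology.residue_numbers[i])}" for i in idx
    ]
    cmap = CorrelationMap(matrix=C, labels=labels, zero_variance=dead)
    cmap.validate()
    return cmap


def _as_frames(item) -> tuple[StructureModel, np.ndarray, str]:
    from .enm import DisplacementSeries

    if isinstance(item, Trajectory):
        return item.topology, item.frames, item.source_id
    if isinstance(item, DisplacementSeries):
        return item.topology, item.coords, f"mode{item.mode_id}"
    raise TypeError(f"cannot merge object of type {type(item).__name__}")


def merge_ensemble(items: list) -> Trajectory:
    """Concatenate trajectories and/or displacement series into one
    pseudo-trajectory, recording the source of every frame."""
    if not items:
        raise ValueError("nothing to merge")
    top0, frames0, src0 = _as_frames(items[0])
    all_frames = [frames0]
    sources = [src0] * len(frames0)
    for item in items[1:]:
        top, frames, src = _as_frames(item)
        if top.n_atoms != top0.n_atoms or not np.array_equal(top.atom_names, top0.atom_names):
            raise TopologyError("merged inputs must share a topology")
        all_frames.append(frames)
        sources.extend([src] * len(frames))
    merged = np.concatenate(all_frames, axis=0)
    traj = Trajectory(
        topology=top0,
        frames=merged,
        times=np.arange(len(merged), dtype=float),
        source_id="merged",
    )
    traj.frame_sources = np.array(sources, dtype=object)
    return traj
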