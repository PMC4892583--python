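"""Reference-structure clustering of merged trajectories.

The procedure: merge all trajectories; repeatedly sample a random remaining
frame as a reference and remove every frame within the RMSD cutoff of it
(including the sample itself); once no frames remain, assign every original
frame to its nearest reference and tabulate per-trajectory cluster
frequencies.  Equal representation of every reference across independent
runs is the convergence diagnostic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .structio import (
    AtomSelection,
    StructureModel,
    TopologyError,
    Trajectory,
    rmsd_to_reference,
)

__all__ = ["ClusterParams", "ClusterResult", "lz_cluster", "convergence_table"]


@dataclasses.dataclass
class ClusterParams:
    d_cutoff: float = 2.5  # Angstrom
    selection: str | None = "ca"
    fit_before_rmsd: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_cutoff <= 0:
            raise ValueError("d_cutoff must be > 0")


@dataclasses.dataclass
class ClusterResult:
    references: list  # (source_id, frame index within source, StructureModel)
    assignment: np.ndarray  # merged frame -> reference index
    frame_sources: np.ndarray  # source_id per merged frame
    frequencies: pd.DataFrame  # rows: source_id, columns: reference index

    @property
    def n_references(self) -> int:
        return len(self.references)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_references)


def _merged(trajs: list[Trajectory]) -> tuple[StructureModel, np.ndarray, np.ndarray, np.ndarray]:
    top = trajs[0].topology
    for t in trajs[1:]:
        if t.topology.n_atoms != top.n_atoms or not np.array_equal(t.topology.atom_names, top.atom_names):
            raise TopologyError("all trajectories must share a topology")
    frames = np.concatenate([t.frames for t in trajs], axis=0)
    sources = np.concatenate([np.full(t.n_frames, t.source_id, dtype=object) for t in trajs])
    local = np.concatenate([np.arange(t.n_frames) for t in trajs])
    return top, frames, sources, local


def lz_cluster(trajs: list[Trajectory], params: ClusterParams | None = None) -> ClusterResult:
    """Cluster merged trajectories against randomly sampled reference frames."""
    if not trajs:
        raise ValueError("need at least one trajectory")
    params = params or ClusterParams()
    top, frames, sources, local = _merged(trajs)
    sel = AtomSelection.from_string(top, params.selection) if params.selection else None
    idx = sel.indices if sel is not None else np.arange(top.n_atoms)
    coords = frames[:, idx]

    rng = np.random.default_rng(params.seed)
    remaining = np.arange(len(frames))
    ref_frames: list[int] = []
    while len(remaining):
        pick = remaining[rng.integers(len(remaining))]
        ref_frames.append(int(pick))
        d = rmsd_to_reference(coords[remaining], coords[pick], fit=params.fit_before_rmsd)
        remaining = remaining[d > params.d_cutoff]

    # nearest-reference assignment; ties resolve to the lowest reference index
    dists = np.stack(
        [rmsd_to_reference(coords, coords[r], fit=params.fit_before_rmsd) for r in ref_frames],
        axis=1,
    )
    assignment = np.argmin(dists, axis=1)

    references = [
        (sources[r], int(local[r]), top.copy(coords=frames[r])) for r in ref_frames
    ]
    source_ids = [t.source_id for t in trajs]
    freq = pd.DataFrame(
        0.0, index=source_ids, columns=list(range(len(ref_frames)))
    )
    for sid in source_ids:
        mask = sources == sid
        counts = np.bincount(assignment[mask], minlength=len(ref_frames))
        freq.loc[sid] = counts / mask.sum()
    return ClusterResult(
        references=references,
        assignment=assignment,
        frame_sources=sources,
        frequencies=freq,
    )


def convergence_table(result: ClusterResult) -> tuple[pd.DataFrame, float]:
    """Per-trajectory reference frequencies and the maximum frequency spread.

    Spread = max over references of (max - min frequency across sources);
    with a single source the spread is undefined (NaN, with a warning).
    """
    table = result.frequencies
    if len(table) < 2:
        warnings.warn("convergence spread undefined with a single trajectory")
        return table, float("nan")
    spread = float((table.max(axis=0) - table.min(axis=0)).max())
    return table, spread
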