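"""C-alpha elastic network: Hessian, normal modes, collectivity, displacement.

Eigenvalues are in arbitrary units (gamma-scaled).  Mode numbering is
1-based with modes 1-6 the rigid-body modes of a connected network; the
first internal mode is therefore mode 7.

The restraint energy reported for displaced conformations is the harmonic
network strain energy per unit total mass, so a pure-mode displacement of a
mass-weighted network to MRMS s costs exactly 0.5 * lambda * s**2.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .structio import StructureModel

__all__ = [
    "EnmParams",
    "ModeSet",
    "DisplacementSeries",
    "DisconnectedNetworkWarning",
    "build_hessian",
    "network_components",
    "compute_modes",
    "collectivity",
    "displace_along_mode",
    "restraint_energy_map",
]


class DisconnectedNetworkWarning(UserWarning):
    pass


@dataclasses.dataclass
class EnmParams:
    cutoff: float = 10.0  # Angstrom spring-inclusion radius
    gamma: float = 1.0  # spring constant, arbitrary energy/A^2
    mass_weighting: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def network_components(structure: StructureModel, cutoff: float) -> int:
    """Number of connected components of the spring network."""
    d = squareform(pdist(structure.coords))
    adj = (d <= cutoff) & (d > 0)
    n, _ = connected_components(adj, directed=False)
    return int(n)


def build_hessian(structure: StructureModel, params: EnmParams | None = None) -> np.ndarray:
    """Anisotropic-network Hessian (3N x 3N), mass-weighted if requested.

    Off-diagonal superblock for a connected pair (i, j) is
    -gamma * rhat rhat^T; diagonal superblocks enforce zero block-row sums.
    A disconnected network triggers a warning carrying the component count.
    """
    params = params or EnmParams()
    if structure.n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    x = structure.coords
    n = len(x)
    d = squareform(pdist(x))
    H = np.zeros((3 * n, 3 * n))
    ii, jj = np.where((d <= params.cutoff) & (d > 0))
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        r = x[j] - x[i]
        rhat = r / np.linalg.norm(r)
        block = -params.gamma * np.outer(rhat, rhat)
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    ncomp = network_components(structure, params.cutoff)
    if ncomp > 1:
        warnings.warn(
            f"spring network has {ncomp} connected components "
            f"({6 * ncomp} zero modes expected)",
            DisconnectedNetworkWarning,
        )
    if params.mass_weighting:
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(structure.masses), 3)
        H = H * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    return H


@dataclasses.dataclass
class ModeSet:
    """Eigenpairs of a vibrational analysis, ascending, 1-based numbering."""

    eigenvalues: np.ndarray  # full spectrum, ascending
    eigenvectors: np.ndarray  # (3N, k) columns for the k retained modes
    n_requested: int
    rigid: np.ndarray  # bool per retained mode
    collectivity: np.ndarray  # NaN for rigid modes
    masses: np.ndarray | None = None  # per-atom masses if mass-weighted

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.eigenvectors.shape[0] // 3

    def eigenvalue(self, mode_id: int) -> float:
        return float(self.eigenvalues[mode_id - 1])

    def vector(self, mode_id: int) -> np.ndarray:
        return self.eigenvectors[:, mode_id - 1]

    def is_rigid(self, mode_id: int) -> bool:
        return bool(self.rigid[mode_id - 1])


def collectivity(vector: np.ndarray, n_atoms: int | None = None) -> float:
    """Entropy-based degree of collectivity in (0, 1].

    kappa = exp(-sum alpha*u_i^2 * log(alpha*u_i^2)) / N with alpha chosen
    so the squared per-atom displacement magnitudes u_i^2 sum to 1; terms
    with u_i^2 = 0 contribute nothing.
    """
    v = np.asarray(vector, float).ravel()
    if v.size % 3 != 0:
        raise ValueError("vector length must be 3N")
    if n_atoms is None:
        n_atoms = v.size // 3
    u2 = np.sum(v.reshape(-1, 3) ** 2, axis=1)
    total = u2.sum()
    if total <= 0:
        raise ValueError("zero displacement vector")
    p = u2 / total
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return float(np.exp(entropy) / n_atoms)


def compute_modes(
    hessian: np.ndarray,
    n_requested: int = 87,
    masses: np.ndarray | None = None,
    zero_tol_factor: float = 1e-8,
) -> ModeSet:
    """Diagonalize and retain the lowest n_requested + 6 modes.

    Rigid modes are those with eigenvalue below zero_tol_factor times the
    largest eigenvalue; for a connected network there are exactly six.
    """
    H = np.asarray(hessian, float)
    if H.ndim != 2 or H.shape[0] != H.shape[1] or H.shape[0] % 3 != 0:
        raise ValueError("hessian must be 3N x 3N")
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("hessian must be symmetric")
    n3 = H.shape[0]
    keep = n_requested + 6
    if keep > n3:
        raise ValueError(f"requested {n_requested}+6 modes but only {n3} exist")
    evals, evecs = np.linalg.eigh(H)
    tol = zero_tol_factor * max(evals[-1], 0.0)
    rigid = evals[:keep] < max(tol, 1e-12)
    kappa = np.full(keep, np.nan)
    for k in range(keep):
        if not rigid[k]:
            kappa[k] = collectivity(evecs[:, k])
    return ModeSet(
        eigenvalues=evals,
        eigenvectors=evecs[:, :keep],
        n_requested=n_requested,
        rigid=rigid,
        collectivity=kappa,
        masses=masses,
    )


@dataclasses.dataclass
class DisplacementSeries:
    mode_id: int
    mrms_grid: np.ndarray  # Angstrom, symmetric about 0
    coords: np.ndarray  # (n_grid, n_atoms, 3)
    restraint_energy: np.ndarray  # per grid point, >= 0, arbitrary units
    topology: StructureModel
    unfavorable: np.ndarray | None = None  # set by restraint_energy_map

    @property
    def n_structures(self) -> int:
        return len(self.mrms_grid)

    def structure(self, k: int) -> StructureModel:
        return self.topology.copy(coords=self.coords[k])


def _mode_cartesian_direction(modes: ModeSet, mode_id: int) -> np.ndarray:
    """Cartesian displacement (n_atoms, 3) with unit MRMS for the mode."""
    w = modes.vector(mode_id)
    n = modes.n_atoms
    if modes.masses is not None:
        m = np.asarray(modes.masses, float)
        dx = (w.reshape(n, 3) / np.sqrt(m)[:, None]) * np.sqrt(m.sum())
    else:
        dx = w.reshape(n, 3) * np.sqrt(n)
    return dx


def displace_along_mode(
    structure: StructureModel,
    modes: ModeSet,
    mode_id: int,
    max_range: float = 3.0,
    step: float = 0.1,
) -> DisplacementSeries:
    """Generate conformations along one mode on a symmetric MRMS grid.

    The grid spans -max_range..+max_range inclusive, giving
    2*(max_range/step) + 1 structures (61 at the 3.0/0.1 defaults); the
    structure at MRMS 0 is the input.
    """
    if step <= 0 or step > max_range:
        raise ValueError("need 0 < step <= max_range")
    if modes.is_rigid(mode_id):
        raise ValueError(f"mode {mode_id} is a rigid-body mode")
    k = int(round(max_range / step))
    grid = step * np.arange(-k, k + 1)
    unit = _mode_cartesian_direction(modes, mode_id)
    lam = modes.eigenvalue(mode_id)
    coords = structure.coords[None, :, :] + grid[:, None, None] * unit[None, :, :]
    energy = 0.5 * lam * grid**2
    return DisplacementSeries(
        mode_id=mode_id,
        mrms_grid=grid,
        coords=coords,
        restraint_energy=energy,
        topology=structure,
    )


def restraint_energy_map(
    modes: ModeSet,
    structure: StructureModel,
    mode_ids: list[int] | None = None,
    max_range: float = 3.0,
    step: float = 0.1,
    unfavorable_percentile: float = 90.0,
) -> tuple[np.ndarray, np.ndarray, list[int], np.ndarray]:
    """Restraint-energy heat map over modes x MRMS grid.

    Returns (energy matrix, grid, mode_ids, unfavorable mask) where the mask
    flags entries above the given percentile of the whole map — the screen
    for discarding unfavorable conformations.
    """
    if mode_ids is None:
        mode_ids = [i for i in range(1, modes.n_modes + 1) if not modes.is_rigid(i)]
    if not mode_ids:
        raise ValueError("need at least one non-rigid mode")
    series = [displace_along_mode(structure, modes, m, max_range, step) for m in mode_ids]
    grid = series[0].mrms_grid
    energy = np.vstack([s.restraint_energy for s in series])
    threshold = np.percentile(energy, unfavorable_percentile)
    unfavorable = energy > threshold
    return energy, grid, mode_ids, unfavorable
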