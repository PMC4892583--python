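import numpy as np
import pytest

from armflex.enm import EnmParams, build_hessian, compute_modes
from armflex.structio import StructureModel, Trajectory
from armflex.synthetic import SolenoidSpec, build_solenoid


@pytest.fixture(scope="session")
def solenoid_spec():
    return SolenoidSpec()


@pytest.fixture(scope="session")
def solenoid(solenoid_spec):
    return build_solenoid(solenoid_spec)


@pytest.fixture(scope="session")
def solenoid_structure(solenoid):
    return solenoid[0]


@pytest.fixture(scope="session")
def solenoid_annotation(solenoid):
    return solenoid[1]


@pytest.fixture(scope="session")
def solenoid_modes(solenoid_structure):
    H = build_hessian(solenoid_structure, EnmParams())
    return compute_modes(H, n_requested=87, masses=solenoid_structure.masses)


def make_structure(coords, names=None, resnums=None, chains=None, elements=None, masses=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    return StructureModel(
        serials=np.arange(1, n + 1),
        atom_names=np.array(names if names is not None else ["CA"] * n, dtype=object),
        residue_names=np.array(["ALA"] * n, dtype=object),
        residue_numbers=np.array(resnums if resnums is not None else np.arange(1, n + 1)),
        chain_ids=np.array(chains if chains is not None else ["A"] * n, dtype=object),
        elements=np.array(elements if elements is not None else ["C"] * n, dtype=object),
        coords=coords,
        masses=np.array(masses if masses is not None else [12.011] * n, dtype=float),
    )


def make_trajectory(topology, frames, source_id="traj"):
    frames = np.asarray(frames, float)
    return Trajectory(
        topology=topology,
        frames=frames,
        times=np.arange(len(frames), dtype=float),
        source_id=source_id,
    )


def rigid_free_direction(base, pattern):
    """Project the 6 rigid-body motions out of a displacement pattern so a
    trajectory driven along it is untouched by mean-fitting."""
    base = np.asarray(base, float)
    n = len(base)
    centered = base - base.mean(axis=0)
    basis = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = 1.0
        basis.append(v.ravel())
    for k in range(3):
        omega = np.zeros(3)
        omega[k] = 1.0
        basis.append(np.cross(omega, centered).ravel())
    Q, _ = np.linalg.qr(np.array(basis).T)
    u = np.asarray(pattern, float).ravel()
    u = u - Q @ (Q.T @ u)
    return (u / np.linalg.norm(u)).reshape(n, 3)


def z_phase_pattern(base, weights_012=(1.0, 1.0, -1.0)):
    """All-z displacement pattern with the given weights on atoms 0-2 and
    compensating z-weights on atoms 3-5 chosen so the pattern has no net
    translation and no overlap with infinitesimal rotations (the mean fit
    then leaves a trajectory driven along it untouched)."""
    base = np.asarray(base, float)
    assert len(base) >= 6
    centered = base - base.mean(axis=0)
    w = np.zeros(len(base))
    w[:3] = weights_012
    # constraints: sum(w) = 0, sum(w*x) = 0, sum(w*y) = 0
    A = np.stack([np.ones(3), centered[3:6, 0], centered[3:6, 1]])
    rhs = -np.array([w.sum(), w @ centered[:, 0], w @ centered[:, 1]])
    w[3:6] = np.linalg.solve(A, rhs)
    pattern = np.zeros_like(base)
    pattern[:, 2] = w
    return pattern / np.linalg.norm(pattern)


@pytest.fixture
def toy_structure():
    rng = np.random.default_rng(42)
    return make_structure(rng.normal(0, 5, (5, 3)))
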