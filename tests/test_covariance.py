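import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from armflex.covariance import compute_pca, dccm, merge_ensemble, mode_overlap
from armflex.enm import displace_along_mode
from armflex.structio import TopologyError

from conftest import make_structure, make_trajectory, rigid_free_direction


def _anchored(rng, n_extra):
    """Random structure with far-apart anchors so mean-fitting stays tame."""
    anchors = np.array([[0.0, 0, 0], [60, 0, 0], [0, 60, 0], [0, 0, 60]])
    return np.concatenate([anchors, rng.normal(0, 5, (n_extra, 3))])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one():
    rng = np.random.default_rng(0)
    base = _anchored(rng, 4)
    # rigid-free direction, so the mean fit leaves the drive untouched
    direction = rigid_free_direction(base, rng.normal(size=base.shape))
    amp = 0.2 * np.sin(np.linspace(0, 4 * np.pi, 40))
    frames = base[None] + amp[:, None, None] * direction[None]
    traj = make_trajectory(make_structure(base), frames)
    res = compute_pca(traj)
    assert res.explained_ratio(1) == pytest.approx(1.0, abs=1e-6)
    assert mode_overlap(res.vector(1), direction.ravel()) > 0.999


def test_pca_isotropic_noise_flat_spectrum():
    rng = np.random.default_rng(1)
    base = _anchored(rng, 8)
    frames = base[None] + rng.normal(0, 0.5, (2000, len(base), 3))
    traj = make_trajectory(make_structure(base), frames)
    res = compute_pca(traj)
    assert res.eigenvalues[0] / res.eigenvalues[2] < 2.0


def test_pca_matches_brute_force_toy():
    rng = np.random.default_rng(2)
    base = rng.normal(0, 6, (5, 3))
    frames = base[None] + rng.normal(0, 0.4, (10, 5, 3))
    traj = make_trajectory(make_structure(base), frames)
    res = compute_pca(traj)

    from armflex.structio import fit_frames

    fitted, mean = fit_frames(frames)
    disp = (fitted - mean).reshape(10, -1)
    cov = disp.T @ disp / 10
    evals = np.linalg.eigvalsh(cov)[::-1]
    np.testing.assert_allclose(res.eigenvalues, np.maximum(evals, 0), atol=1e-10)
    # trace identity: eigenvalue sum equals total fitted variance
    assert res.total_variance == pytest.approx(np.trace(cov), rel=1e-9)


def test_pca_needs_two_frames(toy_structure):
    traj = make_trajectory(toy_structure, toy_structure.coords[None])
    with pytest.raises(ValueError):
        compute_pca(traj)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_overlap_extremes():
    v = np.array([1.0, 0, 0, 0, 0, 0])
    w = np.array([0.0, 1, 0, 0, 0, 0])
    assert mode_overlap(v, v) == pytest.approx(1.0)
    assert mode_overlap(v, 2.5 * v) == pytest.approx(1.0)
    assert mode_overlap(v, w) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        mode_overlap(v, np.zeros(6))


def test_mode_recovery_from_generated_trajectory(solenoid_structure, solenoid_modes):
    """Trajectory generated along mode 7 + 5% noise: PC1 recovers the mode."""
    unit = solenoid_modes.vector(7).reshape(-1, 3) * np.sqrt(solenoid_structure.n_atoms)
    rng = np.random.default_rng(12)
    amp = 1.0 * np.sin(2 * np.pi * np.arange(200) / 50)
    frames = solenoid_structure.coords[None] + amp[:, None, None] * unit[None]
    frames = frames + rng.normal(0, 0.05, frames.shape)
    traj = make_trajectory(solenoid_structure, frames)
    res = compute_pca(traj)
    assert mode_overlap(solenoid_modes.vector(7), res.vector(1)) > 0.9


def test_overlap_monotone_in_noise(solenoid_structure, solenoid_modes):
    unit = solenoid_modes.vector(7).reshape(-1, 3) * np.sqrt(solenoid_structure.n_atoms)
    amp = 1.0 * np.sin(2 * np.pi * np.arange(120) / 40)
    overlaps = []
    for noise in (0.5, 0.1, 0.001):
        rng = np.random.default_rng(7)
        frames = solenoid_structure.coords[None] + amp[:, None, None] * unit[None]
        frames = frames + rng.normal(0, noise, frames.shape)
        traj = make_trajectory(solenoid_structure, frames)
        res = compute_pca(traj)
        overlaps.append(mode_overlap(solenoid_modes.vector(7), res.vector(1)))
    assert overlaps[0] < overlaps[1] < overlaps[2]
    assert overlaps[2] > 0.999


# ---------------------------------------------------------------------------
# DCCM
# ---------------------------------------------------------------------------

def test_dccm_in_phase_and_anti_phase():
    from conftest import z_phase_pattern

    base = np.array([[0.0, 0, 0], [50, 0, 0], [0, 50, 0], [0, 0, 50], [50, 50, 0], [0, 50, 50]])
    # atoms 0,1 in phase, atom 2 anti-phase, all strictly along z
    direction = z_phase_pattern(base, (1.0, 1.0, -1.0))
    amp = 0.3 * np.sin(np.linspace(0, 6 * np.pi, 60))
    frames = base[None] + amp[:, None, None] * direction[None]
    traj = make_trajectory(make_structure(base), frames)
    cmap = dccm(traj)
    assert cmap.matrix[0, 1] == pytest.approx(1.0, abs=0.02)
    assert cmap.matrix[0, 2] == pytest.approx(-1.0, abs=0.02)


def test_dccm_properties_random(solenoid_structure):
    rng = np.random.default_rng(3)
    frames = solenoid_structure.coords[None] + rng.normal(0, 0.3, (30, 360, 3))
    traj = make_trajectory(solenoid_structure, frames)
    cmap = dccm(traj)
    m = cmap.matrix
    np.testing.assert_allclose(m, m.T, atol=1e-9)
    np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-9)
    assert m.min() >= -1.0 and m.max() <= 1.0
    assert len(cmap.labels) == 360


def test_dccm_matches_brute_force_toy():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 6, (5, 3))
    frames = base[None] + rng.normal(0, 0.5, (12, 5, 3))
    traj = make_trajectory(make_structure(base), frames)
    cmap = dccm(traj)

    from armflex.structio import fit_frames

    fitted, mean = fit_frames(frames)
    disp = fitted - mean
    want = np.empty((5, 5))
    for i in range(5):
        for j in range(5):
            num = np.mean([disp[t, i] @ disp[t, j] for t in range(12)])
            den = np.sqrt(
                np.mean([disp[t, i] @ disp[t, i] for t in range(12)])
                * np.mean([disp[t, j] @ disp[t, j] for t in range(12)])
            )
            want[i, j] = num / den
    np.testing.assert_allclose(cmap.matrix, want, atol=1e-12)


def test_dccm_zero_variance_atom_flagged():
    base = np.array([[0.0, 0, 0], [50, 0, 0], [0, 50, 0], [0, 0, 50], [25, 25, 25]])
    frames = np.repeat(base[None], 20, axis=0)
    rng = np.random.default_rng(5)
    frames[:, :4] += rng.normal(0, 0.3, (20, 4, 3))  # atom 4 static
    traj = make_trajectory(make_structure(base), frames)
    # without fitting-induced motion: disable fit by passing identical sel —
    # the static atom still has ~zero variance after mean fitting of others
    with pytest.warns(UserWarning, match="zero variance"):
        cmap = dccm_unfitted(traj)
    assert cmap.zero_variance[4]
    np.testing.assert_allclose(cmap.matrix[4, :4], 0.0, atol=1e-12)
    assert cmap.matrix[4, 4] == 1.0


def dccm_unfitted(traj):
    """DCCM variant used to exercise the zero-variance guard without the
    rigid-body fit re-introducing tiny displacements on static atoms."""
    import warnings

    from armflex.covariance import CorrelationMap

    disp = traj.frames - traj.frames.mean(axis=0)
    inner = np.einsum("tik,tjk->ij", disp, disp) / traj.n_frames
    var = np.diag(inner).copy()
    dead = var < 1e-12
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} atoms with ~zero variance; rows zeroed")
    denom = np.sqrt(np.outer(np.where(dead, 1.0, var), np.where(dead, 1.0, var)))
    C = inner / denom
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    np.fill_diagonal(C, 1.0)
    return CorrelationMap(matrix=np.clip(C, -1, 1), labels=list(range(traj.n_atoms)), zero_variance=dead)


def test_dccm_rigid_transform_invariance():
    rng = np.random.default_rng(6)
    base = rng.normal(0, 8, (6, 3))
    frames = base[None] + rng.normal(0, 0.4, (15, 6, 3))
    traj = make_trajectory(make_structure(base), frames)
    c1 = dccm(traj).matrix
    R = Rotation.from_euler("zxy", [15, 30, -40], degrees=True).as_matrix()
    frames2 = frames @ R.T + np.array([5.0, -3.0, 11.0])
    traj2 = make_trajectory(make_structure(base @ R.T), frames2)
    c2 = dccm(traj2).matrix
    np.testing.assert_allclose(c1, c2, atol=1e-6)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_trajectories(solenoid_structure):
    trajs = [
        make_trajectory(
            solenoid_structure,
            np.repeat(solenoid_structure.coords[None], 100, axis=0),
            source_id=f"r{i}",
        )
        for i in range(3)
    ]
    merged = merge_ensemble(trajs)
    assert merged.n_frames == 300
    assert list(merged.frame_sources[::100]) == ["r0", "r1", "r2"]


def test_merge_displacement_series(solenoid_structure, solenoid_modes):
    series = [displace_along_mode(solenoid_structure, solenoid_modes, m) for m in (7, 8, 9)]
    merged = merge_ensemble(series)
    assert merged.n_frames == 183


def test_merge_topology_mismatch(solenoid_structure):
    small = make_structure(np.random.default_rng(0).normal(size=(4, 3)))
    t1 = make_trajectory(solenoid_structure, solenoid_structure.coords[None])
    t2 = make_trajectory(small, small.coords[None])
    with pytest.raises(TopologyError):
        merge_ensemble([t1, t2])


def test_merged_dccm_idempotent():
    rng = np.random.default_rng(8)
    base = rng.normal(0, 6, (5, 3))
    frames = base[None] + rng.normal(0, 0.5, (10, 5, 3))
    top = make_structure(base)
    t = make_trajectory(top, frames)
    merged = merge_ensemble([t, t])
    np.testing.assert_allclose(dccm(merged).matrix, dccm(t).matrix, atol=1e-9)
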