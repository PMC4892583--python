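import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from armflex.elements import UnknownElementError, mass_of
from armflex.structio import (
    AtomSelection,
    PDBParseError,
    StructureModel,
    TopologyError,
    Trajectory,
    read_pdb,
    rmsd,
    rmsd_series,
    rmsf,
    superpose,
    write_pdb,
)

from conftest import make_structure, make_trajectory


# ---------------------------------------------------------------------------
# model invariants
# ---------------------------------------------------------------------------

def test_structure_requires_atoms():
    with pytest.raises(ValueError):
        make_structure(np.empty((0, 3)))


def test_structure_rejects_nonfinite():
    with pytest.raises(ValueError, match="finite"):
        make_structure([[0, 0, np.nan]])


def test_structure_rejects_duplicate_keys():
    with pytest.raises(ValueError, match="duplicate"):
        make_structure([[0, 0, 0], [1, 0, 0]], resnums=[1, 1])


def test_structure_rejects_nonpositive_mass():
    with pytest.raises(ValueError, match="mass"):
        make_structure([[0, 0, 0]], masses=[0.0])


def test_trajectory_topology_mismatch():
    top = make_structure([[0, 0, 0], [1, 0, 0]])
    with pytest.raises(TopologyError):
        make_trajectory(top, np.zeros((2, 3, 3)))


def test_trajectory_times_strictly_increasing():
    top = make_structure([[0, 0, 0]])
    with pytest.raises(ValueError, match="increasing"):
        Trajectory(top, np.zeros((2, 1, 3)), times=np.array([1.0, 1.0]))


def test_unknown_element_raises():
    with pytest.raises(UnknownElementError):
        mass_of("Xx")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def test_read_single_model(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
        "ATOM      2  CA  ALA A   2       2.000   2.000   3.000  1.00  0.00           C\n"
        "ATOM      3  CA  ALA A   3       3.000   2.000   3.000  1.00  0.00           C\n"
    )
    model = read_pdb(p)
    assert isinstance(model, StructureModel)
    assert model.n_atoms == 3
    np.testing.assert_allclose(model.coords[0], [1.0, 2.0, 3.0])


def test_read_multi_model(tmp_path, solenoid_structure):
    traj = make_trajectory(solenoid_structure, np.repeat(solenoid_structure.coords[None], 5, axis=0))
    p = tmp_path / "traj.pdb"
    write_pdb(traj, p)
    back = read_pdb(p)
    assert isinstance(back, Trajectory)
    assert back.n_frames == 5
    assert back.n_atoms == 360


def test_inconsistent_model_atom_count(tmp_path):
    line = "ATOM  {serial:>5d}  CA  ALA A{res:>4d}       1.000   2.000   3.000  1.00  0.00           C\n"
    text = "MODEL        1\n"
    text += line.format(serial=1, res=1) + line.format(serial=2, res=2)
    text += "ENDMDL\nMODEL        2\n" + line.format(serial=1, res=1) + "ENDMDL\n"
    p = tmp_path / "bad.pdb"
    p.write_text(text)
    with pytest.raises(TopologyError, match="model 2"):
        read_pdb(p)


def test_malformed_record_reports_line(tmp_path):
    p = tmp_path / "mal.pdb"
    p.write_text("ATOM      1  CA  ALA A   1       1.000   xxx     3.000\n")
    with pytest.raises(PDBParseError, match="line 1"):
        read_pdb(p)


def test_roundtrip_identity(tmp_path):
    rng = np.random.default_rng(0)
    model = make_structure(rng.uniform(-50, 50, (10, 3)))
    p = tmp_path / "rt.pdb"
    write_pdb(model, p)
    back = read_pdb(p)
    assert np.array_equal(back.atom_names, model.atom_names)
    assert np.array_equal(back.residue_numbers, model.residue_numbers)
    assert np.array_equal(back.chain_ids, model.chain_ids)
    np.testing.assert_allclose(back.coords, model.coords, atol=5.1e-4)


def test_write_trajectory_has_model_records(tmp_path):
    top = make_structure([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
    traj = make_trajectory(top, np.repeat(top.coords[None], 3, axis=0))
    p = tmp_path / "t.pdb"
    write_pdb(traj, p)
    text = p.read_text()
    assert text.count("MODEL ") == 3
    assert text.count("ENDMDL") == 3


def test_coordinate_overflow(tmp_path):
    model = make_structure([[99999.0, 0, 0], [0, 1, 0], [1, 0, 0]])
    with pytest.raises(ValueError, match="fixed-width"):
        write_pdb(model, tmp_path / "x.pdb")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_superpose_identical(toy_structure):
    _, _, val = superpose(toy_structure, toy_structure)
    assert val < 1e-12


def test_superpose_rotated_copy(toy_structure):
    R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    mobile = toy_structure.copy(coords=toy_structure.coords @ R90.T + [3.0, -2.0, 7.0])
    R, t, val = superpose(mobile, toy_structure)
    assert val < 1e-9
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def _so3_grid_rmsd(mobile, reference):
    """Brute-force oracle: best RMSD over a dense rotation grid (centered)."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    best = np.inf
    best_euler = None
    coarse = np.arange(0, 360, 10.0)
    half = np.arange(0, 181, 10.0)
    for a in coarse:
        for b in half:
            for c in coarse:
                R = Rotation.from_euler("zyz", [a, b, c], degrees=True).as_matrix()
                v = rmsd(mc @ R.T, rc)
                if v < best:
                    best, best_euler = v, (a, b, c)
    a0, b0, c0 = best_euler
    for a in np.arange(a0 - 10, a0 + 10, 0.5):
        for b in np.arange(b0 - 10, b0 + 10, 0.5):
            for c in np.arange(c0 - 10, c0 + 10, 0.5):
                R = Rotation.from_euler("zyz", [a, b, c], degrees=True).as_matrix()
                best = min(best, rmsd(mc @ R.T, rc))
    return best


def test_superpose_against_rotation_grid_oracle():
    # 4-point sets: one point offset by 1 A after an arbitrary rigid motion
    ref = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]])
    mob = ref.copy()
    mob[3] += [0.0, 0.0, 1.0]
    R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
    mob = mob @ R.T + [1.0, 2.0, 3.0]
    a = make_structure(mob)
    b = make_structure(ref)
    _, _, fitted = superpose(a, b)
    oracle = _so3_grid_rmsd(mob, ref)
    assert fitted == pytest.approx(oracle, abs=1e-3)
    assert fitted <= oracle + 1e-12  # Kabsch is optimal


def test_superpose_count_mismatch():
    a = make_structure(np.random.default_rng(1).normal(size=(4, 3)))
    b = make_structure(np.random.default_rng(2).normal(size=(5, 3)))
    with pytest.raises(ValueError):
        superpose(a, b)


def test_superpose_collinear_rejected():
    pts = np.outer(np.arange(4.0), [1.0, 0, 0])
    a = make_structure(pts)
    with pytest.raises(ValueError, match="collinear"):
        superpose(a, a.copy())


def test_superpose_idempotent(toy_structure):
    rng = np.random.default_rng(5)
    mob = toy_structure.copy(coords=toy_structure.coords + rng.normal(0, 0.4, (5, 3)))
    R, t, r1 = superpose(mob, toy_structure)
    fitted = mob.copy(coords=mob.coords @ R.T + t)
    _, _, r2 = superpose(fitted, toy_structure)
    assert abs(r1 - r2) < 1e-9


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_rmsd_invariant_under_common_rigid_transform(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 3, (6, 3))
    b = rng.normal(0, 3, (6, 3))
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.normal(0, 10, 3)
    assert rmsd(a, b) == pytest.approx(rmsd(a @ R.T + t, b @ R.T + t), abs=1e-6)


# ---------------------------------------------------------------------------
# rmsd_series / rmsf
# ---------------------------------------------------------------------------

def test_rmsd_series_of_copies(toy_structure):
    traj = make_trajectory(toy_structure, np.repeat(toy_structure.coords[None], 4, axis=0))
    np.testing.assert_allclose(rmsd_series(traj, toy_structure), 0.0, atol=1e-12)


def test_rmsd_series_translation(toy_structure):
    shifted = toy_structure.coords + [3.0, 0.0, 0.0]
    traj = make_trajectory(toy_structure, shifted[None])
    assert rmsd_series(traj, toy_structure, fit=True)[0] == pytest.approx(0.0, abs=1e-9)
    assert rmsd_series(traj, toy_structure, fit=False)[0] == pytest.approx(3.0, abs=1e-12)


def test_rmsd_series_matches_formula_oracle(toy_structure):
    rng = np.random.default_rng(9)
    frames = toy_structure.coords[None] + rng.normal(0, 1.0, (5, 5, 3))
    traj = make_trajectory(toy_structure, frames)
    got = rmsd_series(traj, toy_structure, fit=False)
    want = [np.sqrt(np.mean(np.sum((f - toy_structure.coords) ** 2, axis=1))) for f in frames]
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_rmsf_constant_trajectory(toy_structure):
    traj = make_trajectory(toy_structure, np.repeat(toy_structure.coords[None], 3, axis=0))
    np.testing.assert_allclose(rmsf(traj), 0.0, atol=1e-12)


def test_rmsf_single_frame_rejected(toy_structure):
    traj = make_trajectory(toy_structure, toy_structure.coords[None])
    with pytest.raises(ValueError):
        rmsf(traj)


def test_rmsf_alternating_atom():
    # closed form without fitting: the alternating atom is exactly 1.0
    base = np.array([[0.0, 0, 0], [50, 0, 0], [0, 50, 0], [0, 0, 50], [50, 50, 50]])
    frames = np.repeat(base[None], 10, axis=0)
    frames[::2, 0, 0] += 1.0
    frames[1::2, 0, 0] -= 1.0
    traj = make_trajectory(make_structure(base), frames)
    vals = rmsf(traj, fit=False)
    assert vals[0] == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(vals[1:], 0.0, atol=1e-12)


def test_rmsf_brute_force_oracle():
    rng = np.random.default_rng(11)
    base = rng.normal(0, 8, (6, 3))
    frames = base[None] + rng.normal(0, 0.3, (10, 6, 3))
    traj = make_trajectory(make_structure(base), frames)
    got = rmsf(traj)
    from armflex.structio import fit_frames

    fitted, mean = fit_frames(frames)
    want = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    np.testing.assert_allclose(got, want, atol=1e-12)
    assert np.all(got >= 0)


def test_rmsf_scales_with_displacement():
    base = np.array([[0.0, 0, 0], [50, 0, 0], [0, 50, 0], [0, 0, 50]])
    rng = np.random.default_rng(3)
    disp = rng.normal(0, 0.2, (8, 4, 3))
    t1 = make_trajectory(make_structure(base), base[None] + disp)
    t2 = make_trajectory(make_structure(base), base[None] + 3.0 * disp)
    np.testing.assert_allclose(rmsf(t2), 3.0 * rmsf(t1), rtol=5e-2)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def test_selection_string_triplets(solenoid_structure):
    sel = AtomSelection.from_string(solenoid_structure, "A:1-36:CA")
    assert len(sel) == 36
    sel2 = AtomSelection.from_string(solenoid_structure, "ca")
    assert len(sel2) == solenoid_structure.n_atoms


def test_selection_indices_sorted_unique(solenoid_structure):
    sel = AtomSelection([5, 3, 3, 1], solenoid_structure.n_atoms)
    assert list(sel.indices) == [1, 3, 5]


def test_empty_selection_rejected():
    with pytest.raises(ValueError):
        AtomSelection([])
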