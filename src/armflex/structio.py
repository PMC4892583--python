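"""Structure/trajectory data model, PDB I/O, superposition, RMSD and RMSF.

Coordinates are in Angstrom throughout, masses in amu, times in ps.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .elements import guess_element, mass_of

__all__ = [
    "StructureModel",
    "Trajectory",
    "AtomSelection",
    "PDBParseError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "kabsch",
    "superpose",
    "rmsd",
    "rmsd_to_reference",
    "rmsd_series",
    "fit_frames",
    "rmsf",
]


class PDBParseError(ValueError):
    """Malformed PDB record; message carries the 1-based line number."""


class TopologyError(ValueError):
    """Frames of a multi-model file / trajectory disagree on the atom table."""


@dataclasses.dataclass
class StructureModel:
    """One conformation: parallel per-atom arrays plus coordinates.

    Invariants (checked in ``validate``): at least one atom, finite
    coordinates, strictly positive masses, and unique
    (chain_id, residue_number, atom_name) keys.
    """

    serials: np.ndarray  # int
    atom_names: np.ndarray  # str
    residue_names: np.ndarray  # str
    residue_numbers: np.ndarray  # int
    chain_ids: np.ndarray  # str (single char)
    elements: np.ndarray  # str
    coords: np.ndarray  # (N, 3) float, Angstrom
    masses: np.ndarray  # float, amu

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.n_atoms
        if n < 1:
            raise ValueError("a StructureModel needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.masses > 0):
            raise ValueError("masses must be strictly positive")
        keys = list(zip(self.chain_ids, self.residue_numbers, self.atom_names))
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom key {k}")
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def copy(self, coords: np.ndarray | None = None) -> "StructureModel":
        return StructureModel(
            serials=self.serials.copy(),
            atom_names=self.atom_names.copy(),
            residue_names=self.residue_names.copy(),
            residue_numbers=self.residue_numbers.copy(),
            chain_ids=self.chain_ids.copy(),
            elements=self.elements.copy(),
            coords=self.coords.copy() if coords is None else np.asarray(coords, float).copy(),
            masses=self.masses.copy(),
        )

    @classmethod
    def from_atoms(cls, atoms: Sequence[tuple]) -> "StructureModel":
        """Build from (serial, name, resname, resnum, chain, element, coord, mass) tuples."""
        serials, names, resnames, resnums, chains, elems, coords, masses = zip(*atoms)
        return cls(
            serials=np.array(serials, dtype=int),
            atom_names=np.array(names, dtype=object),
            residue_names=np.array(resnames, dtype=object),
            residue_numbers=np.array(resnums, dtype=int),
            chain_ids=np.array(chains, dtype=object),
            elements=np.array(elems, dtype=object),
            coords=np.array(coords, dtype=float),
            masses=np.array(masses, dtype=float),
        )


@dataclasses.dataclass
class Trajectory:
    """Ordered frames over a fixed topology; times in ps, strictly increasing."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,) ps
    source_id: str = "traj"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("one time stamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame_structure(self, i: int) -> StructureModel:
        return self.topology.copy(coords=self.frames[i])


class AtomSelection:
    """Resolved, sorted, unique atom indices into a StructureModel."""

    def __init__(self, indices: Sequence[int], n_atoms: int | None = None):
        idx = np.unique(np.asarray(indices, dtype=int))
        if len(idx) == 0:
            raise ValueError("empty selection")
        if np.any(idx < 0):
            raise ValueError("negative atom index in selection")
        if n_atoms is not None and np.any(idx >= n_atoms):
            raise ValueError("selection index out of range")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    @classmethod
    def from_predicate(
        cls,
        structure: StructureModel,
        predicate: Callable[[str, int, str], bool],
    ) -> "AtomSelection":
        """Select atoms for which predicate(chain_id, residue_number, atom_name) is true."""
        idx = [
            i
            for i in range(structure.n_atoms)
            if predicate(structure.chain_ids[i], int(structure.residue_numbers[i]), structure.atom_names[i])
        ]
        return cls(idx, structure.n_atoms)

    @classmethod
    def from_string(cls, structure: StructureModel, spec: str) -> "AtomSelection":
        """Parse selection strings.

        Grammar: comma-separated triplets ``chain:resnum_range:atom_name``
        where any field may be ``*``; the shorthands ``ca`` (all CA atoms)
        and ``backbone`` (N, CA, C, O) are accepted.
        """
        spec = spec.strip()
        if spec.lower() == "ca":
            return cls.from_predicate(structure, lambda c, r, a: a == "CA")
        if spec.lower() == "backbone":
            return cls.from_predicate(structure, lambda c, r, a: a in ("N", "CA", "C", "O"))
        if spec == "*" or spec.lower() == "all":
            return cls(np.arange(structure.n_atoms), structure.n_atoms)
        wanted: list[int] = []
        for triplet in spec.split(","):
            parts = triplet.strip().split(":")
            if len(parts) != 3:
                raise ValueError(f"bad selection triplet {triplet!r}: want chain:resrange:atom")
            chain, resrange, atom = (p.strip() for p in parts)
            if resrange == "*":
                lo, hi = None, None
            elif "-" in resrange:
                lo_s, hi_s = resrange.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(resrange)

            def pred(c, r, a, chain=chain, lo=lo, hi=hi, atom=atom):
                if chain != "*" and c != chain:
                    return False
                if lo is not None and not (lo <= r <= hi):
                    return False
                if atom != "*" and a != atom:
                    return False
                return True

            wanted.extend(cls.from_predicate(structure, pred).indices.tolist())
        return cls(wanted, structure.n_atoms)


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/HETATM with MODEL/ENDMDL framing)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17]
        resname = line[17:20].strip()
        chain = line[21:22]
        resnum = int(line[22:26])
        icode = line[26:27]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    if icode.strip():
        raise PDBParseError(f"line {lineno}: insertion codes are not supported")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = guess_element(name)
    return serial, name, altloc, resname, chain, resnum, (x, y, z), element


def read_pdb(path: str | Path) -> StructureModel | Trajectory:
    """Read a PDB file; one model gives a StructureModel, several a Trajectory.

    First altloc is kept; insertion codes are rejected. Multi-model files
    must have an identical atom table in every model.
    """
    path = Path(path)
    models: list[list[tuple]] = []
    current: list[tuple] = []
    seen_altloc: set = set()
    in_model = False
    any_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                any_model_record = True
                if in_model and current:
                    models.append(current)
                current = []
                seen_altloc = set()
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                seen_altloc = set()
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                serial, name, altloc, resname, chain, resnum, xyz, element = _parse_atom_line(line, lineno)
                key = (chain, resnum, name)
                if altloc.strip():
                    if key in seen_altloc:
                        continue  # keep first altloc only
                    seen_altloc.add(key)
                current.append((serial, name, resname, resnum, chain, element, xyz, mass_of(element)))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    structures = [StructureModel.from_atoms(m) for m in models]
    if len(structures) == 1 and not any_model_record:
        return structures[0]
    if len(structures) == 1:
        return structures[0]

    top = structures[0]
    for i, s in enumerate(structures[1:], start=2):
        if s.n_atoms != top.n_atoms:
            raise TopologyError(
                f"{path}: model {i} has {s.n_atoms} atoms, model 1 has {top.n_atoms}"
            )
        if not (
            np.array_equal(s.atom_names, top.atom_names)
            and np.array_equal(s.residue_numbers, top.residue_numbers)
            and np.array_equal(s.chain_ids, top.chain_ids)
        ):
            raise TopologyError(f"{path}: model {i} atom table differs from model 1")
    frames = np.stack([s.coords for s in structures])
    return Trajectory(topology=top, frames=frames, times=np.arange(len(frames), dtype=float))


def _format_atom_line(serial, name, resname, resnum, chain, element, xyz) -> str:
    x, y, z = xyz
    for c in (x, y, z):
        if not (-999.999 <= c <= 9999.999):
            raise ValueError(f"coordinate {c} exceeds the PDB fixed-width field")
    # atom names of <4 chars start in column 14 per PDB convention
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field}{'':1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}\n"
    )


def write_pdb(obj: StructureModel | Trajectory, path: str | Path) -> Path:
    """Write a structure or trajectory as (multi-model) fixed-column PDB."""
    path = Path(path)
    if isinstance(obj, StructureModel):
        models = [obj.coords]
        top = obj
    else:
        models = list(obj.frames)
        top = obj.topology
    multi = not isinstance(obj, StructureModel)
    with open(path, "w") as fh:
        for im, coords in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {im:>4d}\n")
            for i in range(top.n_atoms):
                fh.write(
                    _format_atom_line(
                        int(top.serials[i]),
                        top.atom_names[i],
                        top.residue_names[i],
                        int(top.residue_numbers[i]),
                        top.chain_ids[i],
                        top.elements[i],
                        coords[i],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


# ---------------------------------------------------------------------------
# Superposition and deviation metrics
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (rotation, translation) mapping mobile onto reference.

    Returns (R, t) with det(R) = +1 such that mobile @ R.T + t approximates
    reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equally sized point sets (no fitting)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _check_selection_geometry(coords: np.ndarray) -> None:
    if len(coords) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection")


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    sel: AtomSelection | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch-fit mobile onto reference over the selection.

    Returns (rotation, translation, post-fit RMSD over the selection). The
    transform maps mobile coordinates as ``x @ R.T + t``.
    """
    if sel is None and mobile.n_atoms != reference.n_atoms:
        raise ValueError(
            f"atom count mismatch: {mobile.n_atoms} vs {reference.n_atoms}"
        )
    idx = sel.indices if sel is not None else np.arange(mobile.n_atoms)
    xm = mobile.coords[idx]
    xr = reference.coords[idx]
    if xm.shape != xr.shape:
        raise ValueError("selection resolves to different atom counts")
    _check_selection_geometry(xm)
    _check_selection_geometry(xr)
    R, t = kabsch(xm, xr)
    fitted = xm @ R.T + t
    return R, t, rmsd(fitted, xr)


def rmsd_to_reference(
    coords: np.ndarray, ref_coords: np.ndarray, fit: bool = True
) -> np.ndarray:
    """Batched RMSD of frames (n, m, 3) against one reference (m, 3).

    With ``fit`` each frame is Kabsch-superposed first (vectorized SVD on
    the 3x3 cross-covariances).
    """
    coords = np.asarray(coords, float)
    ref = np.asarray(ref_coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    if not fit:
        d = coords - ref[None]
        return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
    cm = coords.mean(axis=1, keepdims=True)
    cr = ref.mean(axis=0)
    xm = coords - cm
    xr = ref - cr
    H = np.einsum("nmi,mj->nij", xm, xr)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nij,njk->nik", np.transpose(Vt, (0, 2, 1)), np.transpose(U, (0, 2, 1))))
    D = np.repeat(np.eye(3)[None], len(H), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("nij,njk,nkl->nil", np.transpose(Vt, (0, 2, 1)), D, np.transpose(U, (0, 2, 1)))
    fitted = np.einsum("nmi,nji->nmj", xm, R)
    d = fitted - xr[None]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


def rmsd_series(
    traj: Trajectory,
    reference: StructureModel,
    sel: AtomSelection | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) of the trajectory against a reference structure."""
    idx = sel.indices if sel is not None else np.arange(traj.n_atoms)
    if len(idx) == 0:
        raise ValueError("empty selection")
    return rmsd_to_reference(traj.frames[:, idx], reference.coords[idx], fit=fit)


def fit_frames(frames: np.ndarray, sel_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame on the ensemble mean (one iteration).

    Frames are first fitted to frame 0 over ``sel_idx``, the mean is taken,
    and every frame is refitted to that mean. Returns (fitted_frames, mean).
    """
    frames = np.asarray(frames, float)
    idx = sel_idx if sel_idx is not None else np.arange(frames.shape[1])

    def _fit_all(frames_in: np.ndarray, ref: np.ndarray) -> np.ndarray:
        out = np.empty_like(frames_in)
        for i, fr in enumerate(frames_in):
            R, t = kabsch(fr[idx], ref[idx])
            out[i] = fr @ R.T + t
        return out

    fitted = _fit_all(frames, frames[0])
    mean = fitted.mean(axis=0)
    fitted = _fit_all(fitted, mean)
    return fitted, fitted.mean(axis=0)


def rmsf(traj: Trajectory, sel: AtomSelection | None = None, fit: bool = True) -> np.ndarray:
    """Per-atom RMS fluctuation about the time-average position.

    With ``fit`` (default), frames are first fitted to the time-averaged
    structure (one iteration of fit-to-mean) over the selection; pass
    ``fit=False`` for pre-aligned frames.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = sel.indices if sel is not None else np.arange(traj.n_atoms)
    if fit:
        fitted, mean = fit_frames(traj.frames, idx)
    else:
        fitted, mean = traj.frames, traj.frames.mean(axis=0)
    d = fitted[:, idx] - mean[idx]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=0))
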