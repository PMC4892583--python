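"""Idealized alpha-solenoid fixtures with analytically known bend/twist motions.

The generator builds a C-alpha trace of ``n_repeats`` tandem repeats of three
helices each, related by an exact screw transform about the z axis.  Motion
trajectories apply a hinge bend about the middle repeat and a cumulative
per-repeat twist about vertical axes, both sinusoidal in time, so every
geometric observable downstream has a closed-form ground truth:

* the per-repeat twist spins each repeat about the vertical line through its
  own anchor atom, so the three curvature anchor atoms never move under pure
  twist (radius of curvature exactly constant);
* the hinge axis is parallel to the middle repeat's H3 helix axis, so every
  inter-repeat H3 angle is exactly conserved under pure bend;
* the helical turn per residue is solved so that the principal axis of the
  discrete C-alpha trace coincides with the analytic helix axis, making
  fitted helix vectors exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .structio import StructureModel, Trajectory

__all__ = [
    "SolenoidSpec",
    "ArmAnnotation",
    "MotionSpec",
    "PeptideSpec",
    "ContactEntry",
    "ContactSchedule",
    "GeometryError",
    "build_solenoid",
    "simulate_trajectory",
    "build_complex",
    "make_schedule",
    "schedule_trajectory",
    "write_fixture_set",
]

CARBON_MASS = 12.011


class GeometryError(ValueError):
    """Self-intersecting or otherwise impossible solenoid parameters."""


@dataclasses.dataclass
class SolenoidSpec:
    n_repeats: int = 10
    helices_per_repeat: int = 3
    residues_per_helix: int = 12
    helix_rise: float = 1.5  # Angstrom per residue
    helix_radius: float = 2.3
    superhelix_radius: float = 8.0
    repeat_rise: float = 9.0
    repeat_twist: float = 25.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if self.residues_per_helix < 4:
            raise ValueError("residues_per_helix must be >= 4")
        for name in ("helix_rise", "helix_radius", "superhelix_radius", "repeat_rise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def residues_per_repeat(self) -> int:
        return self.helices_per_repeat * self.residues_per_helix

    @property
    def n_residues(self) -> int:
        return self.n_repeats * self.residues_per_repeat


@dataclasses.dataclass
class ArmAnnotation:
    """Per-repeat residue ranges (inclusive) for helices H1..Hk."""

    ranges: dict  # repeat (1-based) -> {"H1": (lo, hi), ...}
    anchor_residues: dict  # repeat -> residue number of the repeat anchor atom
    middle_repeat: int

    @property
    def n_repeats(self) -> int:
        return len(self.ranges)

    def helix_range(self, repeat: int, helix: str) -> tuple[int, int]:
        return self.ranges[repeat][helix]

    def h3_range(self, repeat: int) -> tuple[int, int]:
        return self.helix_range(repeat, "H3")

    def repeat_residues(self, repeat: int) -> tuple[int, int]:
        helices = self.ranges[repeat]
        lows = [lo for lo, _ in helices.values()]
        highs = [hi for _, hi in helices.values()]
        return min(lows), max(highs)

    def validate(self, n_residues: int) -> None:
        covered: list[int] = []
        for helices in self.ranges.values():
            for lo, hi in helices.values():
                if lo > hi:
                    raise ValueError("helix range reversed")
                covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, n_residues + 1)):
            raise ValueError("annotation ranges must tile all residues without gaps")

    def to_dict(self) -> dict:
        return {
            "ranges": {str(r): {h: list(v) for h, v in hr.items()} for r, hr in self.ranges.items()},
            "anchor_residues": {str(r): v for r, v in self.anchor_residues.items()},
            "middle_repeat": self.middle_repeat,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmAnnotation":
        return cls(
            ranges={int(r): {h: tuple(v) for h, v in hr.items()} for r, hr in d["ranges"].items()},
            anchor_residues={int(r): v for r, v in d["anchor_residues"].items()},
            middle_repeat=int(d["middle_repeat"]),
        )


@dataclasses.dataclass
class MotionSpec:
    bend_amplitude: float = 0.0  # degrees, hinge half-angle about the middle repeat
    twist_amplitude: float = 0.0  # degrees per neighboring repeat pair
    period: int = 50  # frames
    noise_sd: float = 0.0  # Angstrom, isotropic per atom coordinate
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bend_amplitude < 0 or self.twist_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be positive")


# ---------------------------------------------------------------------------
# Helix and solenoid construction
# ---------------------------------------------------------------------------

def _axis_exact_turn(n: int, target_deg: float = 100.0) -> float:
    """Per-residue turn (radians) near ``target_deg`` for which the principal
    axis of the discrete helix trace is exactly the helix axis.

    With phase-centered residues the x-axis cross-covariance vanishes by
    symmetry; the remaining condition is sum_k k*sin(k*dphi) = 0 over the
    half-integer offsets k.
    """
    ks = np.arange(n) - (n - 1) / 2.0

    def f(dphi: float) -> float:
        return float(np.sum(ks * np.sin(ks * dphi)))

    lo, hi = np.radians(target_deg - 25.0), np.radians(target_deg + 25.0)
    grid = np.linspace(lo, hi, 400)
    vals = np.array([f(g) for g in grid])
    best = None
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            return float(grid[i])
        if vals[i] * vals[i + 1] < 0:
            root = brentq(f, grid[i], grid[i + 1])
            if best is None or abs(np.degrees(root) - target_deg) < abs(np.degrees(best) - target_deg):
                best = root
    if best is None:  # pragma: no cover - dense grid always brackets a root
        return np.radians(target_deg)
    return float(best)


def _helix_points(n: int, rise: float, radius: float, axis: np.ndarray, center: np.ndarray) -> np.ndarray:
    """C-alpha trace of an ideal helix whose principal axis equals ``axis``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame
    seed_vec = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, seed_vec)
    v /= np.linalg.norm(v)
    w = np.cross(axis, v)
    dphi = _axis_exact_turn(n)
    ks = np.arange(n) - (n - 1) / 2.0
    theta = ks * dphi
    pts = (
        center[None, :]
        + np.outer(ks * rise, axis)
        + radius * (np.outer(np.cos(theta), v) + np.outer(np.sin(theta), w))
    )
    return pts


def _rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalized) axis."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def _template_repeat(spec: SolenoidSpec) -> np.ndarray:
    """One repeat in the template frame (repeat centroid near x=superhelix_radius).

    H3 is placed innermost (smallest distance to the z axis) — it lines the
    concave face; H1 outermost.  Helix axes are horizontal (+/- y), so twist
    spins about vertical axes act on helix vectors as exact in-plane
    rotations.
    """
    n = spec.residues_per_helix
    offsets = {
        "H1": (+5.0, -3.0, np.array([0.0, 1.0, 0.0])),
        "H2": (0.0, 0.0, np.array([0.0, -1.0, 0.0])),
        "H3": (-5.0, +3.0, np.array([0.0, 1.0, 0.0])),
    }
    helices = []
    for name in ("H1", "H2", "H3")[: spec.helices_per_repeat]:
        dx, dz, axis = offsets[name]
        center = np.array([spec.superhelix_radius + dx, 0.0, dz])
        helices.append(_helix_points(n, spec.helix_rise, spec.helix_radius, axis, center))
    # generic extra helices for helices_per_repeat > 3 (rarely used)
    for k in range(3, spec.helices_per_repeat):
        axis = np.array([0.0, 1.0, 0.0]) * (-1.0 if k % 2 else 1.0)
        center = np.array([spec.superhelix_radius + 5.0 + 4.0 * (k - 2), 0.0, 0.0])
        helices.append(_helix_points(n, spec.helix_rise, spec.helix_radius, axis, center))
    return np.concatenate(helices, axis=0)


def screw_transform(spec: SolenoidSpec, k: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """(rotation, translation) of the k-fold inter-repeat screw about z."""
    R = _rot_z(spec.repeat_twist * k)
    t = np.array([0.0, 0.0, spec.repeat_rise * k])
    return R, t


def build_solenoid(spec: SolenoidSpec) -> tuple[StructureModel, ArmAnnotation]:
    """Ideal C-alpha solenoid plus its helix annotation.

    Repeat r is the template repeat under the (r-1)-fold screw transform;
    residues are numbered 1..N along the chain; the anchor residue of each
    repeat is the middle residue of H2.
    """
    template = _template_repeat(spec)
    per_repeat = spec.residues_per_repeat
    coords = np.concatenate(
        [template @ _rot_z(spec.repeat_twist * r).T + np.array([0, 0, spec.repeat_rise * r]) for r in range(spec.n_repeats)]
    )

    # self-intersection guard: minimum inter-repeat atom distance
    for r in range(spec.n_repeats - 1):
        a = coords[r * per_repeat : (r + 1) * per_repeat]
        rest = coords[(r + 1) * per_repeat :]
        if cdist(a, rest).min() < 1.0:
            raise GeometryError("solenoid parameters produce inter-repeat clashes (< 1 A)")

    n = spec.n_residues
    model = StructureModel(
        serials=np.arange(1, n + 1),
        atom_names=np.array(["CA"] * n, dtype=object),
        residue_names=np.array(["ALA"] * n, dtype=object),
        residue_numbers=np.arange(1, n + 1),
        chain_ids=np.array(["A"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        coords=coords,
        masses=np.full(n, CARBON_MASS),
    )

    ranges: dict = {}
    anchors: dict = {}
    helix_names = [f"H{i+1}" for i in range(spec.helices_per_repeat)]
    for r in range(spec.n_repeats):
        start = r * per_repeat + 1
        helices = {}
        for h, name in enumerate(helix_names):
            lo = start + h * spec.residues_per_helix
            helices[name] = (lo, lo + spec.residues_per_helix - 1)
        ranges[r + 1] = helices
        h2lo, h2hi = helices[helix_names[min(1, len(helix_names) - 1)]]
        anchors[r + 1] = h2lo + (h2hi - h2lo) // 2
    ann = ArmAnnotation(
        ranges=ranges,
        anchor_residues=anchors,
        middle_repeat=(spec.n_repeats + 1) // 2,
    )
    ann.validate(n)
    return model, ann


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def _repeat_slices(annotation: ArmAnnotation) -> list[tuple[int, slice]]:
    out = []
    for r in sorted(annotation.ranges):
        lo, hi = annotation.repeat_residues(r)
        out.append((r, slice(lo - 1, hi)))  # residue i -> atom index i-1 (CA trace)
    return out


def hinge_axis(structure: StructureModel, annotation: ArmAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """(point, direction) of the bend hinge: through the middle repeat's
    anchor atom, parallel to that repeat's H3 axis."""
    from .geometry import fit_helix_vector  # deferred to avoid a cycle

    mid = annotation.middle_repeat
    anchor_res = annotation.anchor_residues[mid]
    point = structure.coords[anchor_res - 1].copy()
    hv = fit_helix_vector(structure, annotation.h3_range(mid))
    return point, hv.vector


def simulate_trajectory(
    structure: StructureModel,
    annotation: ArmAnnotation,
    motion: MotionSpec,
) -> Trajectory:
    """Sinusoidal bend + twist trajectory with optional Gaussian noise.

    Frame t applies a hinge rotation of ``bend_amplitude*sin(2*pi*t/period)``
    (N-side +theta, C-side -theta, middle repeat fixed) and spins repeat r by
    ``(r - middle)*twist_amplitude*sin(2*pi*t/period)`` about the vertical
    axis through its anchor atom.  Frame 0 equals the input exactly when the
    noise is zero.
    """
    rng = np.random.default_rng(motion.seed)
    base = structure.coords
    slices = _repeat_slices(annotation)
    mid = annotation.middle_repeat
    hpoint, hdir = hinge_axis(structure, annotation)
    anchor_points = {r: base[annotation.anchor_residues[r] - 1].copy() for r, _ in slices}
    zhat = np.array([0.0, 0.0, 1.0])

    frames = np.empty((motion.n_frames, structure.n_atoms, 3))
    for t in range(motion.n_frames):
        phase = np.sin(2.0 * np.pi * t / motion.period)
        theta = motion.bend_amplitude * phase
        delta = motion.twist_amplitude * phase
        coords = base.copy()
        for r, sl in slices:
            x = coords[sl]
            if delta != 0.0 and r != mid:
                Rz = rotation_about_axis(zhat, (r - mid) * delta)
                x = (x - anchor_points[r]) @ Rz.T + anchor_points[r]
            if theta != 0.0 and r != mid:
                sign = 1.0 if r < mid else -1.0
                Rh = rotation_about_axis(hdir, sign * theta)
                x = (x - hpoint) @ Rh.T + hpoint
            coords[sl] = x
        if motion.noise_sd > 0:
            coords = coords + rng.normal(0.0, motion.noise_sd, coords.shape)
        frames[t] = coords
    return Trajectory(
        topology=structure,
        frames=frames,
        times=np.arange(motion.n_frames, dtype=float),
        source_id=f"synthetic-seed{motion.seed}",
    )


# ---------------------------------------------------------------------------
# Bound peptide with a scheduled contact inventory
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PeptideSpec:
    """Extended pseudo-peptide: two basic clusters separated by a linker.

    The minor-site cluster sits at the N-proximal end of the groove, the
    major-site cluster at the other; the linker must span at least 10
    residues between them.
    """

    n_residues: int = 18
    minor_cluster: tuple[int, int] = (2, 3)  # residue numbers (chain B)
    major_cluster: tuple[int, int] = (14, 17)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 14:
            raise ValueError("peptide needs >= 14 residues (two clusters + >=10 linker)")
        linker = self.major_cluster[0] - self.minor_cluster[1] - 1
        if linker < 10:
            raise ValueError(f"linker of {linker} residues is shorter than the 10 required")


@dataclasses.dataclass
class ContactEntry:
    contact_id: str
    ctype: str  # salt_bridge | hbond | hydrophobic
    peptide_atoms: list  # list of (chain, resnum, atom_name) moved when broken
    receptor_atom: tuple  # (chain, resnum, atom_name)
    target_occupancy: float
    formed_frames: frozenset = frozenset()
    formed_coords: dict = dataclasses.field(default_factory=dict)  # name key -> xyz
    broken_coords: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class ContactSchedule:
    entries: list
    n_frames: int

    def __post_init__(self) -> None:
        for e in self.entries:
            if not (0.0 <= e.target_occupancy <= 1.0):
                raise ValueError("occupancy must be in [0, 1]")
            if len(e.formed_frames) != round(e.target_occupancy * self.n_frames):
                raise ValueError(
                    f"contact {e.contact_id}: |formed_frames| inconsistent with target occupancy"
                )

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "contacts": [
                {
                    "contact_id": e.contact_id,
                    "type": e.ctype,
                    "peptide_atoms": [list(a) for a in e.peptide_atoms],
                    "receptor_atom": list(e.receptor_atom),
                    "target_occupancy": e.target_occupancy,
                    "formed_frames": sorted(e.formed_frames),
                }
                for e in self.entries
            ],
        }


_DEFAULT_CONTACTS = [
    # (id, type, receptor repeat, peptide residue role)
    ("sb_major", "salt_bridge", 2, "major0"),
    ("hb_major", "hbond", 3, "major1"),
    ("hp_major", "hydrophobic", 4, "linker_c"),
    ("hp_minor", "hydrophobic", 6, "linker_n"),
    ("hb_minor", "hbond", 7, "minor1"),
    ("sb_minor", "salt_bridge", 8, "minor0"),
]

_FORMED_DIST = {"salt_bridge": 3.2, "hbond": 3.0, "hydrophobic": 3.8}
_BROKEN_DIST = {"salt_bridge": 4.6, "hbond": 4.6, "hydrophobic": 5.2}


def build_complex(
    structure: StructureModel,
    annotation: ArmAnnotation,
    spec: SolenoidSpec,
    peptide: PeptideSpec | None = None,
    occupancies: Sequence[float] | None = None,
    n_frames: int = 60,
    seed: int = 0,
) -> tuple[StructureModel, ContactSchedule]:
    """Attach an extended pseudo-peptide along the concave (H3) face.

    The peptide runs antiparallel to the receptor chain along the screw path
    of the solenoid.  For each default contact a designated pair of
    pseudo-atoms is placed so the geometric criterion holds exactly at the
    formed distance and is violated by >= 1 A at the broken distance.
    Returns the complex and a seeded ContactSchedule whose occupancies are
    exact by construction.
    """
    peptide = peptide or PeptideSpec(seed=seed)
    if occupancies is None:
        occupancies = [0.9, 0.75, 0.6, 0.5, 0.4, 0.25][: len(_DEFAULT_CONTACTS)]
    if len(occupancies) != len(_DEFAULT_CONTACTS):
        raise ValueError("need one occupancy per default contact")

    # peptide C-alpha path: follows the solenoid screw at a fixed radius just
    # off the H3 face, numbered antiparallel (descending along +z).
    n_pep = peptide.n_residues
    pep_radius = 3.0 + 4.5  # H3 centroid radius (|superhelix_radius - 5|) + clearance
    pep_radius = abs(spec.superhelix_radius - 5.0) + 4.5
    s_grid = np.linspace(0.8, spec.n_repeats - 1.8, n_pep)
    pep_coords = np.empty((n_pep, 3))
    for j, s in enumerate(s_grid):
        ang = np.radians(spec.repeat_twist * s + 35.0)
        pep_coords[j] = (
            pep_radius * np.cos(ang),
            pep_radius * np.sin(ang),
            spec.repeat_rise * s + 3.0,
        )
    pep_coords = pep_coords[::-1]  # antiparallel numbering

    role_to_res = {
        "minor0": peptide.minor_cluster[0],
        "minor1": peptide.minor_cluster[1],
        "major0": peptide.major_cluster[0],
        "major1": peptide.major_cluster[1],
        "linker_n": peptide.minor_cluster[1] + 3,
        "linker_c": peptide.major_cluster[0] - 3,
    }

    atoms: list[tuple] = []
    serial = structure.n_atoms
    new_coords = [structure.coords]
    new_names = [structure.atom_names]
    new_resnames = [structure.residue_names]
    new_resnums = [structure.residue_numbers]
    new_chains = [structure.chain_ids]
    new_elements = [structure.elements]
    new_masses = [structure.masses]
    new_serials = [structure.serials]
    receptor_resnames = structure.residue_names.copy()

    def add_atom(name, resname, resnum, chain, element, xyz, mass):
        nonlocal serial
        serial += 1
        new_serials.append(np.array([serial]))
        new_names.append(np.array([name], dtype=object))
        new_resnames.append(np.array([resname], dtype=object))
        new_resnums.append(np.array([resnum]))
        new_chains.append(np.array([chain], dtype=object))
        new_elements.append(np.array([element], dtype=object))
        new_coords.append(np.asarray(xyz, float)[None, :])
        new_masses.append(np.array([mass]))

    # peptide C-alpha atoms (chain B); cluster residues are basic (LYS),
    # linker contact residues hydrophobic (LEU), the rest GLY.
    pep_resnames = {}
    for rnum in range(1, n_pep + 1):
        if rnum in (*peptide.minor_cluster, *peptide.major_cluster):
            pep_resnames[rnum] = "LYS"
        elif rnum in (role_to_res["linker_n"], role_to_res["linker_c"]):
            pep_resnames[rnum] = "LEU"
        else:
            pep_resnames[rnum] = "GLY"
    for rnum in range(1, n_pep + 1):
        add_atom("CA", pep_resnames[rnum], rnum, "B", "C", pep_coords[rnum - 1], CARBON_MASS)

    from .elements import mass_of

    entries: list[ContactEntry] = []
    for (cid, ctype, repeat, role), occ in zip(_DEFAULT_CONTACTS, occupancies):
        h3lo, h3hi = annotation.h3_range(repeat)
        rec_res = h3lo + (h3hi - h3lo) // 2
        q = structure.coords[rec_res - 1]
        pep_res = role_to_res[role]
        p = pep_coords[pep_res - 1]
        u = p - q
        u = u / np.linalg.norm(u)
        rec_atom_pos = q + 2.0 * u
        d_on, d_off = _FORMED_DIST[ctype], _BROKEN_DIST[ctype]
        formed: dict = {}
        broken: dict = {}
        if ctype == "salt_bridge":
            receptor_resnames[rec_res - 1] = "GLU"
            add_atom("OE1", "GLU", rec_res, "A", "O", rec_atom_pos, mass_of("O"))
            nz_on = rec_atom_pos + d_on * u
            nz_off = rec_atom_pos + d_off * u
            add_atom("NZ", pep_resnames[pep_res], pep_res, "B", "N", nz_on, mass_of("N"))
            pep_atoms = [("B", pep_res, "NZ")]
            formed["NZ"], broken["NZ"] = nz_on, nz_off
            receptor_atom = ("A", rec_res, "OE1")
        elif ctype == "hbond":
            receptor_resnames[rec_res - 1] = "SER"
            add_atom("OG", "SER", rec_res, "A", "O", rec_atom_pos, mass_of("O"))
            n_on = rec_atom_pos + d_on * u
            n_off = rec_atom_pos + d_off * u
            h_on = n_on - 1.0 * u  # on the D->A line: deviation from linear = 0
            h_off = n_off - 1.0 * u
            add_atom("N", pep_resnames[pep_res], pep_res, "B", "N", n_on, mass_of("N"))
            add_atom("H", pep_resnames[pep_res], pep_res, "B", "H", h_on, mass_of("H"))
            pep_atoms = [("B", pep_res, "N"), ("B", pep_res, "H")]
            formed["N"], formed["H"] = n_on, h_on
            broken["N"], broken["H"] = n_off, h_off
            receptor_atom = ("A", rec_res, "OG")
        elif ctype == "hydrophobic":
            receptor_resnames[rec_res - 1] = "TRP"
            add_atom("CZ2", "TRP", rec_res, "A", "C", rec_atom_pos, CARBON_MASS)
            c_on = rec_atom_pos + d_on * u
            c_off = rec_atom_pos + d_off * u
            add_atom("CD1", pep_resnames[pep_res], pep_res, "B", "C", c_on, CARBON_MASS)
            pep_atoms = [("B", pep_res, "CD1")]
            formed["CD1"], broken["CD1"] = c_on, c_off
            receptor_atom = ("A", rec_res, "CZ2")
        else:  # pragma: no cover
            raise ValueError(f"unknown contact type {ctype}")
        entries.append(
            ContactEntry(
                contact_id=cid,
                ctype=ctype,
                peptide_atoms=pep_atoms,
                receptor_atom=receptor_atom,
                target_occupancy=float(occ),
                formed_coords=formed,
                broken_coords=broken,
            )
        )

    new_resnames[0] = receptor_resnames
    model = StructureModel(
        serials=np.concatenate(new_serials),
        atom_names=np.concatenate(new_names),
        residue_names=np.concatenate(new_resnames),
        residue_numbers=np.concatenate(new_resnums),
        chain_ids=np.concatenate(new_chains),
        elements=np.concatenate(new_elements),
        coords=np.concatenate(new_coords),
        masses=np.concatenate(new_masses),
    )
    schedule = make_schedule(entries, n_frames=n_frames, seed=seed)
    return model, schedule


def make_schedule(entries: Iterable[ContactEntry], n_frames: int, seed: int = 0) -> ContactSchedule:
    """Draw formed-frame sets so each contact's occupancy is exact.

    ``target_occupancy * n_frames`` must be integral for every contact.
    """
    rng = np.random.default_rng(seed)
    out = []
    for e in entries:
        k = e.target_occupancy * n_frames
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"contact {e.contact_id}: occupancy {e.target_occupancy} not an exact "
                f"fraction of {n_frames} frames"
            )
        formed = frozenset(rng.choice(n_frames, size=int(round(k)), replace=False).tolist())
        out.append(dataclasses.replace(e, formed_frames=formed))
    return ContactSchedule(entries=out, n_frames=n_frames)


def schedule_trajectory(complex_model: StructureModel, schedule: ContactSchedule) -> Trajectory:
    """Deterministic ensemble realizing the contact schedule.

    In frames where a contact is not formed its peptide-side atoms sit at the
    broken positions (criterion violated by >= 1 A); all other atoms are
    static.
    """
    index = {
        (complex_model.chain_ids[i], int(complex_model.residue_numbers[i]), complex_model.atom_names[i]): i
        for i in range(complex_model.n_atoms)
    }
    frames = np.repeat(complex_model.coords[None, :, :], schedule.n_frames, axis=0)
    for e in schedule.entries:
        for chain, resnum, name in e.peptide_atoms:
            i = index[(chain, resnum, name)]
            for t in range(schedule.n_frames):
                pos = e.formed_coords[name] if t in e.formed_frames else e.broken_coords[name]
                frames[t, i] = pos
    return Trajectory(
        topology=complex_model,
        frames=frames,
        times=np.arange(schedule.n_frames, dtype=float),
        source_id="contact-schedule",
    )


def write_fixture_set(
    out_dir: str | Path,
    spec: SolenoidSpec | None = None,
    motions: Sequence[MotionSpec] | None = None,
    seed: int = 0,
) -> Path:
    """Write a complete fixture set: solenoid, trajectories, complex ensemble
    and a JSON ground-truth sidecar."""
    from .structio import write_pdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or SolenoidSpec(seed=seed)
    structure, annotation = build_solenoid(spec)
    write_pdb(structure, out / "solenoid.pdb")

    motions = motions or [
        MotionSpec(bend_amplitude=8.0, twist_amplitude=0.0, noise_sd=0.1, n_frames=100, seed=seed + i)
        for i in range(3)
    ]
    traj_files = []
    for i, motion in enumerate(motions):
        traj = simulate_trajectory(structure, annotation, motion)
        fname = f"traj_{i}.pdb"
        write_pdb(traj, out / fname)
        traj_files.append(fname)

    cplx, schedule = build_complex(structure, annotation, spec, seed=seed)
    write_pdb(cplx, out / "complex.pdb")
    ensemble = schedule_trajectory(cplx, schedule)
    write_pdb(ensemble, out / "complex_ensemble.pdb")

    truth = {
        "seed": seed,
        "solenoid": dataclasses.asdict(spec),
        "annotation": annotation.to_dict(),
        "motions": [dataclasses.asdict(m) for m in motions],
        "trajectories": traj_files,
        "contact_schedule": schedule.to_dict(),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return out
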