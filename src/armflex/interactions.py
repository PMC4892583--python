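"""Interface contact detection (salt bridges, hydrogen bonds, hydrophobic
contacts) and per-contact occupancy over an ensemble.

All thresholds are inclusive.  A hydrogen bond requires an explicit hydrogen
on the donor; the angle criterion is the deviation of the
donor-hydrogen-acceptor angle from linearity.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .structio import AtomSelection, StructureModel, Trajectory

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_hydrophobic",
    "occupancy_report",
    "records_to_frame",
]

BASIC_RESIDUES = {"LYS", "ARG", "HIS"}
BASIC_N_ATOMS = {"NZ", "NH1", "NH2", "NE", "ND1", "NE2"}
ACIDIC_RESIDUES = {"ASP", "GLU"}
ACIDIC_O_ATOMS = {"OD1", "OD2", "OE1", "OE2"}
# documented default; the hydrophobic set is overridable via function args
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
BACKBONE_ATOMS = {"N", "CA", "C", "O"}
COVALENT_H_MAX = 1.3  # Angstrom, donor-hydrogen bond detection
_EPS = 1e-9  # floating-point slack so printed thresholds stay inclusive


@dataclasses.dataclass
class InteractionCriteria:
    hbond_dist_max: float = 3.5  # donor-acceptor, Angstrom
    hbond_angle_dev_max: float = 60.0  # deviation of D-H-A from 180 degrees
    saltbridge_dist_max: float = 3.5
    hydrophobic_dist_max: float = 4.0
    report_min_occupancy: float = 0.5

    def __post_init__(self) -> None:
        for name in ("hbond_dist_max", "hbond_angle_dev_max", "saltbridge_dist_max", "hydrophobic_dist_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.report_min_occupancy <= 1.0):
            raise ValueError("report_min_occupancy must be in [0, 1]")


@dataclasses.dataclass
class InteractionRecord:
    ctype: str  # salt_bridge | hbond | hydrophobic
    partner_a: tuple  # (chain, resnum, resname, atom)
    partner_b: tuple
    frames_present: int
    total_frames: int

    @property
    def occupancy(self) -> float:
        return self.frames_present / self.total_frames

    @property
    def key(self) -> tuple:
        return (self.ctype, self.partner_a[:2] + (self.partner_a[3],), self.partner_b[:2] + (self.partner_b[3],))


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def detect_hbonds(
    coords: np.ndarray,
    donors: list[tuple[int, int | None]],
    acceptors: list[int],
    criteria: InteractionCriteria | None = None,
    allow_missing_hydrogen: bool = False,
) -> list[tuple[int, int]]:
    """Present (donor, acceptor) index pairs for one frame.

    ``donors`` are (D index, H index) pairs; a donor without a hydrogen is
    skipped with a warning unless the distance-only fallback is enabled.
    Present iff dist(D, A) <= hbond_dist_max and 180 - angle(D, H, A) <=
    hbond_angle_dev_max, both inclusive.
    """
    criteria = criteria or InteractionCriteria()
    present = []
    for d_idx, h_idx in donors:
        if h_idx is None and not allow_missing_hydrogen:
            warnings.warn(f"donor atom {d_idx} has no hydrogen; skipped")
            continue
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            dist = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
            if dist > criteria.hbond_dist_max + _EPS:
                continue
            if h_idx is not None:
                deviation = 180.0 - _angle_deg(coords[d_idx], coords[h_idx], coords[a_idx])
                if deviation > criteria.hbond_angle_dev_max + _EPS:
                    continue
            present.append((d_idx, a_idx))
    return present


def detect_salt_bridges(
    coords: np.ndarray,
    basic_groups: dict,
    acidic_groups: dict,
    criteria: InteractionCriteria | None = None,
) -> list[tuple]:
    """Present (basic residue key, acidic residue key) pairs for one frame.

    Groups map a residue key to its charged-group atom indices; a pair is
    present iff the minimum N-O distance is within the cutoff (inclusive).
    """
    criteria = criteria or InteractionCriteria()
    if not basic_groups or not acidic_groups:
        raise ValueError("empty charged-group lists")
    present = []
    for bkey, bidx in basic_groups.items():
        for akey, aidx in acidic_groups.items():
            d = np.linalg.norm(coords[np.asarray(bidx)][:, None, :] - coords[np.asarray(aidx)][None, :, :], axis=2)
            if d.min() <= criteria.saltbridge_dist_max + _EPS:
                present.append((bkey, akey))
    return present


def detect_hydrophobic(
    coords: np.ndarray,
    carbons_a: dict,
    carbons_b: dict,
    criteria: InteractionCriteria | None = None,
) -> list[tuple]:
    """Present residue pairs whose closest side-chain carbon-carbon distance
    is within the cutoff (inclusive)."""
    criteria = criteria or InteractionCriteria()
    present = []
    for ka, ia in carbons_a.items():
        if len(ia) == 0:
            warnings.warn(f"residue {ka} has no designated carbons; skipped")
            continue
        for kb, ib in carbons_b.items():
            if len(ib) == 0:
                continue
            d = np.linalg.norm(coords[np.asarray(ia)][:, None, :] - coords[np.asarray(ib)][None, :, :], axis=2)
            if d.min() <= criteria.hydrophobic_dist_max + _EPS:
                present.append((ka, kb))
    return present


# ---------------------------------------------------------------------------
# Candidate enumeration over an interface
# ---------------------------------------------------------------------------

def _residue_key(model: StructureModel, i: int) -> tuple:
    return (model.chain_ids[i], int(model.residue_numbers[i]), model.residue_names[i])


def _donor_list(model: StructureModel, idx: np.ndarray) -> list[tuple[int, int | None]]:
    """(D, H) pairs: N/O atoms with a covalently attached hydrogen."""
    donors = []
    hydrogens = [i for i in idx if model.elements[i] == "H"]
    for i in idx:
        if model.elements[i] not in ("N", "O"):
            continue
        h_found = None
        for h in hydrogens:
            if _residue_key(model, h)[:2] != _residue_key(model, i)[:2]:
                continue
            if np.linalg.norm(model.coords[h] - model.coords[i]) <= COVALENT_H_MAX:
                h_found = h
                break
        if h_found is not None:
            donors.append((i, h_found))
    return donors


def _acceptor_list(model: StructureModel, idx: np.ndarray) -> list[int]:
    return [i for i in idx if model.elements[i] in ("N", "O")]


def _charged_groups(model: StructureModel, idx: np.ndarray, kind: str) -> dict:
    resnames, atoms = (
        (BASIC_RESIDUES, BASIC_N_ATOMS) if kind == "basic" else (ACIDIC_RESIDUES, ACIDIC_O_ATOMS)
    )
    groups: dict = {}
    for i in idx:
        if model.residue_names[i] in resnames and model.atom_names[i] in atoms:
            groups.setdefault(_residue_key(model, i), []).append(i)
    return groups


def _hydrophobic_carbons(model: StructureModel, idx: np.ndarray, residues: set) -> dict:
    groups: dict = {}
    for i in idx:
        if (
            model.residue_names[i] in residues
            and model.elements[i] == "C"
            and model.atom_names[i] not in BACKBONE_ATOMS
        ):
            groups.setdefault(_residue_key(model, i), []).append(i)
    return groups


def occupancy_report(
    ensemble: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    criteria: InteractionCriteria | None = None,
    hydrophobic_residues: set | None = None,
) -> list[InteractionRecord]:
    """Enumerate interface contact candidates and score their occupancy.

    Candidates cross the interface only (one partner in each selection):
    salt bridges between charged residue groups, hydrogen bonds between
    explicit-H donors and N/O acceptors, hydrophobic contacts between
    side-chain carbons of hydrophobic residues.  Returns every candidate
    observed in at least one frame; filter with
    ``[r for r in records if r.occupancy >= criteria.report_min_occupancy]``.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    criteria = criteria or InteractionCriteria()
    hydrophobic_residues = hydrophobic_residues or HYDROPHOBIC_RESIDUES
    model = ensemble.topology
    ia, ib = sel_a.indices, sel_b.indices

    donors_a = _donor_list(model, ia)
    donors_b = _donor_list(model, ib)
    acceptors_a = _acceptor_list(model, ia)
    acceptors_b = _acceptor_list(model, ib)
    basic_a, basic_b = _charged_groups(model, ia, "basic"), _charged_groups(model, ib, "basic")
    acidic_a, acidic_b = _charged_groups(model, ia, "acidic"), _charged_groups(model, ib, "acidic")
    hp_a = _hydrophobic_carbons(model, ia, hydrophobic_residues)
    hp_b = _hydrophobic_carbons(model, ib, hydrophobic_residues)

    # pre-register every candidate so never-formed contacts report occupancy 0
    counts: dict = {}
    for d_idx, _ in donors_a:
        for a_idx in acceptors_b:
            counts[("hbond", d_idx, a_idx)] = 0
    for d_idx, _ in donors_b:
        for a_idx in acceptors_a:
            counts[("hbond", d_idx, a_idx)] = 0
    for bkey in basic_a:
        for akey in acidic_b:
            counts[("salt_bridge", bkey, akey)] = 0
    for bkey in basic_b:
        for akey in acidic_a:
            counts[("salt_bridge", bkey, akey)] = 0
    for ka in hp_a:
        for kb in hp_b:
            counts[("hydrophobic", ka, kb)] = 0

    def bump(key):
        counts[key] = counts.get(key, 0) + 1

    for t in range(ensemble.n_frames):
        coords = ensemble.frames[t]
        for d_idx, a_idx in detect_hbonds(coords, donors_a, acceptors_b, criteria):
            bump(("hbond", d_idx, a_idx))
        for d_idx, a_idx in detect_hbonds(coords, donors_b, acceptors_a, criteria):
            bump(("hbond", d_idx, a_idx))
        if basic_a and acidic_b:
            for bkey, akey in detect_salt_bridges(coords, basic_a, acidic_b, criteria):
                bump(("salt_bridge", bkey, akey))
        if basic_b and acidic_a:
            for bkey, akey in detect_salt_bridges(coords, basic_b, acidic_a, criteria):
                bump(("salt_bridge", bkey, akey))
        if hp_a and hp_b:
            for ka, kb in detect_hydrophobic(coords, hp_a, hp_b, criteria):
                bump(("hydrophobic", ka, kb))

    records = []
    for key, n in sorted(counts.items(), key=lambda kv: repr(kv[0])):
        ctype = key[0]
        if ctype == "hbond":
            d_idx, a_idx = key[1], key[2]
            pa = _residue_key(model, d_idx) + (model.atom_names[d_idx],)
            pb = _residue_key(model, a_idx) + (model.atom_names[a_idx],)
        elif ctype == "salt_bridge":
            bkey, akey = key[1], key[2]
            pa = bkey + (",".join(sorted(model.atom_names[i] for i in (basic_a | basic_b)[bkey])),)
            pb = akey + (",".join(sorted(model.atom_names[i] for i in (acidic_a | acidic_b)[akey])),)
        else:
            ka, kb = key[1], key[2]
            pa = ka + ("*",)
            pb = kb + ("*",)
        records.append(
            InteractionRecord(
                ctype=ctype,
                partner_a=pa,
                partner_b=pb,
                frames_present=n,
                total_frames=ensemble.n_frames,
            )
        )
    return records


def records_to_frame(records: list[InteractionRecord], criteria: InteractionCriteria | None = None) -> pd.DataFrame:
    """Tabulate records with the occupancy-threshold verdict."""
    criteria = criteria or InteractionCriteria()
    rows = []
    for r in records:
        rows.append(
            {
                "type": r.ctype,
                "partner_a": ":".join(str(x) for x in r.partner_a),
                "partner_b": ":".join(str(x) for x in r.partner_b),
                "frames_present": r.frames_present,
                "total_frames": r.total_frames,
                "occupancy": r.occupancy,
                "passes_filter": r.occupancy >= criteria.report_min_occupancy,
            }
        )
    return pd.DataFrame(rows)
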