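"""Bend/twist quantification: radius of curvature from three anchor atoms
and inter-repeat H3 helix-axis angles."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .structio import AtomSelection, StructureModel, Trajectory

__all__ = [
    "CollinearAnchorsError",
    "DegenerateAnchorsError",
    "CurvatureAnchors",
    "HelixVector",
    "radius_of_curvature",
    "fit_helix_vector",
    "inter_repeat_angles",
    "geometry_series",
    "default_anchors",
]


class CollinearAnchorsError(ValueError):
    """Anchors are collinear — infinite radius of curvature."""


class DegenerateAnchorsError(ValueError):
    """Two or more anchors coincide."""


def radius_of_curvature(p_n: np.ndarray, p_m: np.ndarray, p_c: np.ndarray) -> float:
    """Radius of the circle through the two distal anchors and the middle one.

    Solved from the perpendicular-bisector conditions (a 2x2 linear system in
    the triangle plane).  For the isoceles arrangement with distal-to-middle
    distance d and half distal-distal separation m this reduces to
    R = d**2 / (2*sqrt(d**2 - m**2)); larger R means a flatter (more open)
    arrangement.
    """
    p_n = np.asarray(p_n, float)
    p_m = np.asarray(p_m, float)
    p_c = np.asarray(p_c, float)
    a = p_n - p_m
    b = p_c - p_m
    la, lb = np.linalg.norm(a), np.linalg.norm(b)
    if la < 1e-9 or lb < 1e-9 or np.linalg.norm(p_n - p_c) < 1e-9:
        raise DegenerateAnchorsError("coincident anchor points")
    d_mean = 0.5 * (la + lb)
    m_half = 0.5 * np.linalg.norm(p_n - p_c)
    cross = np.linalg.norm(np.cross(a, b))
    scale = max(la, lb)
    if d_mean - m_half < 1e-9 or cross < 1e-9 * scale**2:
        raise CollinearAnchorsError("collinear anchors: infinite radius of curvature")
    # circumcenter = p_m + alpha*a + beta*b with |c-p_m| = |c-p_n| = |c-p_c|
    G = np.array([[a @ a, a @ b], [a @ b, b @ b]])
    rhs = 0.5 * np.array([a @ a, b @ b])
    alpha, beta = np.linalg.solve(G, rhs)
    center = p_m + alpha * a + beta * b
    return float(np.linalg.norm(center - p_m))


@dataclasses.dataclass
class CurvatureAnchors:
    """Three single-atom selections: distal N-side, middle, distal C-side."""

    distal_n: tuple  # (chain, resnum, atom_name)
    middle: tuple
    distal_c: tuple

    def resolve(self, structure: StructureModel) -> tuple[int, int, int]:
        out = []
        for chain, resnum, name in (self.distal_n, self.middle, self.distal_c):
            try:
                sel = AtomSelection.from_predicate(
                    structure, lambda c, r, a, ch=chain, rn=resnum, an=name: c == ch and r == rn and a == an
                )
            except ValueError:
                raise ValueError(f"anchor {(chain, resnum, name)} resolves to 0 atoms") from None
            if len(sel) != 1:
                raise ValueError(f"anchor {(chain, resnum, name)} resolves to {len(sel)} atoms")
            out.append(int(sel.indices[0]))
        return tuple(out)

    def measure(self, structure: StructureModel) -> dict:
        """d (mean distal-to-middle distance), m (half distal separation), R."""
        i, j, k = self.resolve(structure)
        pn, pm, pc = structure.coords[i], structure.coords[j], structure.coords[k]
        d = 0.5 * (np.linalg.norm(pn - pm) + np.linalg.norm(pc - pm))
        m = 0.5 * np.linalg.norm(pn - pc)
        return {"d": float(d), "m": float(m), "R": radius_of_curvature(pn, pm, pc)}


def default_anchors(annotation) -> CurvatureAnchors:
    """Anchor atoms at the first, middle and last repeat's anchor residues."""
    repeats = sorted(annotation.ranges)
    return CurvatureAnchors(
        distal_n=("A", annotation.anchor_residues[repeats[0]], "CA"),
        middle=("A", annotation.anchor_residues[annotation.middle_repeat], "CA"),
        distal_c=("A", annotation.anchor_residues[repeats[-1]], "CA"),
    )


@dataclasses.dataclass
class HelixVector:
    repeat_index: int
    vector: np.ndarray  # unit, N->C oriented
    centroid: np.ndarray


def fit_helix_vector(
    structure: StructureModel,
    residue_range: tuple[int, int],
    chain: str | None = None,
    repeat_index: int = 0,
) -> HelixVector:
    """Dominant principal direction of the C-alpha atoms in a residue range,
    oriented from the N-terminal to the C-terminal end."""
    lo, hi = residue_range
    sel = AtomSelection.from_predicate(
        structure,
        lambda c, r, a: a == "CA" and lo <= r <= hi and (chain is None or c == chain),
    )
    idx = sel.indices
    order = np.argsort(structure.residue_numbers[idx])
    pts = structure.coords[idx[order]]
    if len(pts) < 4:
        raise ValueError(f"helix fit needs >= 4 C-alpha atoms, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise ValueError("degenerate helix: all points coincide")
    v = vt[0]
    if v @ (pts[-1] - pts[0]) < 0:
        v = -v
    return HelixVector(repeat_index=repeat_index, vector=v / np.linalg.norm(v), centroid=centroid)


def _signed_torsion(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> float:
    u = axis / np.linalg.norm(axis)
    a = v1 - (v1 @ u) * u
    b = v2 - (v2 @ u) * u
    return float(np.degrees(np.arctan2(u @ np.cross(a, b), a @ b)))


def inter_repeat_angles(
    structure: StructureModel,
    annotation,
    signed_torsion: bool = True,
) -> pd.DataFrame:
    """Angles between H3 axis vectors of neighboring repeats.

    One row per pair (r, r+1): unsigned angle in [0, 180] degrees and, when
    requested, the signed torsion about the inter-centroid axis in
    (-180, 180].
    """
    repeats = sorted(annotation.ranges)
    vectors = {}
    for r in repeats:
        if "H3" not in annotation.ranges[r]:
            raise ValueError(f"repeat {r} has no H3 annotation")
        vectors[r] = fit_helix_vector(structure, annotation.h3_range(r), repeat_index=r)
    rows = []
    for r in repeats[:-1]:
        hv1, hv2 = vectors[r], vectors[r + 1]
        cosang = np.clip(hv1.vector @ hv2.vector, -1.0, 1.0)
        row = {"pair": f"{r}-{r+1}", "angle": float(np.degrees(np.arccos(cosang)))}
        if signed_torsion:
            row["torsion"] = _signed_torsion(hv1.vector, hv2.vector, hv2.centroid - hv1.centroid)
        rows.append(row)
    return pd.DataFrame(rows)


def geometry_series(
    frames,
    anchors: CurvatureAnchors,
    annotation,
    signed_torsion: bool = True,
) -> pd.DataFrame:
    """Per-frame curvature and inter-repeat angle table.

    ``frames`` may be a Trajectory or a DisplacementSeries.  Columns: frame,
    R, d, m, angle_1..angle_{k}, mean_angle and (optionally) torsion_i.
    """
    from .enm import DisplacementSeries

    if isinstance(frames, Trajectory):
        top, coords = frames.topology, frames.frames
    elif isinstance(frames, DisplacementSeries):
        top, coords = frames.topology, frames.coords
    else:
        raise TypeError("frames must be a Trajectory or DisplacementSeries")

    rows = []
    for t in range(len(coords)):
        model = top.copy(coords=coords[t])
        try:
            row = {"frame": t}
            row.update(anchors.measure(model))
            ang = inter_repeat_angles(model, annotation, signed_torsion=signed_torsion)
            for _, pair_row in ang.iterrows():
                i = pair_row["pair"].split("-")[0]
                row[f"angle_{i}"] = pair_row["angle"]
                if signed_torsion:
                    row[f"torsion_{i}"] = pair_row["torsion"]
            row["mean_angle"] = float(ang["angle"].mean())
            rows.append(row)
        except (CollinearAnchorsError, DegenerateAnchorsError) as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
    return pd.DataFrame(rows)
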