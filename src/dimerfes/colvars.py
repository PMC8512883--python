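"""Collective variables for an aromatic dimer: COG distance, inter-ring torsion,
plane-normal angle — plus PLUMED-style COLVAR text I/O.

Conventions
-----------
* distance: Euclidean distance between the ring-atom centers of geometry,
  minimum image, nm.
* torsion: signed dihedral over (anchor_a, COG_a, COG_b, anchor_b) in (-pi, pi].
  Exchanging the molecule labels flips the sign (standard dihedral behaviour).
* normal angle: angle between the best-fit ring-plane normals, folded to
  [0, pi/2] because a plane normal has no preferred sign. 0 is stacked
  (parallel planes), pi/2 is T-shaped (perpendicular).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .toysystems import DimerState, MoleculeTemplate

__all__ = [
    "CVValue",
    "cog_distance",
    "ring_torsion",
    "normal_angle",
    "dimer_cvs",
    "cvs_from_coords",
    "write_colvar",
    "read_colvar",
]

COLVAR_FIELDS = ["time", "dist", "torsion", "nangle", "bias"]


@dataclass(frozen=True)
class CVValue:
    distance: float  # nm, >= 0
    torsion: float  # rad, (-pi, pi]
    normal_angle: float  # rad, [0, pi/2]


def _plane_normal(ring_coords: np.ndarray) -> np.ndarray:
    """Best-fit plane normal of a set of ring atoms (smallest-variance direction)."""
    centered = ring_coords - ring_coords.mean(axis=0)
    # right-singular vector of the smallest singular value
    _, sv, vt = np.linalg.svd(centered, full_matrices=True)
    if sv[1] < 1e-12:
        raise ValueError("ring atoms are collinear; plane normal undefined")
    return vt[-1]


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle of four points, (-pi, pi] (praxeolitic formulation)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.arctan2(y, x))
    return np.pi if ang == -np.pi else ang


def _min_image_shift(cog_a: np.ndarray, cog_b: np.ndarray, box_edge: float) -> np.ndarray:
    """Lattice shift placing COG_b in the image nearest COG_a."""
    delta = cog_b - cog_a
    return -box_edge * np.round(delta / box_edge)


def cvs_from_coords(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    ring_a,
    ring_b,
    anchor_a: int,
    anchor_b: int,
    box_edge: float,
) -> CVValue:
    """All three CVs from world-frame coordinate arrays.

    Molecule B is shifted coherently to its minimum-image position relative to
    molecule A before any geometry is measured, so the torsion and the normal
    angle see the same image as the distance.
    """
    cog_a = coords_a[ring_a].mean(axis=0)
    cog_b_raw = coords_b[ring_b].mean(axis=0)
    shift = _min_image_shift(cog_a, cog_b_raw, box_edge)
    coords_b = coords_b + shift
    cog_b = cog_b_raw + shift

    dist = float(np.linalg.norm(cog_b - cog_a))
    if dist < 1e-9:
        raise ValueError("COGs coincide; torsion CV undefined")
    torsion = _dihedral(coords_a[anchor_a], cog_a, cog_b, coords_b[anchor_b])

    na = _plane_normal(coords_a[ring_a])
    nb = _plane_normal(coords_b[ring_b])
    cosang = abs(float(np.dot(na, nb)))  # fold: normals are sign-ambiguous
    nang = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return CVValue(distance=dist, torsion=torsion, normal_angle=nang)


def _world(state: DimerState, tmpl_a: MoleculeTemplate, tmpl_b: MoleculeTemplate):
    return state.pose_a.apply(tmpl_a.coords), state.pose_b.apply(tmpl_b.coords)


def dimer_cvs(state: DimerState, tmpl_a: MoleculeTemplate, tmpl_b: MoleculeTemplate) -> CVValue:
    """All three CVs of a dimer state."""
    ca, cb = _world(state, tmpl_a, tmpl_b)
    return cvs_from_coords(
        ca, cb,
        tmpl_a.ring_atom_indices, tmpl_b.ring_atom_indices,
        tmpl_a.dihedral_anchor_index, tmpl_b.dihedral_anchor_index,
        state.box_edge,
    )


def cog_distance(state: DimerState, tmpl_a: MoleculeTemplate, tmpl_b: MoleculeTemplate) -> float:
    """Minimum-image distance between the two ring-atom COGs, nm."""
    ca, cb = _world(state, tmpl_a, tmpl_b)
    cog_a = ca[tmpl_a.ring_atom_indices].mean(axis=0)
    cog_b = cb[tmpl_b.ring_atom_indices].mean(axis=0)
    delta = cog_b - cog_a
    delta -= state.box_edge * np.round(delta / state.box_edge)
    return float(np.linalg.norm(delta))


def ring_torsion(state: DimerState, tmpl_a: MoleculeTemplate, tmpl_b: MoleculeTemplate) -> float:
    """Signed dihedral over (anchor_a, COG_a, COG_b, anchor_b), rad in (-pi, pi]."""
    return dimer_cvs(state, tmpl_a, tmpl_b).torsion


def normal_angle(state: DimerState, tmpl_a: MoleculeTemplate, tmpl_b: MoleculeTemplate) -> float:
    """Angle between the best-fit ring-plane normals, folded to [0, pi/2], rad."""
    return dimer_cvs(state, tmpl_a, tmpl_b).normal_angle


def write_colvar(path, time, dist, torsion, nangle, bias, header_extra: str | None = None) -> None:
    """Write a CV time series as PLUMED-style COLVAR text."""
    cols = np.column_stack([time, dist, torsion, nangle, bias])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(COLVAR_FIELDS) + "\n")
        if header_extra:
            fh.write(f"# {header_extra}\n")
        np.savetxt(fh, cols, fmt="%.10g")


def read_colvar(path):
    """Read a COLVAR file; returns a dict of column name -> array."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing '#! FIELDS' COLVAR header")
        fields = first.split()[2:]
        data = np.loadtxt(fh, comments="#", ndmin=2)
    if data.size == 0:
        return {f: np.empty(0) for f in fields}
    if data.shape[1] != len(fields):
        raise ValueError(f"{path}: {data.shape[1]} columns but {len(fields)} FIELDS")
    return {f: data[:, i] for i, f in enumerate(fields)}
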