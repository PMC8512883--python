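"""Synthetic rigid planar aromatic molecules and the plain-text formats they travel in.

The molecules here are desk-scale stand-ins for server-parameterized aromatic
compounds: flat carbon-only rings (benzene-like hexagon up to a linear
tetracene-like four-ring acene) carrying merged, uniform nonbonded parameters.
Hydrogens are omitted; the pipeline, not the chemistry, is under test.

Formats:

* topology — ``molecule <name>`` / ``ring <indices>`` / ``anchor <index>``
  header lines followed by one ``name x y z sigma epsilon charge`` line per
  atom (nm, nm, kJ/mol, e; 0-based indices).
* XYZ — standard dialect, coordinates in Angstrom on disk, nm in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomSpec",
    "MoleculeTemplate",
    "Pose",
    "DimerState",
    "make_ring_template",
    "read_topology",
    "write_topology",
    "read_xyz",
    "write_xyz",
    "random_unit_quaternion",
]

#: nm per Angstrom (XYZ files are written in Angstrom).
_NM_PER_ANGSTROM = 0.1

# Merged carbon-like nonbonded parameters per "param style".
_PARAM_STYLES = {
    "generic": {"sigma": 0.355, "epsilon": 0.29, "charge": 0.0},
    # Ideal-gas style: geometry only, no interactions.
    "ideal": {"sigma": 0.355, "epsilon": 0.0, "charge": 0.0},
}


@dataclass(frozen=True)
class AtomSpec:
    """One rigid-body atom: body-frame position plus nonbonded parameters.

    Positions are nm in the molecule's body frame; ``sigma`` (nm) and
    ``epsilon`` (kJ/mol) are Lennard-Jones parameters; ``charge`` is the
    partial charge in e.
    """

    name: str
    position: np.ndarray
    sigma: float
    epsilon: float
    charge: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"atom {self.name!r}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name!r}: non-finite position")
        if self.sigma <= 0:
            raise ValueError(f"atom {self.name!r}: sigma must be > 0 (got {self.sigma})")
        if self.epsilon < 0:
            raise ValueError(f"atom {self.name!r}: epsilon must be >= 0 (got {self.epsilon})")
        object.__setattr__(self, "position", pos)


@dataclass
class MoleculeTemplate:
    """A rigid planar molecule in its body frame.

    ``ring_atom_indices`` select the atoms defining the aromatic plane; their
    center of geometry must sit at the body-frame origin. ``dihedral_anchor_index``
    names the single ring atom used, together with the two ring COGs, to define
    the inter-ring torsion collective variable.
    """

    name: str
    atoms: list[AtomSpec]
    ring_atom_indices: list[int]
    dihedral_anchor_index: int = 0
    net_charge: float = 0.0

    def __post_init__(self):
        n = len(self.atoms)
        if len(self.ring_atom_indices) < 3:
            raise ValueError("molecule must have at least 3 ring atoms to define a plane")
        if any(i < 0 or i >= n for i in self.ring_atom_indices):
            raise ValueError("ring atom index out of range")
        if not (0 <= self.dihedral_anchor_index < n):
            raise ValueError("dihedral anchor index out of range")
        ring = self.ring_coords
        centered = ring - ring.mean(axis=0)
        # Non-collinearity: two significant singular values needed for a plane.
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] < 1e-9:
            raise ValueError("ring atoms are collinear; plane normal undefined")
        if np.linalg.norm(ring.mean(axis=0)) > 1e-9:
            raise ValueError("ring-atom COG must be at the body-frame origin")
        qsum = sum(a.charge for a in self.atoms)
        if abs(qsum - self.net_charge) > 1e-6:
            raise ValueError(
                f"net_charge {self.net_charge} does not match atom charge sum {qsum}"
            )

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) body-frame coordinates, nm."""
        return np.array([a.position for a in self.atoms])

    @property
    def ring_coords(self) -> np.ndarray:
        return np.array([self.atoms[i].position for i in self.ring_atom_indices])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([a.sigma for a in self.atoms])

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([a.epsilon for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radius(self) -> float:
        """Largest body-frame atom distance from the origin, nm."""
        return float(np.linalg.norm(self.coords, axis=1).max())


def _normalize_quaternion(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("quaternion must have 4 components (x, y, z, w)")
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"quaternion must have unit norm (|q| = {norm})")
    return q


@dataclass
class Pose:
    """Rigid-body placement: translation (nm) and unit quaternion (x, y, z, w)."""

    translation: np.ndarray
    quaternion: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.translation, dtype=float)
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        self.translation = t
        self.quaternion = _normalize_quaternion(self.quaternion)

    def rotation_matrix(self) -> np.ndarray:
        from scipy.spatial.transform import Rotation

        return Rotation.from_quat(self.quaternion).as_matrix()

    def apply(self, body_coords: np.ndarray) -> np.ndarray:
        """World-frame coordinates of body-frame points."""
        return body_coords @ self.rotation_matrix().T + self.translation


@dataclass
class DimerState:
    """Poses of two rigid molecules in a cubic periodic box of edge ``box_edge`` nm."""

    pose_a: Pose
    pose_b: Pose
    box_edge: float = 5.0

    def __post_init__(self):
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation as a unit quaternion (x, y, z, w)."""
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def make_ring_template(
    n_fused_rings: int,
    bond_length: float = 0.14,
    param_style: str = "generic",
    name: str | None = None,
) -> MoleculeTemplate:
    """Build a planar linear-acene carbon skeleton with 1..4 fused six-rings.

    One ring is a regular hexagon with circumradius equal to ``bond_length``;
    each additional fused ring shares a vertical edge with its neighbour and
    contributes 4 new atoms (6, 10, 14, 18 atoms for 1..4 rings). All atoms
    are ring atoms with uniform carbon-like parameters from ``param_style``
    and zero net charge. The ring-atom COG is moved to the body-frame origin.
    """
    if n_fused_rings not in (1, 2, 3, 4):
        raise ValueError(f"n_fused_rings must be in 1..4 (got {n_fused_rings})")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    if param_style not in _PARAM_STYLES:
        raise ValueError(
            f"unknown param_style {param_style!r}; choose from {sorted(_PARAM_STYLES)}"
        )
    p = _PARAM_STYLES[param_style]
    L = bond_length
    h = L * math.sqrt(3) / 2  # half the ring-center spacing

    # First hexagon, oriented with vertical edges at x = +-h.
    pts = [
        (h, L / 2),
        (0.0, L),
        (-h, L / 2),
        (-h, -L / 2),
        (0.0, -L),
        (h, -L / 2),
    ]
    # Each fused ring reuses the previous ring's right vertical edge and adds
    # the four remaining vertices.
    for k in range(1, n_fused_rings):
        xc = 2 * h * k
        pts.extend([(xc, L), (xc + h, L / 2), (xc + h, -L / 2), (xc, -L)])

    coords = np.array([(x, y, 0.0) for x, y in pts])
    coords -= coords.mean(axis=0)
    atoms = [
        AtomSpec(name=f"C{i}", position=c, sigma=p["sigma"], epsilon=p["epsilon"], charge=p["charge"])
        for i, c in enumerate(coords)
    ]
    if name is None:
        name = {1: "ring1", 2: "ring2", 3: "ring3", 4: "ring4"}[n_fused_rings]
    return MoleculeTemplate(
        name=name,
        atoms=atoms,
        ring_atom_indices=list(range(len(atoms))),
        dihedral_anchor_index=0,
        net_charge=0.0,
    )


def write_topology(template: MoleculeTemplate, path) -> None:
    """Serialize a template in the package's plain-text topology format."""
    lines = [
        f"molecule {template.name}",
        "ring " + " ".join(str(i) for i in template.ring_atom_indices),
        f"anchor {template.dihedral_anchor_index}",
    ]
    for a in template.atoms:
        x, y, z = a.position
        lines.append(
            f"{a.name} {x:.12g} {y:.12g} {z:.12g} {a.sigma:.12g} {a.epsilon:.12g} {a.charge:.12g}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_topology(path) -> MoleculeTemplate:
    """Parse the topology format written by :func:`write_topology`.

    Malformed lines raise :class:`ValueError` naming the line number;
    violated template invariants surface as the invariant's own message.
    """
    name = None
    ring: list[int] | None = None
    anchor = 0
    atoms: list[AtomSpec] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            try:
                if tok[0] == "molecule":
                    name = tok[1]
                elif tok[0] == "ring":
                    ring = [int(t) for t in tok[1:]]
                elif tok[0] == "anchor":
                    anchor = int(tok[1])
                else:
                    if len(tok) != 7:
                        raise ValueError("expected 'name x y z sigma epsilon charge'")
                    atoms.append(
                        AtomSpec(
                            name=tok[0],
                            position=np.array([float(tok[1]), float(tok[2]), float(tok[3])]),
                            sigma=float(tok[4]),
                            epsilon=float(tok[5]),
                            charge=float(tok[6]),
                        )
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed topology line {lineno}: {raw.rstrip()!r} ({exc})") from exc
    if name is None or ring is None or not atoms:
        raise ValueError(f"{path}: incomplete topology (need molecule, ring and atom lines)")
    net_charge = float(sum(a.charge for a in atoms))
    return MoleculeTemplate(
        name=name,
        atoms=atoms,
        ring_atom_indices=ring,
        dihedral_anchor_index=anchor,
        net_charge=net_charge,
    )


def write_xyz(frames, path, labels=None, comment: str = "") -> None:
    """Write one or more coordinate frames as a standard XYZ file.

    ``frames`` is an (n_atoms, 3) array or a sequence of them, in nm;
    coordinates are converted to Angstrom on disk per the XYZ convention.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_atoms = frames.shape[1]
    if labels is None:
        labels = ["C"] * n_atoms
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{n_atoms}\n{comment}\n")
            for lab, (x, y, z) in zip(labels, frame / _NM_PER_ANGSTROM):
                fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path):
    """Read an XYZ file; returns (labels, frames) with frames (n_frames, n_atoms, 3) in nm."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines]
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"{path}: empty XYZ file")
    frames = []
    labels = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 1}: expected atom count") from exc
        atom_lines = lines[i + 2 : i + 2 + count]
        if len(atom_lines) < count:
            raise ValueError(
                f"{path}: frame starting at line {i + 1} declares {count} atoms "
                f"but only {len(atom_lines)} lines follow"
            )
        labs, coords = [], []
        for ln in atom_lines:
            tok = ln.split()
            if len(tok) < 4:
                raise ValueError(f"{path}: malformed atom line {ln!r}")
            labs.append(tok[0])
            coords.append([float(tok[1]), float(tok[2]), float(tok[3])])
        labels = labs
        frames.append(np.array(coords) * _NM_PER_ANGSTROM)
        i += 2 + count
    return labels, np.array(frames)
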