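"""Nonbonded energy of a rigid aromatic dimer: Lennard-Jones + reaction-field Coulomb.

Molecules are rigid, so the bonded terms of a molecular-mechanics Hamiltonian
vanish identically and the dimer energy is the sum over intermolecular atom
pairs of a plainly truncated LJ term and a constant-shifted reaction-field
Coulomb term, under the minimum-image convention in a cubic box. A one-sided
harmonic "upper wall" on the center-of-geometry distance keeps the molecules
from drifting past the second interaction shell.

Defaults mirror a common explicit-solvent general setup: 1.4 nm cutoff for
both terms, reaction-field dielectric eps_rf = 54, 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_CONSTANT, DEFAULT_TEMPERATURE
from .toysystems import DimerState, MoleculeTemplate

__all__ = [
    "NonbondedConfig",
    "WallConfig",
    "lj_pair",
    "coulomb_rf_pair",
    "dimer_energy",
    "pair_energy_tables",
    "dimer_energy_from_coords",
    "wall_energy",
]


@dataclass
class NonbondedConfig:
    """Cutoffs, dielectric, mixing rule and temperature for nonbonded terms."""

    cutoff: float = 1.4  # nm, for both LJ and Coulomb
    epsilon_rf: float = 54.0
    coulomb_constant: float = COULOMB_CONSTANT
    combination_rule: str = "lorentz_berthelot"
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.epsilon_rf <= 1:
            raise ValueError("epsilon_rf must exceed 1")
        if self.combination_rule not in ("lorentz_berthelot", "geometric"):
            raise ValueError(
                f"unknown combination rule {self.combination_rule!r} "
                "(use 'lorentz_berthelot' or 'geometric')"
            )

    @property
    def k_rf(self) -> float:
        """Reaction-field quadratic coefficient, nm^-3."""
        rc = self.cutoff
        return (self.epsilon_rf - 1.0) / ((2.0 * self.epsilon_rf + 1.0) * rc**3)

    @property
    def c_rf(self) -> float:
        """Constant shift making the RF potential vanish at the cutoff, nm^-1."""
        rc = self.cutoff
        return 1.0 / rc + self.k_rf * rc**2


@dataclass
class WallConfig:
    """One-sided harmonic restraint V = k/2 (r - r0)^2 for r > r0."""

    r0: float = 2.0  # nm
    k: float = 200.0  # kJ mol^-1 nm^-2

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("wall onset r0 must be positive")
        if self.k < 0:
            raise ValueError("wall force constant must be >= 0")


def lj_pair(r, sigma_ij, epsilon_ij, cutoff: float = np.inf):
    """12-6 Lennard-Jones energy 4*eps*[(sigma/r)^12 - (sigma/r)^6], kJ/mol.

    Plain truncation: zero beyond ``cutoff``. Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (np.asarray(sigma_ij) / r) ** 6
    e = 4.0 * np.asarray(epsilon_ij) * (sr6**2 - sr6)
    return np.where(r <= cutoff, e, 0.0) if np.ndim(e) else (float(e) if r <= cutoff else 0.0)


def coulomb_rf_pair(r, qi, qj, cfg: NonbondedConfig):
    """Reaction-field Coulomb energy f*qi*qj*(1/r + k_rf r^2 - c_rf), kJ/mol.

    The constant shift c_rf makes the potential continuous (zero) at the
    cutoff; beyond the cutoff the energy is zero.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    e = cfg.coulomb_constant * np.asarray(qi) * np.asarray(qj) * (
        1.0 / r + cfg.k_rf * r**2 - cfg.c_rf
    )
    if np.ndim(e):
        return np.where(r <= cfg.cutoff, e, 0.0)
    return float(e) if r <= cfg.cutoff else 0.0


def wall_energy(r: float, wall: WallConfig) -> float:
    """Upper-wall energy on a distance CV: 0 below the onset, harmonic beyond."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    dr = r - wall.r0
    return 0.5 * wall.k * dr * dr if dr > 0 else 0.0


def pair_energy_tables(tmpl_a: MoleculeTemplate, tmpl_b: MoleculeTemplate, cfg: NonbondedConfig):
    """Precombined per-pair parameter tables (sigma_ij, eps_ij, f*qi*qj).

    Shapes are (n_a, n_b); combining once up front keeps the Monte Carlo
    inner loop free of rule dispatch.
    """
    sa, sb = tmpl_a.sigmas, tmpl_b.sigmas
    ea, eb = tmpl_a.epsilons, tmpl_b.epsilons
    if cfg.combination_rule == "lorentz_berthelot":
        sigma_ij = 0.5 * (sa[:, None] + sb[None, :])
    else:  # geometric (OPLS-style)
        sigma_ij = np.sqrt(sa[:, None] * sb[None, :])
    eps_ij = np.sqrt(ea[:, None] * eb[None, :])
    qq_ij = cfg.coulomb_constant * tmpl_a.charges[:, None] * tmpl_b.charges[None, :]
    return sigma_ij, eps_ij, qq_ij


def dimer_energy_from_coords(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    sigma_ij: np.ndarray,
    eps_ij: np.ndarray,
    qq_ij: np.ndarray,
    box_edge: float,
    cfg: NonbondedConfig,
) -> float:
    """Intermolecular nonbonded energy from world-frame coordinates.

    Minimum-image displacement per atom pair in a cubic box. Atom overlap
    (r < 1e-6 nm) is rejected with the offending pair named.
    """
    delta = coords_a[:, None, :] - coords_b[None, :, :]
    delta -= box_edge * np.round(delta / box_edge)
    r = np.sqrt((delta**2).sum(axis=-1))
    if np.any(r < 1e-6):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ValueError(f"overlapping atoms: pair ({i}, {j}) at r = {r[i, j]:.2e} nm")
    within = r <= cfg.cutoff
    if not np.any(within):
        return 0.0
    rw = r[within]
    sr6 = (sigma_ij[within] / rw) ** 6
    e_lj = 4.0 * eps_ij[within] * (sr6**2 - sr6)
    e_coul = qq_ij[within] * (1.0 / rw + cfg.k_rf * rw**2 - cfg.c_rf)
    return float(e_lj.sum() + e_coul.sum())


def dimer_energy(
    state: DimerState,
    tmpl_a: MoleculeTemplate,
    tmpl_b: MoleculeTemplate,
    cfg: NonbondedConfig | None = None,
) -> float:
    """Total intermolecular LJ + reaction-field Coulomb energy of a dimer pose."""
    cfg = cfg or NonbondedConfig()
    coords_a = state.pose_a.apply(tmpl_a.coords)
    coords_b = state.pose_b.apply(tmpl_b.coords)
    tables = pair_energy_tables(tmpl_a, tmpl_b, cfg)
    return dimer_energy_from_coords(coords_a, coords_b, *tables, state.box_edge, cfg)
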