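"""Desk-scale biased samplers.

Two channels replace explicit-solvent molecular dynamics:

* :func:`mc_sample` — rigid-body Metropolis Monte Carlo of a molecular dimer
  on the full nonbonded potential (plus wall and, optionally, a metadynamics
  bias on the distance/torsion pair). One MC move plays the role of one MD
  step for stride accounting. The inner loop is numba-compiled; hills are
  deposited from Python at chunk boundaries so the bias is frozen in between.
* :func:`langevin_cv_sample` — overdamped Euler–Maruyama dynamics directly in
  CV space on an analytic potential; the validation channel for the
  metadynamics engine, where the exact free energy is known in closed form.

Both are strictly reproducible given a seed. Frames that coincide with a
deposition step are recorded *before* the new hill lands, so the stored bias
column is the bias that actually acted on the frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .colvars import _plane_normal
from .constants import DEFAULT_TEMPERATURE, kT
from .energetics import (
    NonbondedConfig,
    WallConfig,
    dimer_energy_from_coords,
    pair_energy_tables,
    wall_energy,
)
from .toysystems import MoleculeTemplate, random_unit_quaternion
from .wtmetad import BiasGrid

__all__ = [
    "SamplerConfig",
    "CVTrajectory",
    "metropolis_accept",
    "mc_sample",
    "metropolis_cv_sample",
    "langevin_cv_sample",
]

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Shared sampler settings; the seed is mandatory (no silent entropy)."""

    n_steps: int
    seed: int
    record_stride: int = 10
    max_translation: float = 0.25  # nm per MC move
    max_rotation: float = 0.5  # rad per MC move
    langevin_dt: float = 5e-4  # CV-time units
    langevin_friction: float = 1.0  # inverse CV-time
    temperature: float = DEFAULT_TEMPERATURE
    tune_moves: bool = True
    burn_in: int = 5000  # MC tuning steps, discarded

    def __post_init__(self):
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.record_stride <= 0:
            raise ValueError("record_stride must be positive")
        if self.seed is None:
            raise ValueError("a seed is required")


@dataclass
class CVTrajectory:
    """Per-frame CV record: time index, CV values, instantaneous bias (kJ/mol)."""

    time: np.ndarray
    cvs: np.ndarray  # (n_frames, n_cvs)
    cv_names: tuple[str, ...]
    bias: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time)
        self.cvs = np.atleast_2d(np.asarray(self.cvs, dtype=float))
        self.bias = np.asarray(self.bias, dtype=float)
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.bias)):
            raise ValueError("bias values must be finite")

    def __len__(self):
        return len(self.time)

    def column(self, name: str) -> np.ndarray:
        return self.cvs[:, self.cv_names.index(name)]

    @property
    def distance(self) -> np.ndarray:
        return self.column("dist")

    @property
    def torsion(self) -> np.ndarray:
        return self.column("torsion")

    @property
    def normal_angle(self) -> np.ndarray:
        return self.column("nangle")

    def to_colvar(self, path, header_extra: str | None = None) -> None:
        cols = np.column_stack([self.time, self.cvs, self.bias])
        fields = ["time", *self.cv_names, "bias"]
        with open(path, "w") as fh:
            fh.write("#! FIELDS " + " ".join(fields) + "\n")
            if header_extra:
                fh.write(f"# {header_extra}\n")
            np.savetxt(fh, cols, fmt="%.10g")

    @classmethod
    def from_colvar(cls, path, meta=None) -> "CVTrajectory":
        from .colvars import read_colvar

        cols = read_colvar(path)
        names = [n for n in cols if n not in ("time", "bias")]
        cvs = (
            np.column_stack([cols[n] for n in names])
            if names
            else np.empty((len(cols["time"]), 0))
        )
        return cls(
            time=cols["time"],
            cvs=cvs,
            cv_names=tuple(names),
            bias=cols.get("bias", np.zeros(len(cols["time"]))),
            meta=meta or {},
        )


def metropolis_accept(delta_u: float, kt: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min(1, exp(-dU/kT))."""
    if delta_u <= 0:
        return True
    return rng.random() < math.exp(-delta_u / kt)


def _initial_dimer(tmpl_a, tmpl_b, rng):
    """Starting coordinates: stacked at 1.0 nm separation, random orientations."""
    from scipy.spatial.transform import Rotation

    Ra = Rotation.from_quat(random_unit_quaternion(rng)).as_matrix()
    Rb = Rotation.from_quat(random_unit_quaternion(rng)).as_matrix()
    coords_a = tmpl_a.coords @ Ra.T
    coords_b = tmpl_b.coords @ Rb.T + np.array([0.0, 0.0, 1.0])
    return coords_a, coords_b


def mc_sample(
    tmpl_a: MoleculeTemplate,
    tmpl_b: MoleculeTemplate,
    cfg: SamplerConfig,
    nb_cfg: NonbondedConfig | None = None,
    wall: WallConfig | None = None,
    box_edge: float = 5.0,
    bias_grid: BiasGrid | None = None,
    deposit: bool = False,
) -> CVTrajectory:
    """Metropolis Monte Carlo of a rigid dimer, optionally under a growing bias.

    Alternates single-molecule translation and rotation moves with the
    acceptance rule exp(-dU/kT) on U = nonbonded + wall + bias. When
    ``deposit`` is true a well-tempered hill is added to ``bias_grid`` every
    ``bias_grid.deposition_stride`` moves; the bias is frozen in between.
    Move sizes are tuned toward 30–50% acceptance during a discarded burn-in,
    then frozen (continued tuning would break detailed balance).

    Returns the recorded :class:`CVTrajectory` (columns dist/torsion/nangle).
    """
    from ._mcfast import run_chunk

    nb_cfg = nb_cfg or NonbondedConfig(temperature=cfg.temperature)
    wall = wall or WallConfig()
    if deposit and bias_grid is None:
        raise ValueError("deposit=True requires a bias_grid")
    if deposit and bias_grid.deposition_stride % cfg.record_stride != 0:
        raise ValueError("record_stride must divide the deposition stride")
    if bias_grid is not None:
        if len(bias_grid.axes) != 2 or bias_grid.axes[1].periodic is False:
            raise ValueError("mc_sample expects a distance x torsion (periodic) bias grid")
    rng = np.random.default_rng(cfg.seed)
    kt = kT(cfg.temperature)

    coords_a, coords_b = _initial_dimer(tmpl_a, tmpl_b, rng)
    ring_a = np.asarray(tmpl_a.ring_atom_indices, dtype=np.int64)
    ring_b = np.asarray(tmpl_b.ring_atom_indices, dtype=np.int64)
    normal_a = _plane_normal(coords_a[ring_a]).copy()
    normal_b = _plane_normal(coords_b[ring_b]).copy()
    sigma_ij, eps_ij, qq_ij = pair_energy_tables(tmpl_a, tmpl_b, nb_cfg)

    if bias_grid is not None:
        ax0, ax1 = bias_grid.axes
        bias_args = (
            True, bias_grid.values,
            ax0.lo, ax0.spacing, ax0.n_nodes,
            ax1.lo, ax1.spacing, ax1.n_nodes,
        )
    else:
        bias_args = (False, np.zeros((2, 2)), 0.0, 1.0, 2, 0.0, 1.0, 2)

    def current_energy():
        u = dimer_energy_from_coords(
            coords_a, coords_b, sigma_ij, eps_ij, qq_ij, box_edge, nb_cfg
        )
        cog_a = coords_a[ring_a].mean(axis=0)
        cog_b = coords_b[ring_b].mean(axis=0)
        delta = cog_b - cog_a
        delta -= box_edge * np.round(delta / box_edge)
        dist = float(np.linalg.norm(delta))
        u += wall_energy(dist, wall)
        if bias_grid is not None:
            from .colvars import _dihedral

            cog_b_img = cog_a + delta
            shift = cog_b_img - cog_b
            torsion = _dihedral(
                coords_a[tmpl_a.dihedral_anchor_index], cog_a, cog_b_img,
                coords_b[tmpl_b.dihedral_anchor_index] + shift,
            )
            u += bias_grid.bias_at((dist, torsion))
        else:
            torsion = 0.0
        return u, dist, torsion

    cur_energy, _, _ = current_energy()

    def run_steps(n, step0, max_trans, max_rot, record_stride):
        uniforms = rng.random((n, 5))
        gauss = rng.standard_normal((n, 3))
        max_rec = n // record_stride + 2 if record_stride > 0 else 1
        rec_t = np.zeros(max_rec, dtype=np.int64)
        rec_cv = np.zeros((max_rec, 3))
        rec_bias = np.zeros(max_rec)
        nonlocal cur_energy
        accepted, n_rec, cur_energy = run_chunk(
            coords_a, coords_b, normal_a, normal_b, ring_a, ring_b,
            tmpl_a.dihedral_anchor_index, tmpl_b.dihedral_anchor_index,
            sigma_ij, eps_ij, qq_ij,
            box_edge, nb_cfg.cutoff**2, nb_cfg.k_rf, nb_cfg.c_rf,
            wall.r0, wall.k, kt,
            *bias_args,
            uniforms, gauss, n, step0, max_trans, max_rot,
            record_stride, rec_t, rec_cv, rec_bias, cur_energy,
        )
        return accepted, rec_t[:n_rec], rec_cv[:n_rec], rec_bias[:n_rec]

    # Burn-in with move-size tuning toward 30-50% acceptance, then freeze.
    max_trans, max_rot = cfg.max_translation, cfg.max_rotation
    if cfg.tune_moves and cfg.burn_in > 0:
        window = 500
        for w0 in range(0, cfg.burn_in, window):
            n = min(window, cfg.burn_in - w0)
            accepted, *_ = run_steps(n, w0, max_trans, max_rot, 0)
            rate = accepted / n
            factor = 1.25 if rate > 0.5 else (0.8 if rate < 0.3 else 1.0)
            max_trans = min(max_trans * factor, 0.5)
            max_rot = min(max_rot * factor, math.pi)

    chunk = bias_grid.deposition_stride if deposit else 20_000
    times, rows, biases = [], [], []
    accepted_total = 0
    step = 0
    while step < cfg.n_steps:
        n = min(chunk, cfg.n_steps - step)
        accepted, t, cv, b = run_steps(n, step, max_trans, max_rot, cfg.record_stride)
        accepted_total += accepted
        if accepted == 0 and n >= 1000:
            logger.warning("zero acceptance over the last %d MC moves", n)
        times.append(t)
        rows.append(cv)
        biases.append(b)
        step += n
        if deposit and step % bias_grid.deposition_stride == 0:
            # Deposit at the current chain state; the chunk length guarantees
            # the last recorded frame is that state.
            _, dist, torsion = current_energy()
            old = bias_grid.bias_at((dist, torsion))
            bias_grid.deposit_hill((dist, torsion), step_index=step)
            cur_energy += bias_grid.bias_at((dist, torsion)) - old

    times = np.concatenate(times)
    rows = np.concatenate(rows)
    biases = np.concatenate(biases)
    return CVTrajectory(
        time=times,
        cvs=rows,
        cv_names=("dist", "torsion", "nangle"),
        bias=biases,
        meta={
            "sampler": "mc",
            "seed": cfg.seed,
            "temperature": cfg.temperature,
            "acceptance": accepted_total / cfg.n_steps,
            "max_translation": max_trans,
            "max_rotation": max_rot,
            "bias_factor": bias_grid.bias_factor if bias_grid else None,
        },
    )


def metropolis_cv_sample(
    potential_fn,
    cfg: SamplerConfig,
    bounds=(-2.0, 2.0),
    step_size: float = 0.1,
    start: float = 0.0,
    cv_name: str = "s",
) -> CVTrajectory:
    """Plain 1-D Metropolis sampling of an unbiased CV-space potential.

    A small utility channel for closed-form checks (harmonic variance,
    two-state populations); shares the acceptance rule with :func:`mc_sample`.
    """
    rng = np.random.default_rng(cfg.seed)
    kt = kT(cfg.temperature)
    s = float(start)
    u = float(potential_fn(s))
    times, vals = [], []
    for step in range(1, cfg.n_steps + 1):
        s_new = s + rng.uniform(-step_size, step_size)
        if bounds[0] <= s_new <= bounds[1]:
            u_new = float(potential_fn(s_new))
            if metropolis_accept(u_new - u, kt, rng):
                s, u = s_new, u_new
        if step % cfg.record_stride == 0:
            times.append(step)
            vals.append(s)
    return CVTrajectory(
        time=np.array(times),
        cvs=np.array(vals)[:, None],
        cv_names=(cv_name,),
        bias=np.zeros(len(times)),
        meta={"sampler": "metropolis_cv", "seed": cfg.seed, "temperature": cfg.temperature},
    )


def langevin_cv_sample(
    potential,
    cfg: SamplerConfig,
    bounds=(-1.7, 1.7),
    bias_grid: BiasGrid | None = None,
    deposit: bool = False,
    start: float | None = None,
    cv_name: str = "s",
) -> CVTrajectory:
    """Overdamped Euler–Maruyama dynamics on a 1-D CV, optionally biased.

    ``potential`` is either a callable U(s) (numerical gradient) or an object
    with ``gradient(s)``. The update is

        s += -(dt / friction) * dU/ds + sqrt(2 kT dt / friction) * xi

    with reflection at ``bounds``. With ``deposit`` a well-tempered hill is
    added to ``bias_grid`` every ``deposition_stride`` steps.
    """
    if callable(getattr(potential, "gradient", None)):
        grad = potential.gradient
        ufun = potential
    else:
        ufun = potential

        def grad(s, _h=1e-6):
            return (ufun(s + _h) - ufun(s - _h)) / (2 * _h)

    if deposit and bias_grid is None:
        raise ValueError("deposit=True requires a bias_grid")
    if deposit and bias_grid.deposition_stride % cfg.record_stride != 0:
        raise ValueError("record_stride must divide the deposition stride")

    rng = np.random.default_rng(cfg.seed)
    kt = kT(cfg.temperature)
    mobility = 1.0 / cfg.langevin_friction
    dt = cfg.langevin_dt
    noise_scale = math.sqrt(2.0 * kt * mobility * dt)
    lo, hi = bounds
    s = float(start) if start is not None else 0.5 * (lo + hi)

    # Fast inline linear interpolation on the (live) 1-D bias array.
    if bias_grid is not None:
        if len(bias_grid.axes) != 1:
            raise ValueError("langevin_cv_sample expects a 1-D bias grid")
        ax = bias_grid.axes[0]
        g_lo, g_ds, g_vals = ax.lo, ax.spacing, bias_grid.values
        g_n = ax.n_nodes

    def bias_value_and_force(x):
        u = (x - g_lo) / g_ds
        i = int(u)
        i = 0 if i < 0 else (g_n - 2 if i > g_n - 2 else i)
        f = u - i
        v0, v1 = g_vals[i], g_vals[i + 1]
        return v0 + f * (v1 - v0), -(v1 - v0) / g_ds

    noises = None
    times, vals, biases = [], [], []
    chunk = 0
    for step in range(1, cfg.n_steps + 1):
        if noises is None or chunk >= len(noises):
            noises = rng.standard_normal(10000)
            chunk = 0
        force = -grad(s)
        if bias_grid is not None:
            bv, bf = bias_value_and_force(s)
            force += bf
        s = s + mobility * force * dt + noise_scale * noises[chunk]
        chunk += 1
        if not math.isfinite(s) or abs(s) > 1e3:
            raise FloatingPointError(
                "Langevin trajectory diverged; reduce langevin_dt or increase friction"
            )
        if s < lo:
            s = lo + (lo - s)
        elif s > hi:
            s = hi - (s - hi)
        if step % cfg.record_stride == 0:
            times.append(step)
            vals.append(s)
            biases.append(bias_value_and_force(s)[0] if bias_grid is not None else 0.0)
        if deposit and step % bias_grid.deposition_stride == 0:
            bias_grid.deposit_hill((s,), step_index=step)

    return CVTrajectory(
        time=np.array(times),
        cvs=np.array(vals)[:, None],
        cv_names=(cv_name,),
        bias=np.array(biases),
        meta={
            "sampler": "langevin",
            "seed": cfg.seed,
            "temperature": cfg.temperature,
            "bias_factor": bias_grid.bias_factor if bias_grid else None,
        },
    )
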