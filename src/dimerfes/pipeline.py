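"""End-to-end drivers behind the command line: generate, run, analyze, compare.

A run directory is self-describing: it holds the resolved ``config.yaml``
(with a short hash echoed into every output header for provenance), the
sampled ``COLVAR`` and ``HILLS`` files, and after analysis the biased and
reweighted ``fes*.dat`` surfaces, a ``binding.json`` report and the
block-error convergence TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .blockerror import block_fes_error, convergence_curve, write_curve_tsv
from .colvars import read_colvar
from .energetics import NonbondedConfig, WallConfig
from .fesutils import (
    compare_profiles,
    entropic_correction,
    extract_binding,
    frame_weights,
    read_fes,
    reweight_to_cv,
    write_fes,
    zero_shift,
)
from .grids import Axis
from .sampling import CVTrajectory, SamplerConfig, mc_sample
from .toysystems import make_ring_template, read_topology, write_topology, write_xyz
from .wtmetad import BiasGrid, default_dimer_axes, fes_from_bias, grid_from_hills, read_hills, write_hills

__all__ = ["RunConfig", "generate", "run", "analyze", "compare"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable description of one metadynamics run."""

    # molecules: ring count (1..4) or a topology file path, one per molecule
    molecule_a: int | str = 1
    molecule_b: int | str = 1
    bond_length: float = 0.14
    param_style: str = "generic"
    box_edge: float = 5.0
    # sampler
    seed: int = 1
    n_steps: int = 500_000
    record_stride: int = 10
    burn_in: int = 5000
    max_translation: float = 0.25
    max_rotation: float = 0.5
    temperature: float = 300.0
    # nonbonded / wall
    cutoff_nm: float = 1.4
    epsilon_rf: float = 54.0
    combination_rule: str = "lorentz_berthelot"
    wall_r0_nm: float = 2.0
    wall_k: float = 200.0
    # metadynamics
    hill_height: float = 1.0
    sigma_dist: float = 0.05
    sigma_torsion: float = 0.2
    stride: int = 500
    bias_factor: float = 5.0
    dist_range: tuple[float, float] = (0.0, 2.2)
    dist_resolution: float = 0.01
    torsion_resolution: float = 0.025
    # analysis
    shift_window: tuple[float, float] = (1.6, 1.8)
    reweight_variant: str = "time_dependent"
    analysis_dist_resolution: float = 0.05
    analysis_nangle_resolution_deg: float = 5.0
    block_sizes: tuple[int, ...] = (250, 500, 1000, 2000, 4000)

    def resolved(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.resolved(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        for name in ("dist_range", "shift_window", "block_sizes"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def template(self, which: str):
        spec = self.molecule_a if which == "a" else self.molecule_b
        if isinstance(spec, int):
            return make_ring_template(spec, self.bond_length, self.param_style)
        return read_topology(spec)

    def bias_axes(self) -> tuple[Axis, Axis]:
        return default_dimer_axes(
            dist_range=self.dist_range,
            dist_spacing=self.dist_resolution,
            torsion_spacing=self.torsion_resolution,
        )

    def analysis_axes(self, angle: str = "nangle") -> tuple[Axis, Axis]:
        dist = Axis("dist", 0.0, self.dist_range[1], self.analysis_dist_resolution)
        if angle == "nangle":
            n = max(2, int(round(90.0 / self.analysis_nangle_resolution_deg)))
            other = Axis("nangle", 0.0, math.pi / 2, (math.pi / 2) / n)
        else:
            n = int(round(2 * math.pi / 0.2))
            other = Axis("torsion", -math.pi, math.pi, 2 * math.pi / n, periodic=True)
        return dist, other


def generate(n_fused_rings: int, outdir, bond_length: float = 0.14,
             param_style: str = "generic") -> dict:
    """Build a ring template and write its topology and XYZ files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tmpl = make_ring_template(n_fused_rings, bond_length, param_style)
    topo = outdir / f"{tmpl.name}.top"
    xyz = outdir / f"{tmpl.name}.xyz"
    write_topology(tmpl, topo)
    write_xyz(tmpl.coords, xyz, labels=[a.name[:1] for a in tmpl.atoms],
              comment=f"{tmpl.name} body frame")
    return {"template": tmpl, "topology": topo, "xyz": xyz}


def run(config: RunConfig, outdir) -> Path:
    """Full well-tempered metadynamics MC run; writes COLVAR, HILLS, config, log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())
    tag = f"config_hash={config.config_hash}"

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("dimerfes")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        tmpl_a = config.template("a")
        tmpl_b = config.template("b")
        grid = BiasGrid(
            config.bias_axes(),
            bias_factor=config.bias_factor,
            initial_height=config.hill_height,
            widths=(config.sigma_dist, config.sigma_torsion),
            deposition_stride=config.stride,
            temperature=config.temperature,
        )
        scfg = SamplerConfig(
            n_steps=config.n_steps,
            seed=config.seed,
            record_stride=config.record_stride,
            max_translation=config.max_translation,
            max_rotation=config.max_rotation,
            temperature=config.temperature,
            burn_in=config.burn_in,
        )
        nb = NonbondedConfig(
            cutoff=config.cutoff_nm,
            epsilon_rf=config.epsilon_rf,
            combination_rule=config.combination_rule,
            temperature=config.temperature,
        )
        wall = WallConfig(r0=config.wall_r0_nm, k=config.wall_k)
        logger.info(
            "run %s: %s + %s, %d MC moves, seed %d",
            config.config_hash, tmpl_a.name, tmpl_b.name, config.n_steps, config.seed,
        )
        traj = mc_sample(
            tmpl_a, tmpl_b, scfg, nb_cfg=nb, wall=wall,
            box_edge=config.box_edge, bias_grid=grid, deposit=True,
        )
        logger.info(
            "finished: acceptance %.1f%%, %d hills, final hill height %.3g kJ/mol",
            100 * traj.meta["acceptance"], len(grid.hills),
            grid.hills[-1].height if grid.hills else float("nan"),
        )
        traj.to_colvar(outdir / "COLVAR", header_extra=tag)
        write_hills(grid.hills, outdir / "HILLS",
                    axis_names=tuple(ax.name for ax in grid.axes),
                    bias_factor=config.bias_factor, header_extra=tag)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _load_run(run_dir):
    run_dir = Path(run_dir)
    cfg_path = run_dir / "config.yaml"
    colvar = run_dir / "COLVAR"
    hills_path = run_dir / "HILLS"
    if not colvar.exists():
        raise FileNotFoundError(f"{colvar}: COLVAR file not found in run directory")
    if not hills_path.exists():
        raise FileNotFoundError(f"{hills_path}: HILLS file not found in run directory")
    config = RunConfig.from_yaml(cfg_path.read_text()) if cfg_path.exists() else RunConfig()
    traj = CVTrajectory.from_colvar(colvar)
    hills, _, bias_factor = read_hills(hills_path)
    return config, traj, hills, bias_factor


def analyze(run_dir, reweight_variant: str | None = None) -> dict:
    """Post-process a run directory into FES surfaces, binding report and errors."""
    run_dir = Path(run_dir)
    config, traj, hills, bias_factor = _load_run(run_dir)
    variant = reweight_variant or config.reweight_variant
    tag = f"config_hash={config.config_hash}"
    T = config.temperature

    # Biased-pair FES straight from the accumulated hills.
    bias_axes = config.bias_axes()
    grid = grid_from_hills(hills, bias_axes, bias_factor=bias_factor,
                           temperature=T, deposition_stride=config.stride)
    fes_biased = fes_from_bias(grid, shift_window=config.shift_window)
    fes_biased = zero_shift(entropic_correction(fes_biased, temperature=T))
    write_fes(fes_biased, run_dir / "fes.dat", header_extra=tag)

    # Reweighted projection onto distance x normal angle.
    weights = frame_weights(traj, hills, bias_axes, bias_factor=bias_factor,
                            temperature=T, variant=variant)
    target_axes = config.analysis_axes("nangle")
    fes_rw = reweight_to_cv(traj, hills, target_axes, bias_axes,
                            bias_factor=bias_factor, temperature=T,
                            variant=variant, weights=weights)
    fes_rw.shift_window = config.shift_window
    fes_rw = zero_shift(entropic_correction(fes_rw, temperature=T))

    # Block-error curves: biased histogram (unweighted) vs reweighted, on the
    # 1-D distance projection where every node is populated in every block.
    sizes = [b for b in config.block_sizes if len(traj) // b >= 2]
    if len(sizes) < 2:
        sizes = [max(2, len(traj) // 8), max(4, len(traj) // 4)]
    dist_axis = (target_axes[0],)
    curve_biased = convergence_curve(traj, None, dist_axis, sizes, temperature=T)
    curve_rw = convergence_curve(traj, weights, dist_axis, sizes, temperature=T)
    write_curve_tsv(run_dir / "blockerror.tsv",
                    {"biased": curve_biased, "reweighted": curve_rw},
                    header_extra=tag)
    # Per-node errors of the 2-D surface from 8 large blocks (NaN where a
    # node is missing from some block).
    stderr2d, _ = block_fes_error(
        traj, weights, target_axes, max(sizes[-1], len(traj) // 8), temperature=T
    )
    fes_rw.stderr = stderr2d
    write_fes(fes_rw, run_dir / "fes_reweighted.dat", header_extra=tag)

    summary = extract_binding(fes_rw)
    d1, a1, depth1 = summary.first_shell_min
    d2, a2, depth2 = summary.second_shell_min
    report = {
        "config_hash": config.config_hash,
        "mode": summary.mode_label,
        "first_shell": {
            "distance_nm": d1,
            "angle_deg": None if a1 is None else math.degrees(a1),
            "depth_kj_mol": depth1,
            "stderr_kj_mol": summary.first_shell_stderr,
        },
        "second_shell": {
            "distance_nm": d2,
            "angle_deg": None if a2 is None else math.degrees(a2),
            "depth_kj_mol": depth2,
        },
        "converged": curve_rw.converged,
        "block_error_slope": curve_rw.slope,
    }
    (run_dir / "binding.json").write_text(json.dumps(report, indent=2) + "\n")
    return {
        "fes_biased": fes_biased,
        "fes_reweighted": fes_rw,
        "binding": summary,
        "report": report,
        "curves": {"biased": curve_biased, "reweighted": curve_rw},
        "weights": weights,
    }


def compare(run_dirs, labels=None, out_path=None):
    """Tabulate first-shell depths across analyzed runs and flag > kT gaps."""
    run_dirs = [Path(d) for d in run_dirs]
    if labels is None:
        labels = [d.name for d in run_dirs]
    profiles, mols = [], set()
    for d, label in zip(run_dirs, labels):
        fes_path = d / "fes_reweighted.dat"
        if not fes_path.exists():
            raise FileNotFoundError(f"{fes_path}: run not analyzed yet (run 'analyze' first)")
        cfg_path = d / "config.yaml"
        if cfg_path.exists():
            cfg = RunConfig.from_yaml(cfg_path.read_text())
            # Same molecule means same geometry; nonbonded parameters may
            # differ (that is the force-field comparison use case).
            geom = tuple(
                (len(t.atoms), tuple(np.round(t.coords, 6).ravel()))
                for t in (cfg.template("a"), cfg.template("b"))
            )
            mols.add(geom)
        profiles.append((label, read_fes(fes_path)))
    if len(mols) > 1:
        raise ValueError(
            f"runs describe different molecules ({len(mols)} distinct geometries)"
        )
    result = compare_profiles(profiles)
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(result.table.to_csv(sep="\t", index=False))
            fh.write(f"# kBT threshold: {result.threshold:.4g} kJ/mol\n")
            for a, b, diff in result.flagged:
                fh.write(f"# FLAG {a} vs {b}: |d depth| = {diff:.4g} kJ/mol > kBT\n")
    return result
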