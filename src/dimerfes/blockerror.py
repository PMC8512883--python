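"""Block-average error estimation for (re)weighted free-energy profiles.

The trajectory is cut into contiguous blocks of equal frame count; each block
yields its own weighted-histogram FES, and the spread of the block estimates
gives a per-node standard error. Blocks are weighted by their total
reweighting weight, with the effective block count

    n_eff = (sum W_b)^2 / sum W_b^2

entering the standard error s / sqrt(n_eff) (standard practice for
reweighted metadynamics trajectories). If the average error grows with block
size the blocks are still correlated and the run is not converged; a flat
curve is the convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT
from .sampling import CVTrajectory

__all__ = ["BlockErrorCurve", "block_fes_error", "convergence_curve", "write_curve_tsv"]

#: Converged when avg error grows slower than this per doubling of block size.
DEFAULT_SLOPE_TOL = 0.05  # kJ/mol per doubling


@dataclass
class BlockErrorCurve:
    block_sizes: np.ndarray
    avg_error: np.ndarray  # kJ/mol, one per block size
    node_errors: np.ndarray  # per-node stderr at the largest block size
    converged: bool
    slope: float  # kJ/mol per doubling over the largest three sizes

    def __post_init__(self):
        bs = np.asarray(self.block_sizes)
        if np.any(np.diff(bs) <= 0):
            raise ValueError("block sizes must be strictly increasing")


def _block_profiles(samples, weights, axes, block_size, temperature):
    """Per-block F grids and block total weights; trailing partial block dropped."""
    n = samples.shape[0]
    n_blocks = n // block_size
    if n_blocks < 2:
        raise ValueError(
            f"block size {block_size} leaves {n_blocks} block(s); need at least 2"
        )
    from .fesutils import weighted_fes_histogram

    profiles, totals = [], []
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        w = weights[sl]
        F = weighted_fes_histogram(samples[sl], w, axes, temperature=temperature)
        # Normalize each block's density so blocks are comparable.
        profiles.append(F.values + kT(temperature) * np.log(w.sum()))
        totals.append(w.sum())
    return np.array(profiles), np.array(totals)


def block_fes_error(
    traj: CVTrajectory,
    weights: np.ndarray | None,
    axes,
    block_size: int,
    temperature: float = DEFAULT_TEMPERATURE,
):
    """Per-node standard error of the FES from contiguous blocks.

    Returns ``(stderr_grid, avg_error)``. Nodes not populated in every block
    get NaN stderr and are excluded from the average (they have no defined
    block spread). Error estimates are invariant under uniform rescaling of
    the weights.
    """
    samples = np.column_stack([traj.column(ax.name) for ax in axes])
    if weights is None:
        weights = np.ones(len(traj))
    weights = np.asarray(weights, dtype=float)
    profiles, W = _block_profiles(samples, weights, axes, block_size, temperature)

    finite = np.isfinite(profiles)
    in_all = finite.all(axis=0)
    Wn = W / W.sum()
    n_eff = 1.0 / np.sum(Wn**2)

    shape = profiles.shape[1:]
    stderr = np.full(shape, np.nan)
    if np.any(in_all) and n_eff > 1.0:
        P = profiles[:, in_all]  # (n_blocks, n_nodes_in_all)
        mean = np.tensordot(Wn, P, axes=1)
        var = np.tensordot(Wn, (P - mean) ** 2, axes=1) * n_eff / (n_eff - 1.0)
        stderr[in_all] = np.sqrt(var / n_eff)
    avg = float(np.nanmean(stderr)) if np.any(np.isfinite(stderr)) else np.nan
    return stderr, avg


def convergence_curve(
    traj: CVTrajectory,
    weights: np.ndarray | None,
    axes,
    block_sizes,
    temperature: float = DEFAULT_TEMPERATURE,
    slope_tol: float = DEFAULT_SLOPE_TOL,
) -> BlockErrorCurve:
    """Average block error as a function of block size, with a flatness verdict.

    The verdict fits the average error against log2(block size) over the
    largest three sizes; a slope below ``slope_tol`` kJ/mol per doubling
    reads as converged. To keep sizes comparable, the average runs over the
    nodes that are populated in every block at *every* size (otherwise rare
    nodes, which only qualify at large block sizes, fake a rising curve).
    """
    block_sizes = sorted(int(b) for b in block_sizes)
    stderr_grids = [
        block_fes_error(traj, weights, axes, bs, temperature)[0] for bs in block_sizes
    ]
    node_errors = stderr_grids[-1]
    common = np.all([np.isfinite(g) for g in stderr_grids], axis=0)
    if np.any(common):
        avg_errors = np.array([float(g[common].mean()) for g in stderr_grids])
    else:
        avg_errors = np.array([float(np.nanmean(g)) for g in stderr_grids])
    tail = min(3, len(block_sizes))
    x = np.log2(np.array(block_sizes[-tail:], dtype=float))
    y = avg_errors[-tail:]
    slope = float(np.polyfit(x, y, 1)[0]) if tail >= 2 and np.all(np.isfinite(y)) else np.nan
    converged = bool(np.isfinite(slope) and slope < slope_tol)
    return BlockErrorCurve(
        block_sizes=np.array(block_sizes),
        avg_error=avg_errors,
        node_errors=node_errors,
        converged=converged,
        slope=slope,
    )


def write_curve_tsv(path, curves: dict[str, BlockErrorCurve], header_extra: str | None = None) -> None:
    """Write one or more curves as TSV: block_size then one avg-error column per label."""
    labels = list(curves)
    sizes = curves[labels[0]].block_sizes
    for lab in labels[1:]:
        if not np.array_equal(curves[lab].block_sizes, sizes):
            raise ValueError("curves must share block sizes")
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("block_size\t" + "\t".join(f"avg_error_{l}" for l in labels) + "\n")
        for i, bs in enumerate(sizes):
            row = [str(int(bs))] + [f"{curves[l].avg_error[i]:.6g}" for l in labels]
            fh.write("\t".join(row) + "\n")
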