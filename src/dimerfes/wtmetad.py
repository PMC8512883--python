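"""Well-tempered metadynamics bias: Gaussian hill deposition on a CV grid,
interpolated bias evaluation, and PLUMED-style HILLS file I/O.

The bias is accumulated on a regular grid (standard PLUMED practice) so that
evaluating it during sampling is O(1) per step rather than a sum over the
full hill history. The well-tempered height law

    w = w0 * exp(-V(s) / ((gamma - 1) * kB * T))

makes deposited heights decay wherever the bias has already grown, and the
converged bias relates to the free energy by F(s) = -gamma/(gamma-1) * V(s)
up to a constant fixed later by the zero-shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT
from .grids import Axis, FESGrid

__all__ = [
    "Hill",
    "BiasGrid",
    "default_dimer_axes",
    "grid_from_hills",
    "fes_from_bias",
    "fes_time_average",
    "write_hills",
    "read_hills",
]

#: Gaussians are cut off beyond this many widths per axis (error < 1e-8 of height).
TRUNCATION_SIGMAS = 6.0


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: center and widths in CV space, height in kJ/mol."""

    center: tuple[float, ...]
    widths: tuple[float, ...]
    height: float
    step_index: int

    def __post_init__(self):
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")


def default_dimer_axes(
    dist_range=(0.0, 2.2), dist_spacing=0.01, torsion_spacing=0.025
) -> tuple[Axis, Axis]:
    """Bias axes for the dimer pipeline: bounded distance x periodic torsion.

    The default spacings keep the bilinear interpolation error around 1% of
    a hill height — fine for sampling; exact-summation cross-checks use a
    finer grid (see the oracle-equivalence tests).
    """
    n = int(round(2 * math.pi / torsion_spacing))
    spacing = 2 * math.pi / n  # force an integer number of periodic bins
    return (
        Axis("dist", dist_range[0], dist_range[1], dist_spacing, periodic=False),
        Axis("torsion", -math.pi, math.pi, spacing, periodic=True),
    )


class BiasGrid:
    """Accumulated metadynamics bias on a 1-D or 2-D CV grid.

    Parameters
    ----------
    axes : tuple of Axis
    bias_factor : float
        Well-tempered gamma (> 1); gamma = 5 by default.
    initial_height : float
        Height w0 of the first hill, kJ/mol (1.0 by default).
    widths : tuple of float
        Gaussian width per axis (0.05 nm and 0.2 rad by default for the
        distance/torsion pair).
    deposition_stride : int
        Sampler steps between depositions (500 by default).
    temperature : float, K
    """

    def __init__(
        self,
        axes,
        bias_factor: float = 5.0,
        initial_height: float = 1.0,
        widths=None,
        deposition_stride: int = 500,
        temperature: float = DEFAULT_TEMPERATURE,
    ):
        if bias_factor <= 1:
            raise ValueError("bias_factor must exceed 1 (well-tempered limit undefined)")
        if initial_height <= 0:
            raise ValueError("initial hill height must be positive")
        self.axes = tuple(axes)
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("BiasGrid supports 1 or 2 CV axes")
        if widths is None:
            widths = {"dist": 0.05, "torsion": 0.2}
            widths = tuple(widths.get(ax.name, 0.1) for ax in self.axes)
        self.widths = tuple(float(w) for w in widths)
        self.bias_factor = float(bias_factor)
        self.initial_height = float(initial_height)
        self.deposition_stride = int(deposition_stride)
        self.temperature = float(temperature)
        self.values = np.zeros(tuple(ax.n_nodes for ax in self.axes))
        self.hills: list[Hill] = []
        self._clamp_warned = False

    # -- evaluation -----------------------------------------------------

    def _axis_coords(self, ax_i: int, x: float):
        """Fractional grid coordinate and bracketing node indices on one axis."""
        ax = self.axes[ax_i]
        if ax.periodic:
            u = (ax.wrap(x) - ax.lo) / ax.spacing
            i0 = int(np.floor(u)) % ax.n_nodes
            i1 = (i0 + 1) % ax.n_nodes
            frac = u - np.floor(u)
        else:
            u = (x - ax.lo) / ax.spacing
            if u < 0 or u > ax.n_nodes - 1:
                if not self._clamp_warned:
                    import warnings

                    warnings.warn(
                        f"CV value {x:g} outside axis {ax.name!r} range; clamping "
                        "(the wall should normally prevent this)",
                        stacklevel=3,
                    )
                    self._clamp_warned = True
                u = min(max(u, 0.0), float(ax.n_nodes - 1))
            i0 = min(int(np.floor(u)), ax.n_nodes - 2) if ax.n_nodes > 1 else 0
            i1 = min(i0 + 1, ax.n_nodes - 1)
            frac = u - i0
        return i0, i1, frac

    def bias_at(self, s) -> float:
        """Multilinearly interpolated bias at CV point ``s``, kJ/mol."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if s.shape != (len(self.axes),):
            raise ValueError(f"expected {len(self.axes)} CV values, got {s.shape}")
        V = self.values
        if len(self.axes) == 1:
            i0, i1, f = self._axis_coords(0, s[0])
            return float((1 - f) * V[i0] + f * V[i1])
        i0, i1, fx = self._axis_coords(0, s[0])
        j0, j1, fy = self._axis_coords(1, s[1])
        return float(
            (1 - fx) * ((1 - fy) * V[i0, j0] + fy * V[i0, j1])
            + fx * ((1 - fy) * V[i1, j0] + fy * V[i1, j1])
        )

    def force_at(self, s) -> np.ndarray:
        """Negative bias gradient at ``s`` (finite differences on the grid)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty(len(self.axes))
        for k, ax in enumerate(self.axes):
            h = ax.spacing
            sp, sm = s.copy(), s.copy()
            sp[k] += 0.5 * h
            sm[k] -= 0.5 * h
            if not ax.periodic:
                sp[k] = min(sp[k], ax.hi)
                sm[k] = max(sm[k], ax.lo)
            denom = sp[k] - sm[k]
            out[k] = -(self.bias_at(sp) - self.bias_at(sm)) / denom if denom else 0.0
        return out

    # -- deposition -----------------------------------------------------

    def hill_height(self, s) -> float:
        """Well-tempered height the next hill would take at CV point ``s``."""
        dkt = (self.bias_factor - 1.0) * kT(self.temperature)
        return self.initial_height * math.exp(-self.bias_at(s) / dkt)

    def _add_gaussian(self, center, widths, height: float) -> None:
        axis_terms = []
        for k, ax in enumerate(self.axes):
            d = ax.displacement(ax.nodes, float(center[k]))
            g = np.exp(-0.5 * (d / widths[k]) ** 2)
            g[np.abs(d) > TRUNCATION_SIGMAS * widths[k]] = 0.0
            axis_terms.append(g)
        if len(axis_terms) == 1:
            self.values += height * axis_terms[0]
        else:
            self.values += height * np.outer(axis_terms[0], axis_terms[1])

    def add_hill(self, hill: Hill) -> None:
        """Replay a previously recorded hill (height taken as stored)."""
        self._add_gaussian(hill.center, hill.widths, hill.height)
        self.hills.append(hill)

    def deposit_hill(self, s_now, step_index: int = 0) -> Hill:
        """Deposit one Gaussian at the current CV point and return its record.

        The height follows the well-tempered decay law at the current bias.
        The Gaussian is truncated beyond ``TRUNCATION_SIGMAS`` widths on each
        axis; on the periodic torsion axis displacements are minimum-image
        wrapped.
        """
        s_now = np.atleast_1d(np.asarray(s_now, dtype=float))
        height = self.hill_height(s_now)
        self._add_gaussian(s_now, self.widths, height)
        hill = Hill(
            center=tuple(float(x) for x in s_now),
            widths=self.widths,
            height=height,
            step_index=int(step_index),
        )
        self.hills.append(hill)
        return hill


def grid_from_hills(
    hills,
    axes,
    bias_factor: float = 5.0,
    temperature: float = DEFAULT_TEMPERATURE,
    deposition_stride: int = 500,
) -> BiasGrid:
    """Rebuild a bias grid by replaying a hill list (e.g. from a HILLS file)."""
    widths = hills[0].widths if hills else None
    grid = BiasGrid(
        axes,
        bias_factor=bias_factor,
        widths=widths,
        deposition_stride=deposition_stride,
        temperature=temperature,
    )
    for h in hills:
        grid.add_hill(h)
    return grid


def fes_from_bias(grid: BiasGrid, shift_window=(1.6, 1.8)) -> FESGrid:
    """Free-energy estimate F(s) = -gamma/(gamma-1) * V(s) from the final bias.

    The additive constant is left open; apply
    :func:`dimerfes.fesutils.zero_shift` to pin the flat tail at zero.
    """
    g = grid.bias_factor
    prefactor = -g / (g - 1.0)
    return FESGrid(
        axes=grid.axes,
        values=prefactor * grid.values,
        shift_window=shift_window,
        meta={
            "source": "bias",
            "bias_factor": g,
            "temperature": grid.temperature,
        },
    )


def fes_time_average(
    hills,
    axes,
    bias_factor: float = 5.0,
    temperature: float = DEFAULT_TEMPERATURE,
    average_fraction: float = 0.5,
    shift_window=(1.6, 1.8),
) -> FESGrid:
    """FES from the time-averaged well-tempered bias.

    The instantaneous bias fluctuates around its converged profile; averaging
    -gamma/(gamma-1) * V(s, t) over the last ``average_fraction`` of
    deposition epochs is the standard variance reduction for the final
    estimate. Implemented by replaying the hill list.
    """
    if not hills:
        raise ValueError("no hills to average over")
    if not 0 < average_fraction <= 1:
        raise ValueError("average_fraction must be in (0, 1]")
    grid = grid_from_hills([], axes, bias_factor=bias_factor, temperature=temperature)
    k0 = int(len(hills) * (1.0 - average_fraction))
    acc = np.zeros_like(grid.values)
    count = 0
    for i, h in enumerate(hills):
        grid.add_hill(h)
        if i >= k0:
            acc += grid.values
            count += 1
    prefactor = -bias_factor / (bias_factor - 1.0)
    return FESGrid(
        axes=grid.axes,
        values=prefactor * acc / count,
        shift_window=shift_window,
        meta={
            "source": "bias/time_average",
            "bias_factor": bias_factor,
            "temperature": temperature,
            "average_fraction": average_fraction,
        },
    )


# -- HILLS I/O ----------------------------------------------------------


def write_hills(hills, path, axis_names=("dist", "torsion"), bias_factor: float = 5.0,
                header_extra: str | None = None) -> None:
    """Write hills in the PLUMED HILLS dialect.

    Header: ``#! FIELDS time <cv names> <sigma_... names> height biasf``.
    """
    hills = list(hills)
    ndim = len(hills[0].center) if hills else len(axis_names)
    names = list(axis_names[:ndim])
    fields = ["time"] + names + [f"sigma_{n}" for n in names] + ["height", "biasf"]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        if header_extra:
            fh.write(f"# {header_extra}\n")
        for h in hills:
            row = [h.step_index, *h.center, *h.widths, h.height, bias_factor]
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_hills(path):
    """Read a HILLS file; returns (hills, axis_names, bias_factor)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing '#! FIELDS' HILLS header")
        fields = first.split()[2:]
        if (
            fields[0] != "time"
            or fields[-2:] != ["height", "biasf"]
            or (len(fields) - 3) % 2 != 0
        ):
            raise ValueError(
                f"{path}: unexpected FIELDS {fields}; expected "
                "'time <cvs> <sigma_cvs> height biasf'"
            )
        ndim = (len(fields) - 3) // 2
        names = fields[1 : 1 + ndim]
        for n in names:
            if f"sigma_{n}" not in fields:
                raise ValueError(f"{path}: missing sigma column for CV {n!r}")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty hill list -> empty file body
            data = np.loadtxt(fh, comments="#", ndmin=2)
    hills = []
    bias_factor = 5.0
    for row in data:
        center = tuple(row[1 : 1 + ndim])
        widths = tuple(row[1 + ndim : 1 + 2 * ndim])
        hills.append(
            Hill(center=center, widths=widths, height=float(row[-2]), step_index=int(row[0]))
        )
        bias_factor = float(row[-1])
    return hills, names, bias_factor
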