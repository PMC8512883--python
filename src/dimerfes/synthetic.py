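"""Analytic fixtures and independent oracles for the test suite.

Everything here is deliberately naive — closed forms and quadrature, no shared
numerical kernels with the production path — so that agreement between the
two is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .constants import DEFAULT_TEMPERATURE, kT
from .energetics import WallConfig
from .grids import Axis, FESGrid
from .toysystems import MoleculeTemplate, make_ring_template

__all__ = [
    "AnalyticPotential",
    "make_double_well",
    "make_harmonic",
    "make_flat",
    "make_ideal_gas_dimer",
    "make_ar1_series",
    "make_dip_grid",
    "ideal_gas_radial_fes",
]


@dataclass
class AnalyticPotential:
    """A 1-D CV-space potential with a quadrature-normalized free energy.

    For a single CV sampled from the Boltzmann density the free energy is the
    potential itself up to the additive constant kT ln Z;
    :meth:`free_energy` returns exactly ``U(s) + kT ln Z`` with Z computed by
    adaptive quadrature, i.e. -kT ln of the normalized density.
    """

    name: str
    u: Callable[[float], float]
    gradient: Callable[[float], float]
    domain: tuple[float, float]
    params: dict = field(default_factory=dict)

    def __call__(self, s):
        return self.u(s)

    def partition_function(self, temperature: float = DEFAULT_TEMPERATURE) -> float:
        beta = 1.0 / kT(temperature)
        z, _ = quad(lambda s: np.exp(-beta * self.u(s)), *self.domain, limit=200)
        return z

    def free_energy(self, s, temperature: float = DEFAULT_TEMPERATURE):
        z = self.partition_function(temperature)
        return np.vectorize(self.u)(s) + kT(temperature) * np.log(z)


def make_double_well(h: float = 10.0) -> AnalyticPotential:
    """Symmetric double well U(s) = h (s^2 - 1)^2: minima at +-1, barrier h at 0."""
    if h <= 0:
        raise ValueError("barrier height must be positive")
    return AnalyticPotential(
        name="double_well",
        u=lambda s: h * (s * s - 1.0) ** 2,
        gradient=lambda s: 4.0 * h * s * (s * s - 1.0),
        domain=(-1.7, 1.7),
        params={"h": h},
    )


def make_harmonic(k: float = 100.0) -> AnalyticPotential:
    """Harmonic well U(s) = k s^2 / 2 with Boltzmann variance kT/k."""
    if k <= 0:
        raise ValueError("force constant must be positive")
    return AnalyticPotential(
        name="harmonic",
        u=lambda s: 0.5 * k * s * s,
        gradient=lambda s: k * s,
        domain=(-2.0, 2.0),
        params={"k": k},
    )


def make_flat(domain=(0.0, 1.0)) -> AnalyticPotential:
    """Zero potential on a bounded domain (uniform stationary density)."""
    return AnalyticPotential(
        name="flat", u=lambda s: 0.0, gradient=lambda s: 0.0, domain=domain
    )


def make_ideal_gas_dimer(
    n_fused_rings: int = 1, bond_length: float = 0.14
) -> tuple[MoleculeTemplate, MoleculeTemplate]:
    """Two ring templates with epsilon = 0 and q = 0: only the wall acts.

    The only structure in the sampled radial distribution is then the r^2
    volume Jacobian (plus the wall tail), which the entropic correction must
    remove exactly — the physical content of the Jacobian term.
    """
    a = make_ring_template(n_fused_rings, bond_length, param_style="ideal", name="ideal_a")
    b = make_ring_template(n_fused_rings, bond_length, param_style="ideal", name="ideal_b")
    return a, b


def ideal_gas_radial_fes(
    r, wall: WallConfig | None = None, temperature: float = DEFAULT_TEMPERATURE
):
    """Closed-form uncorrected radial FES of a non-interacting pair.

    F(r) = -2 kT ln r + V_wall(r) up to a constant: the r^2 surface Jacobian
    in 3 dimensions plus the wall. An independent oracle for the Monte Carlo
    channel.
    """
    wall = wall or WallConfig()
    r = np.asarray(r, dtype=float)
    vw = np.where(r > wall.r0, 0.5 * wall.k * (r - wall.r0) ** 2, 0.0)
    with np.errstate(divide="ignore"):
        return -2.0 * kT(temperature) * np.log(r) + vw


def make_ar1_series(phi: float, n: int, seed: int, sigma: float = 1.0) -> np.ndarray:
    """Stationary AR(1) series x_t = phi x_{t-1} + sigma xi_t.

    Correlation time ~ -1/ln(phi); phi = 0 gives white noise. Used as a
    fixture with known autocorrelation for the block-error curve.
    """
    if not -1 < phi < 1:
        raise ValueError("phi must lie in (-1, 1) for stationarity")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(scale=sigma / np.sqrt(1.0 - phi * phi))
    noise = rng.normal(scale=sigma, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + noise[t - 1]
    return x


def make_dip_grid(
    axes,
    dips,
    baseline: float = 0.0,
    stderr: float | None = None,
    shift_window=(1.6, 1.8),
) -> FESGrid:
    """Constructed FES fixture: Gaussian dips of known depth on a flat baseline.

    ``dips`` is a list of ``(center, widths, depth)`` with depth < 0 for a
    well. The grid is marked corrected and shifted, ready for
    binding-extraction tests.
    """
    axes = tuple(axes)
    mesh = np.meshgrid(*[ax.nodes for ax in axes], indexing="ij")
    values = np.full(mesh[0].shape, float(baseline))
    for center, widths, depth in dips:
        arg = np.zeros_like(values)
        for k, ax in enumerate(axes):
            d = ax.displacement(mesh[k], center[k])
            arg += (d / widths[k]) ** 2
        values += depth * np.exp(-0.5 * arg)
    err = None if stderr is None else np.full_like(values, float(stderr))
    return FESGrid(
        axes=axes,
        values=values,
        stderr=err,
        entropic_corrected=True,
        zero_shifted=True,
        shift_window=shift_window,
    )
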