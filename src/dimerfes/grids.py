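"""Regular CV-space grids shared by the bias engine and the FES post-processing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Axis", "FESGrid"]


@dataclass(frozen=True)
class Axis:
    """One regularly spaced CV axis.

    Nodes are ``lo + i * spacing``. A periodic axis (period ``hi - lo``) has no
    node at ``hi`` — the interval wraps; a bounded axis includes both endpoints.
    """

    name: str
    lo: float
    hi: float
    spacing: float
    periodic: bool = False

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError(f"axis {self.name!r}: hi must exceed lo")
        if self.spacing <= 0:
            raise ValueError(f"axis {self.name!r}: spacing must be positive")

    @property
    def n_nodes(self) -> int:
        span = self.hi - self.lo
        n = int(round(span / self.spacing))
        return n if self.periodic else n + 1

    @property
    def nodes(self) -> np.ndarray:
        return self.lo + self.spacing * np.arange(self.n_nodes)

    @property
    def period(self) -> float:
        return self.hi - self.lo

    def wrap(self, x):
        """Fold values into the axis range (periodic axes only)."""
        if not self.periodic:
            return x
        return self.lo + np.mod(np.asarray(x) - self.lo, self.period)

    def displacement(self, x, x0):
        """x - x0 with the minimum-image convention on periodic axes."""
        d = np.asarray(x) - x0
        if self.periodic:
            d = d - self.period * np.round(d / self.period)
        return d

    @property
    def edges(self) -> np.ndarray:
        """Bin edges centered on the nodes (for histogramming onto this grid)."""
        return np.concatenate(
            [self.nodes - 0.5 * self.spacing, [self.nodes[-1] + 0.5 * self.spacing]]
        )


@dataclass
class FESGrid:
    """Free energy on a 1-D or 2-D CV grid, with optional per-node standard errors.

    ``values`` has shape ``(axes[0].n_nodes, ...)``; kJ/mol. ``shift_window``
    is the distance interval whose mean is defined to be zero after
    :func:`dimerfes.fesutils.zero_shift`.
    """

    axes: tuple[Axis, ...]
    values: np.ndarray
    stderr: np.ndarray | None = None
    entropic_corrected: bool = False
    zero_shifted: bool = False
    shift_window: tuple[float, float] = (1.6, 1.8)
    distance_axis: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = tuple(ax.n_nodes for ax in self.axes)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid shape {expected}")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != expected:
                raise ValueError("stderr shape does not match grid shape")

    def copy(self) -> "FESGrid":
        return FESGrid(
            axes=self.axes,
            values=self.values.copy(),
            stderr=None if self.stderr is None else self.stderr.copy(),
            entropic_corrected=self.entropic_corrected,
            zero_shifted=self.zero_shifted,
            shift_window=self.shift_window,
            distance_axis=self.distance_axis,
            meta=dict(self.meta),
        )
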