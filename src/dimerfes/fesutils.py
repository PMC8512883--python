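"""FES post-processing: reweighting, entropic correction, zero-shift,
binding-mode extraction and force-field-style profile comparison.

The free-energy surfaces handled here live on :class:`~dimerfes.grids.FESGrid`
objects. The standard processing chain for a dimerization profile is

    fes_from_bias / reweight_to_cv  ->  entropic_correction  ->  zero_shift

after which well depths are read off relative to the flat dissociated tail.

Entropic (Jacobian) correction
------------------------------
In n spatial dimensions the volume available to the second molecule at
distance r grows like r^(n-1), so the raw radial profile acquires a spurious
-(n-1) R T ln r attraction. Adding

    dV(r) = (n - 1) * R * T * ln(r)

removes it; for a non-interacting pair the corrected, zero-shifted profile is
flat — which is exactly what the test suite checks.

Reweighting
-----------
Frames of a well-tempered run are unbiased with weights

    w_t ∝ exp(beta * [V(s_t, t) - c(t)])

where V(s_t, t) is the instantaneous bias recorded with the frame and c(t) is
the time-dependent offset computed on the bias grid at the frame's deposition
epoch:

    c(t) = (1/beta) ln [ int exp(beta*gamma*V/(gamma-1)) ds
                       / int exp(beta*V/(gamma-1)) ds ].

A simpler ``final_bias`` variant (w_t ∝ exp(beta * V_final(s_t))) is kept as a
cross-check; both are standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, R_GAS, kT
from .grids import Axis, FESGrid
from .sampling import CVTrajectory
from .wtmetad import BiasGrid, grid_from_hills

__all__ = [
    "BindingSummary",
    "ComparisonResult",
    "entropic_correction",
    "zero_shift",
    "frame_weights",
    "weighted_fes_histogram",
    "reweight_to_cv",
    "extract_binding",
    "compare_profiles",
    "write_fes",
    "read_fes",
]

FIRST_SHELL = (0.4, 0.7)  # nm
SECOND_SHELL = (0.8, 1.1)  # nm
STACKED_MAX_DEG = 30.0
TSHAPED_MIN_DEG = 60.0


def entropic_correction(F: FESGrid, n_dims: int = 3, temperature: float = DEFAULT_TEMPERATURE) -> FESGrid:
    """Add the (n-1) R T ln(r) Jacobian term along the distance axis.

    Nodes at r <= 0 are outside the physical domain and are set to +inf.
    Refuses to run twice on the same grid (the flag guards double
    application).
    """
    if F.entropic_corrected:
        raise ValueError("entropic correction already applied (entropic_corrected flag is set)")
    out = F.copy()
    r = F.axes[F.distance_axis].nodes
    corr = np.full_like(r, np.inf)
    pos = r > 0
    corr[pos] = (n_dims - 1) * R_GAS * temperature * np.log(r[pos])
    shape = [1] * out.values.ndim
    shape[F.distance_axis] = len(r)
    out.values = out.values + corr.reshape(shape)
    out.entropic_corrected = True
    return out


def zero_shift(F: FESGrid) -> FESGrid:
    """Translate the profile so its mean over the flat-tail window is zero.

    The mean is taken over all finite nodes whose distance falls in
    ``F.shift_window`` (angle-averaged for 2-D grids).
    """
    lo, hi = F.shift_window
    r = F.axes[F.distance_axis].nodes
    in_window = (r >= lo) & (r <= hi)
    if not np.any(in_window):
        raise ValueError(f"shift window {F.shift_window} lies outside the distance axis")
    sel = np.take(F.values, np.where(in_window)[0], axis=F.distance_axis)
    finite = np.isfinite(sel)
    if not np.any(finite):
        raise ValueError("no finite free-energy values inside the shift window")
    out = F.copy()
    out.values = out.values - float(sel[finite].mean())
    out.zero_shifted = True
    return out


def frame_weights(
    traj: CVTrajectory,
    hills,
    bias_axes,
    bias_factor: float = 5.0,
    temperature: float = DEFAULT_TEMPERATURE,
    variant: str = "time_dependent",
) -> np.ndarray:
    """Per-frame reweighting factors, normalized to mean 1.

    ``variant`` selects the time-dependent-offset weights (default) or the
    ``final_bias`` fallback. ``bias_axes`` must be the axes the bias was
    deposited on (order matters; their names must match trajectory columns
    for the final-bias variant).
    """
    beta = 1.0 / kT(temperature)
    g = bias_factor
    if variant == "final_bias":
        grid = grid_from_hills(hills, bias_axes, bias_factor=g, temperature=temperature)
        s_cols = np.column_stack([traj.column(ax.name) for ax in bias_axes])
        v_final = np.array([grid.bias_at(s) for s in s_cols])
        logw = beta * v_final
    elif variant == "time_dependent":
        # Running c(t): replay hills on a fresh grid; after each deposition
        # epoch compute the offset from the current bias.
        grid = BiasGrid(
            bias_axes,
            bias_factor=g,
            widths=hills[0].widths if hills else None,
            temperature=temperature,
        )
        epochs = np.array([h.step_index for h in hills])
        c_of_epoch = [0.0]  # before any hill, V = 0 and c = 0
        for h in hills:
            grid.add_hill(h)
            V = grid.values.ravel()
            c = (logsumexp(beta * g * V / (g - 1.0)) - logsumexp(beta * V / (g - 1.0))) / beta
            c_of_epoch.append(c)
        # Frames are recorded before a coincident deposition, so a frame at a
        # hill's own step still saw the bias without that hill.
        k = np.searchsorted(epochs, np.asarray(traj.time), side="left")
        c_t = np.asarray(c_of_epoch)[k]
        logw = beta * (traj.bias - c_t)
    else:
        raise ValueError(f"unknown reweighting variant {variant!r}")
    logw = logw - logw.max()
    w = np.exp(logw)
    mean = w.mean()
    if mean == 0 or not np.isfinite(mean):
        raise ValueError("all-zero reweighting weights: bias and trajectory do not match")
    return w / mean


def weighted_fes_histogram(
    samples: np.ndarray,
    weights: np.ndarray | None,
    axes,
    temperature: float = DEFAULT_TEMPERATURE,
) -> FESGrid:
    """F = -kT ln of a (weighted) density histogram on grid-node-centred bins.

    ``samples`` is (n_frames, n_axes). Values on periodic axes are wrapped
    before binning. Empty bins get F = +inf.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    cols = []
    for k, ax in enumerate(axes):
        cols.append(ax.wrap(samples[:, k]) if ax.periodic else samples[:, k])
    pts = np.column_stack(cols)
    edges = [ax.edges for ax in axes]
    hist, _ = np.histogramdd(pts, bins=edges, weights=weights)
    with np.errstate(divide="ignore"):
        F = -kT(temperature) * np.log(hist)
    return FESGrid(axes=tuple(axes), values=F, meta={"temperature": temperature})


def reweight_to_cv(
    traj: CVTrajectory,
    hills,
    target_axes,
    bias_axes,
    bias_factor: float = 5.0,
    temperature: float = DEFAULT_TEMPERATURE,
    variant: str = "time_dependent",
    weights: np.ndarray | None = None,
) -> FESGrid:
    """Project the unbiased FES onto ``target_axes`` by frame reweighting.

    ``target_axes`` name trajectory columns (e.g. dist and nangle — the
    normal angle was never biased, which is the point of the projection).
    Precomputed ``weights`` may be passed to share them with block analysis.
    """
    if weights is None:
        weights = frame_weights(
            traj, hills, bias_axes, bias_factor=bias_factor,
            temperature=temperature, variant=variant,
        )
    samples = np.column_stack([traj.column(ax.name) for ax in target_axes])
    F = weighted_fes_histogram(samples, weights, target_axes, temperature=temperature)
    F.meta.update({"source": f"reweight/{variant}", "bias_factor": bias_factor})
    return F


@dataclass
class BindingSummary:
    """Locations and depths of the first- and second-shell minima."""

    first_shell_min: tuple[float, float | None, float]  # (distance nm, angle rad, depth kJ/mol)
    second_shell_min: tuple[float, float | None, float]
    mode_label: str  # "T-shaped" | "stacked" | "mixed"
    first_shell_stderr: float | None = None


def _shell_minimum(F: FESGrid, shell: tuple[float, float]):
    r = F.axes[F.distance_axis].nodes
    mask = (r >= shell[0]) & (r <= shell[1])
    if not np.any(mask):
        raise ValueError(f"shell window {shell} outside the distance grid")
    sub = np.take(F.values, np.where(mask)[0], axis=F.distance_axis)
    if not np.any(np.isfinite(sub)):
        raise ValueError(f"no finite free-energy values inside shell {shell}")
    sub = np.where(np.isfinite(sub), sub, np.inf)
    idx = np.unravel_index(int(np.argmin(sub)), sub.shape)
    dist = r[np.where(mask)[0][idx[F.distance_axis]]]
    angle = None
    if F.values.ndim == 2:
        other = 1 - F.distance_axis
        angle = float(F.axes[other].nodes[idx[other]])
    depth = float(sub[idx])
    err = None
    if F.stderr is not None:
        full_idx = list(idx)
        full_idx[F.distance_axis] = np.where(mask)[0][idx[F.distance_axis]]
        err = float(F.stderr[tuple(full_idx)])
        if not np.isfinite(err):
            err = None
    return float(dist), angle, depth, err


def extract_binding(
    F: FESGrid,
    first_shell: tuple[float, float] = FIRST_SHELL,
    second_shell: tuple[float, float] = SECOND_SHELL,
    stacked_max_deg: float = STACKED_MAX_DEG,
    tshaped_min_deg: float = TSHAPED_MIN_DEG,
) -> BindingSummary:
    """Find the shell minima and classify the first-shell binding mode.

    Requires a corrected, zero-shifted grid. For a 2-D distance x normal-angle
    grid the mode is T-shaped when the first-shell minimum sits at >= 60 deg,
    stacked when <= 30 deg, mixed otherwise. Depths are clipped at zero (a
    "well" above the dissociated tail is no well), with a warning when the
    profile is flat.
    """
    if not (F.entropic_corrected and F.zero_shifted):
        raise ValueError("extract_binding expects an entropic-corrected, zero-shifted grid")
    d1, a1, depth1, err1 = _shell_minimum(F, first_shell)
    d2, a2, depth2, _ = _shell_minimum(F, second_shell)
    if depth1 >= -1e-9:
        warnings.warn("no first-shell well below the tail; mode labelled mixed by convention")
        depth1 = min(depth1, 0.0)
        mode = "mixed"
    elif a1 is not None and F.axes[1 - F.distance_axis].name == "nangle":
        angle_deg = np.degrees(abs(a1))
        if angle_deg >= tshaped_min_deg:
            mode = "T-shaped"
        elif angle_deg <= stacked_max_deg:
            mode = "stacked"
        else:
            mode = "mixed"
    else:
        mode = "mixed"
    depth2 = min(depth2, 0.0)
    return BindingSummary(
        first_shell_min=(d1, a1, depth1),
        second_shell_min=(d2, a2, depth2),
        mode_label=mode,
        first_shell_stderr=err1,
    )


@dataclass
class ComparisonResult:
    """First-shell depths per label plus pairs differing by more than kT."""

    table: "object"  # pandas.DataFrame: label, depth, stderr, distance, angle
    flagged: list[tuple[str, str, float]]
    threshold: float  # kJ/mol


def compare_profiles(profiles, temperature: float = DEFAULT_TEMPERATURE) -> ComparisonResult:
    """Tabulate first-shell well depths of several FES grids and flag pairs
    whose depths differ by more than the thermal energy kT.

    ``profiles`` is a sequence of (label, FESGrid) with identical axes.
    """
    import pandas as pd

    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    ref_axes = profiles[0][1].axes
    for label, F in profiles[1:]:
        if len(F.axes) != len(ref_axes) or any(
            a.name != b.name or a.n_nodes != b.n_nodes or abs(a.lo - b.lo) > 1e-12
            for a, b in zip(F.axes, ref_axes)
        ):
            raise ValueError(f"profile {label!r} has mismatched axes")
    rows = []
    for label, F in profiles:
        s = extract_binding(F)
        d, a, depth = s.first_shell_min
        rows.append(
            {"label": label, "depth": depth, "stderr": s.first_shell_stderr,
             "distance": d, "angle": a, "mode": s.mode_label}
        )
    table = pd.DataFrame(rows)
    threshold = kT(temperature)
    flagged = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            diff = abs(rows[i]["depth"] - rows[j]["depth"])
            if diff > threshold:
                flagged.append((rows[i]["label"], rows[j]["label"], float(diff)))
    return ComparisonResult(table=table, flagged=flagged, threshold=threshold)


# -- fes.dat I/O --------------------------------------------------------


def write_fes(F: FESGrid, path, header_extra: str | None = None) -> None:
    """Write a grid as PLUMED-style fes.dat text.

    Header ``#! FIELDS <cv names> free err``; rows in grid-major order with a
    blank line between outer-axis blocks (2-D grids).
    """
    names = [ax.name for ax in F.axes]
    err = F.stderr if F.stderr is not None else np.full_like(F.values, np.nan)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + " free err\n")
        fh.write(
            f"# entropic_corrected={F.entropic_corrected} zero_shifted={F.zero_shifted} "
            f"shift_window={F.shift_window[0]},{F.shift_window[1]}\n"
        )
        if header_extra:
            fh.write(f"# {header_extra}\n")
        if F.values.ndim == 1:
            for x, v, e in zip(F.axes[0].nodes, F.values, err):
                fh.write(f"{x:.10g} {v:.10g} {e:.10g}\n")
        else:
            for i, x in enumerate(F.axes[0].nodes):
                for j, y in enumerate(F.axes[1].nodes):
                    fh.write(f"{x:.10g} {y:.10g} {F.values[i, j]:.10g} {err[i, j]:.10g}\n")
                fh.write("\n")


def read_fes(path) -> FESGrid:
    """Read back a fes.dat file written by :func:`write_fes`."""
    flags = {"entropic_corrected": False, "zero_shifted": False}
    shift_window = (1.6, 1.8)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        fields = first.split()[2:]
        if fields[-2:] != ["free", "err"]:
            raise ValueError(f"{path}: expected trailing 'free err' columns")
        names = fields[:-2]
        rows = []
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "entropic_corrected=" in line:
                    for tok in line.lstrip("# ").split():
                        if tok.startswith("entropic_corrected="):
                            flags["entropic_corrected"] = tok.endswith("True")
                        elif tok.startswith("zero_shifted="):
                            flags["zero_shifted"] = tok.endswith("True")
                        elif tok.startswith("shift_window="):
                            a, b = tok.split("=")[1].split(",")
                            shift_window = (float(a), float(b))
                continue
            if line:
                rows.append([float(t) for t in line.split()])
    data = np.array(rows)
    axes = []
    for k, name in enumerate(names):
        vals = np.unique(data[:, k])
        spacing = float(np.min(np.diff(vals))) if len(vals) > 1 else 1.0
        periodic = name == "torsion"
        hi = vals[-1] + spacing if periodic else vals[-1]
        axes.append(Axis(name, float(vals[0]), float(hi), spacing, periodic=periodic))
    shape = tuple(ax.n_nodes for ax in axes)
    values = np.full(shape, np.nan)
    stderr = np.full(shape, np.nan)
    for row in data:
        idx = tuple(
            int(round((row[k] - axes[k].lo) / axes[k].spacing)) for k in range(len(axes))
        )
        values[idx] = row[len(axes)]
        stderr[idx] = row[len(axes) + 1]
    if np.all(np.isnan(stderr)):
        stderr = None
    return FESGrid(
        axes=tuple(axes), values=values, stderr=stderr,
        entropic_corrected=flags["entropic_corrected"],
        zero_shifted=flags["zero_shifted"],
        shift_window=shift_window,
    )
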