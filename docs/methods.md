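# Methods

This note records the model, the estimators, the numerical choices and the
limits of what the desk-scale samplers can show. Units throughout: nm,
kJ/mol, radians (degrees only in reports), K; R = 8.3145×10⁻³ kJ mol⁻¹ K⁻¹;
the Coulomb conversion factor is f = 138.935458 kJ mol⁻¹ nm e⁻².

## System model

Molecules are rigid planar carbon skeletons: a regular hexagon (circumradius
= bond length, 0.14 nm by default) extended acene-style, each fused ring
sharing a vertical edge and adding four atoms (6/10/14/18 for 1–4 rings).
The four-ring template is tetracene-like; a compact pyrene-like topology is
not built atom-for-atom — the pipeline, not the chemistry, is under test.
Hydrogens are merged into carbon-like united atoms (generic style:
σ = 0.355 nm, ε = 0.29 kJ/mol, q = 0); real charges and per-atom parameters
enter through the plain-text topology format. Rigidity means every bonded
term vanishes identically; the Hamiltonian is purely intermolecular.

Nonbonded interactions use plain-truncated 12-6 Lennard-Jones and
constant-shifted reaction-field Coulomb,
V_rf(r) = f q₁q₂ (1/r + k_rf r² − c_rf) with
k_rf = (ε_rf−1)/((2ε_rf+1) r_c³) and c_rf chosen so V_rf(r_c) = 0 —
the standard continuous-potential RF form. Defaults: r_c = 1.4 nm for both
terms, ε_rf = 54, Lorentz–Berthelot mixing (geometric mixing available for
OPLS-style parameter sets), no dispersion correction. There is no explicit
water: ε_rf acts as a configured dielectric screening. A one-sided harmonic
wall (onset 2.0 nm, k = 200 kJ mol⁻¹ nm⁻²) on the COG distance confines
sampling to the first two interaction shells. The box (5 nm) enters only
through the minimum-image convention.

## Collective variables

* distance — Euclidean distance between the ring-atom COGs, minimum image;
* torsion — the dihedral over (anchor_A, COG_A, COG_B, anchor_B), signed,
  in (−π, π]. Sign convention: positive when the far anchor is rotated
  right-handed about the COG_A→COG_B axis; exchanging molecule labels flips
  the sign. The anchor defaults to atom 0 and is configurable — no single
  atom is canonical for this CV, so the choice is exposed;
* normal angle — the angle between best-fit ring-plane normals (smallest
  principal direction of the centered ring coordinates), folded to [0, π/2]
  because a plane normal has no preferred sign. For exactly planar rings
  this equals the three-atom cross-product normal, which the tests verify.

Molecule B is shifted coherently to its minimum image before any CV is
measured, so all three CVs see the same periodic image.

## Samplers

**Rigid-dimer Monte Carlo.** Metropolis sampling at 300 K alternating
single-molecule translations (uniform in a cube) and rotations (random axis,
uniform angle) about the ring COG; acceptance exp(−ΔU/k_BT) on
U = nonbonded + wall + bias. Move sizes are tuned toward 30–50 % acceptance
during a discarded burn-in (default 5000 moves, caps 0.5 nm and π) and then
frozen — continued tuning would break detailed balance. The initial state is
stacked at 1.0 nm with seed-derived random orientations. One MC move plays
the role of one MD step for all stride accounting. The inner loop is a
numba kernel; all randomness is pre-drawn from the seeded generator in
Python, so trajectories are bit-reproducible and independent of how the loop
is chunked. Each molecule's plane normal is carried along and rotated with
it — exact for rigid bodies and cheaper than refitting a plane per frame.

**CV-space Langevin.** Overdamped Euler–Maruyama,
s ← s − (dt/ξ) U′(s) + √(2k_BT dt/ξ) η, with reflecting bounds; defaults
dt = 5×10⁻⁴, ξ = 1 (CV-time units; only products of dt with mobility are
meaningful). This is the validation channel: on analytic potentials the
exact free energy is available by quadrature.

A generic 1-D Metropolis sampler (`metropolis_cv_sample`) shares the
acceptance rule and serves the closed-form checks (harmonic variance kT/k,
two-state populations).

## Well-tempered bias

Hills are deposited every 500 steps on (distance, torsion) with w₀ = 1
kJ/mol, widths (0.05 nm, 0.2 rad), γ = 5; heights follow
w = w₀ exp(−V/((γ−1)k_BT)). The bias lives on a regular grid (default
0.01 nm × 0.025 rad, torsion periodic, distance clamped with a one-time
warning — the wall normally keeps the walker inside), evaluated by bilinear
interpolation, with Gaussians truncated at 6σ (error < 10⁻⁸ of a height).
Bilinear interpolation carries a discretization error of roughly
Δ²|V″|/8 ≈ 1 % of a hill height near peaks at the default resolution —
irrelevant for sampling; the exact-summation cross-checks therefore run on a
finer validation grid (0.00125 nm × 0.005 rad) where the measured error is
~2×10⁻⁴ kJ/mol. Frames that coincide with a deposition are recorded
*before* the hill lands, so a frame's stored bias is the bias that actually
acted on it.

The final FES uses the time-averaged bias over the last half of deposition
epochs, F = −γ/(γ−1)·⟨V⟩ — the standard variance reduction; the
instantaneous-final-bias estimate is also available. On the double well
(h = 10 kJ/mol, 2×10⁶ steps, hill width 0.1) this recovers the symmetric ΔF
and the barrier to within a few tenths of kJ/mol.

## Reweighting

Primary variant: frame weights w_t ∝ exp(β[V(s_t, t) − c(t)]) with

c(t) = (1/β) ln [ Σ exp(βγV/(γ−1)) / Σ exp(βV/(γ−1)) ]

summed over the bias-grid nodes at the frame's deposition epoch (computed by
replaying the hill list; log-sum-exp for stability). A `final_bias` fallback
(w_t ∝ exp(βV_final(s_t))) is provided; on the double-well benchmark it
agrees clearly less well with the bias-derived FES, so the time-dependent
offset is the default. The first half of a trajectory is treated as the
equilibration transient of the bias and discarded before reweighting in the
consistency checks. Weighted histograms bin on grid-node-centred edges, so a
zero-bias reweight reproduces the plain histogram estimator bit-for-bit.

Two estimator systematics are worth naming. The bias-derived FES is the true
profile smoothed by the Gaussian hill kernel, a bias of ≈ ½σ²|F″| (≈ 0.2–0.4
kJ/mol at the wells/barrier of the validation landscape); the reweighted
histogram has no such smoothing. Consistency between the two is therefore
asserted within 3× the combined block standard errors *plus* this computable
smoothing term.

## Entropic correction, zero shift, binding modes

In n = 3 dimensions the volume element inflates radial densities by r²;
adding ΔV(r) = (n−1)RT ln r removes it. The ideal-gas dimer (ε = q = 0, wall
only) is the package's ground truth here: its corrected, zero-shifted radial
profile must be flat — with 10⁶ MC moves the residual ripple is ≲ 0.3 kJ/mol
over 0.4–1.7 nm. Nodes at r ≤ 0 are set to +∞ (outside the physical
domain). The zero shift subtracts the angle-averaged mean over the
1.6–1.8 nm window (operationalizing "flat by ≈1.7 nm"); it is idempotent and
removes constant gauges exactly.

Binding summaries take the global minimum within the first (0.4–0.7 nm) and
second (0.8–1.1 nm) interaction shells of a corrected, zero-shifted surface.
The mode label reads the normal angle at the first-shell minimum: ≥ 60°
T-shaped, ≤ 30° stacked, otherwise mixed (thresholds configurable; they
operationalize the qualitative perpendicular/parallel language of the
field). Depths are reported relative to the zeroed tail and clipped at zero;
a flat profile yields depth 0 and "mixed" with a warning. Profile comparison
tabulates first-shell depths and flags pairs differing by more than
k_BT = 2.494 kJ/mol at 300 K — gaps below thermal energy are not
meaningfully distinguishable.

## Block-average errors and convergence

The trajectory is cut into contiguous equal blocks (trailing partial block
dropped); each block yields a weighted-histogram FES; per-node errors are
the weighted spread across blocks with blocks weighted by their total
weight, n_eff = (ΣW)²/ΣW², stderr = s/√n_eff — invariant under uniform
weight rescaling, and reducing to the textbook d/2 for two equal blocks.
Per-node errors are defined only where every block populates the node.

The convergence curve averages per-node errors over the nodes populated at
*every* block size — without this, rare nodes that only qualify at large
blocks fake a rising curve even on i.i.d. data. The verdict fits avg error
against log₂(block size) over the largest three sizes; slope below the
tolerance reads as converged. The default tolerance, 0.05 kJ/mol per
doubling, matches the ~0.1–1 kJ/mol error scale of the dimer pipeline;
synthetic fixtures with smaller error scales pass a proportionally smaller
tolerance. Pipeline curves are computed on the 1-D distance projection
(every node populated in every block); the 2-D reweighted surface gets
per-node errors at an 8-block size, NaN where undefined.

The block-analysis fixture for the not-converged case is a slow AR(1) mode
(φ = 0.999, correlation time ≫ the largest block) underneath unit fast
sampling noise: the fast component keeps every bin populated in every block
(a pure slow series parks in one bin per block and leaves the estimator
undefined at small blocks), while the slow drift is exactly what block
analysis must detect.

## Study conditions and problem sizes

Defaults are fixed once and shared by the tests, the examples and the
acceptance script: dimer runs use 5×10⁵ MC moves (record stride 10, hills
every 500); the ideal-gas check uses 10⁶ moves; the double-well validation
uses 2×10⁶ Langevin steps (4000 hills) with hill width 0.1 on a dimensionless
CV, three seeds with a majority verdict for stochastic checks. These lengths
were chosen so that the block-error curves of the corresponding runs are
flat — the method's own convergence criterion — with margin on one CPU core.

## What the synthetic systems do and do not show

The generators emulate: planar-ring geometry with realistic bond lengths,
r²-Jacobian statistics of a confined pair, analytic landscapes with known
free energies, and autocorrelation structure for error estimators. They do
not emulate explicit solvation: there is no water structure, so
solvent-mediated second-shell features, hydrophobic contributions and
force-field-specific water models are out of reach, and the absolute well
depths produced here (≈ −4.5 kJ/mol radial-angle-resolved for the hexagon
pair) characterize the implicit-solvent toy Hamiltonian, not any published
explicit-solvent value. Passing tests certify the estimators — bias
deposition, reweighting, corrections, error bars — not the chemistry of any
particular force field.

## Known limitations

* Rigid bodies only: no conformational flexibility, no bonded terms.
* Two fixed CV types for biasing (distance, torsion); the normal angle is
  reweighting-only, mirroring the intended workflow.
* The linear acene series stands in for all "larger aromatic" shapes;
  compact fused topologies (pyrene-like) are approximated by ring count.
* c(t) replay scales with bias-grid size × hill count; at the default
  resolution this is ~1–2 s per 10³ hills but grows quickly on finer grids.
* The Langevin channel is 1-D; 2-D analytic validation would require a
  vector-gradient integrator (the grid and reweighting layers are already
  dimension-agnostic).
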