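"""Full dimerization pipeline for a benzene-like hexagon pair.

Runs well-tempered metadynamics Monte Carlo on the COG-distance/torsion pair,
then post-processes: bias -> FES, reweighted projection onto distance x
plane-normal angle, entropic (Jacobian) correction, zero shift at the flat
tail, binding-mode extraction and block-error convergence check. All outputs
(COLVAR, HILLS, fes.dat, fes_reweighted.dat, binding.json, blockerror.tsv)
land in the run directory.
"""

import json

from dimerfes import pipeline
from dimerfes.pipeline import RunConfig

cfg = RunConfig(seed=1, n_steps=500_000)
run_dir = pipeline.run(cfg, "example_output/hexagon_run")
result = pipeline.analyze(run_dir)

rep = result["report"]
print(json.dumps(rep, indent=2))

first = rep["first_shell"]
print(f"\nFirst interaction shell: {first['depth_kj_mol']:.2f} kJ/mol at "
      f"{first['distance_nm']:.2f} nm, plane angle {first['angle_deg']:.0f} deg "
      f"-> {rep['mode']} binding mode.")
print("A perpendicular (~90 deg) minimum near 0.55 nm with a few-kJ/mol depth is")
print("the classic T-shaped aromatic contact; the second shell is the shallower")
print("solvent-separated-like minimum near 0.9 nm.")
print(f"Block-error curve flat -> converged: {rep['converged']}")
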