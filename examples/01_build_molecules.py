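"""Build the synthetic planar ring molecules and write their topology/XYZ files.

The templates are rigid carbon-only stand-ins for small aromatics: a benzene-
like hexagon up to a tetracene-like linear four-ring acene. Printed below are
the atom counts, the geometry checks (planarity, centred ring COG) and the
files written.
"""

from pathlib import Path

import numpy as np

from dimerfes import make_ring_template, read_topology, write_topology, write_xyz

outdir = Path("example_output/molecules")
outdir.mkdir(parents=True, exist_ok=True)

for n_rings in (1, 2, 3, 4):
    t = make_ring_template(n_rings, bond_length=0.14)
    radius = np.linalg.norm(t.coords, axis=1).max()
    print(
        f"{t.name}: {len(t.atoms):2d} atoms, max |z| = {abs(t.coords[:, 2]).max():.1e} nm "
        f"(planar), radius {radius:.3f} nm"
    )
    topo = outdir / f"{t.name}.top"
    write_topology(t, topo)
    write_xyz(t.coords, outdir / f"{t.name}.xyz", comment=f"{t.name} body frame")
    back = read_topology(topo)
    assert np.allclose(back.coords, t.coords)

print(f"\ntopologies and XYZ files written to {outdir}/")
print("Each added fused ring contributes 4 atoms (6, 10, 14, 18): the acene series.")
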