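"""Bragg-peak emergence in the HC point pattern.

Compares the structure factor of the HC centroids before and after the
patterning protocol: the disordered mosaic has a flat, liquid-like S(q),
while the final checkerboard develops sharp peaks at the reciprocal
lattice vectors of the HC rows.
"""

import numpy as np

from corti_vertex import ModelParams, ProtocolConfig, RegionSpec
from corti_vertex.analysis import CentroidSet, structure_factor
from corti_vertex.protocols import run_full

spec = RegionSpec()
params = ModelParams()
cfg = ProtocolConfig(steps_stage1=4000, steps_stage2=4000, snapshot_every=2000)
t1, t2 = run_full(spec, params, cfg, seed=2)

initial = CentroidSet.from_state(t1.snapshots[0][1]).hc()
final = CentroidSet.from_state(t2.final_state).hc()

qs = np.linspace(-8.0, 8.0, 96)
S0 = structure_factor(initial, qx=qs, qy=qs).S
S1 = structure_factor(final, qx=qs, qy=qs).S

qmag = np.hypot(*np.meshgrid(qs, qs, indexing="ij"))
mask = qmag > 1.0  # skip the forward-scattering peak S(0) = N
k = np.argmax(np.where(mask, S1, -np.inf))
qx, qy = qs[k // len(qs)], qs[k % len(qs)]
print(f"N = {final.n} hair cells")
print(f"strongest Bragg peak at q = ({qx:.2f}, {qy:.2f}), "
      f"|q| = {np.hypot(qx, qy):.2f}")
print(f"S(q*) final / initial: {S1.ravel()[k]:.1f} / {S0.ravel()[k]:.1f} "
      f"= {S1.ravel()[k] / max(S0.ravel()[k], 1e-9):.1f}x")
print("A ratio well above 1 is the crystallisation signature: the "
      "shear-compacted HCs develop long-range positional order.")
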