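"""Run the default two-stage patterning protocol on a reduced schedule.

Builds the disordered 12x12 tissue (pre-formed IHC/pillar rows, lateral
inhibition in the OHC zone), runs the compaction stage (shear +
compression + HC-HC repulsion) and the refinement stage (elevated SC:SC
and top-border tension), and prints the order parameters before and
after.
"""

import numpy as np

from corti_vertex import ModelParams, ProtocolConfig, RegionSpec
from corti_vertex.protocols import run_full

spec = RegionSpec()                 # 12x12 lattice, 5-row OHC zone
params = ModelParams()              # calibrated defaults
cfg = ProtocolConfig(steps_stage1=4000, steps_stage2=4000,
                     snapshot_every=500)

t1, t2 = run_full(spec, params, cfg, seed=1)

start = t1.metrics.iloc[0]
mid = t1.metrics.iloc[-1]
end = t2.metrics.iloc[-1]
print(f"{'':>22}  start   stage1-end  stage2-end")
for key, label in [("mean_sc_neighbors", "SC neighbours / HC"),
                   ("mean_psi6_star", "hexagonal order psi6*"),
                   ("area_ratio", "HC/SC area ratio"),
                   ("n_hc", "HC count"),
                   ("hc_rows", "HC rows")]:
    print(f"{label:>22}  {start[key]:6.2f} {mid[key]:10.2f} {end[key]:11.2f}")

n_t1 = sum(e.kind == "T1" for t in (t1, t2) for e in t.events)
n_t2 = sum(e.kind == "T2" for t in (t1, t2) for e in t.events)
print(f"\n{n_t1} intercalations (T1), {n_t2} delaminations (T2)")
print("Falling SC-neighbour counts and a rising area ratio mark the "
      "transition from the disordered mosaic toward the checkerboard; "
      "the modal SC-neighbour count of a fully refined middle-row HC is 4.")
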