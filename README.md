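# corti-vertex

A 2D vertex-model simulator and analysis toolkit for the mechanical
patterning of the organ of Corti — the strip of sensory epithelium in
the mammalian cochlea where outer hair cells (OHCs) and supporting cells
(SCs) rearrange from a disordered salt-and-pepper mosaic into an ordered
checkerboard of exactly three HC rows.

The package is for researchers in tissue mechanics and inner-ear
development who want to simulate the shear-driven ordering hypothesis,
perturb it in silico, or score the same order parameters on their own
segmented epithelia (the analysis functions accept generic centroid
tables as well as simulated tissues).

## The model

Each cell is a polygon on a doubly periodic lattice. The tissue energy
is the standard vertex-model form plus a steric HC–HC repulsion acting
through cell centroids:

    E = Σ_n [ α_n/2 (A_n − A_{n,0})² + Σ_(ij) γ_n^{ij} l_n^{ij}
              + Γ_n/2 L_n² + Σ_(m≠n) σ_nm (D/R_nm)^κ ]

and hair cells feel external shear/compression forces conveyed from the
nuclear layer,

    F_i = η y_cm x̂ + ζ y_cm ∇_i y_cm ,

with `y_cm` measured from the pillar-cell row. Vertices follow gradient
descent with fluctuation forces; junctions below a threshold length
intercalate (T1), cells below a threshold area delaminate (T2), and SCs
in the OHC zone keep differentiating into HCs under lateral inhibition
(no HC neighbour) up to the budget that fits three rows.

Stage 1 (compaction) runs shear + compression + repulsion; stage 2
(refinement) raises SC:SC junction tension above HC:SC tension and
constricts the top border. Perturbation protocols start from a stage-2
endpoint: myosin inhibition (tensions reduced and equated, shear off),
single-cell ablation (contractility spike until delamination), and an
adhesion-only alternative model (differential tension without global
forces). The analysis suite computes SC-neighbour counts, the
stretch-corrected hexagonal bond-order parameter ψ₆*, HC/SC area ratios,
OHC row classification, the structure factor S(q) with iterative
straightening, event rates and displacement profiles.

## A worked example

```sh
python examples/run_two_stage.py
```

prints, for one seed of a reduced-schedule run:

```
                        start   stage1-end  stage2-end
    SC neighbours / HC    5.78       6.29        4.71
 hexagonal order psi6*    0.48       0.42        0.50
      HC/SC area ratio    1.00       1.47        1.90
              HC count   18.00      18.00       18.00
               HC rows    2.00       3.00        1.00

3168 intercalations (T1), 9 delaminations (T2)
```

Reading the columns: the disordered mosaic starts with ~6 SC contacts
per hair cell and no area asymmetry; compaction pulls the HCs into a
dense band (area ratio ≈ 1.5); refinement then squeezes SC:SC contacts
so each analysed HC approaches the checkerboard value of 4 SC
neighbours while the area ratio keeps rising. Single-seed,
single-snapshot values such as the instantaneous row count are noisy —
the replicate studies in `scripts/acceptance.py` are the quantitative
statement. `examples/` contains
similar narrative scripts for the order parameters on known patterns
(`order_parameters.py`), the perturbation protocols
(`perturbations.py`) and Bragg-peak emergence (`structure_factor.py`).

The thin CLI wraps the same library:

```sh
corti-vertex run --protocol full --seed 1 --out out/
corti-vertex analyze --in out/final.json
corti-vertex fixture --kind checkerboard-strip --out strip.json
```

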