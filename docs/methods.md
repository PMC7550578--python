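# Methods

## The model

`corti-vertex` simulates the apical surface of the embryonic organ of
Corti as a 2D vertex model on a doubly periodic box. Each cell is a
polygon defined by shared vertices; the tissue's mechanical energy is

    E = Σ_n [ α_n/2 (A_n − A_n,0)²  +  Σ_(ij) γ_n^ij l_n^ij
              + Γ_n/2 L_n²  +  Σ_(m≠n) σ_nm (D / R_nm)^κ ]

summed over cells *n*, with cell area *A*, perimeter *L*, junction
lengths *l*, and centroid-to-centroid distances *R* between hair-cell
(HC) pairs. The junction sum runs per cell, so each physical junction is
counted once for each of its two owners; the default tensions fold that
factor of two in. The last term is a steep power-law repulsion (κ = 8 by
default) that stands in for the steric interaction of HC nuclei in the
sub-apical layer; it couples HC pairs only, through their vertex-mean
centroids, with periodic minimum-image distances.

Hair cells additionally feel external forces that model the global shear
and compression conveyed from the nuclear layer (hypothesised to be
driven by Hensen-cell migration lateral to the sensory band):

    F_i = η y_cm x̂ + ζ y_cm ∇_i y_cm ,

applied to every vertex *i* of every HC, where `y_cm` is the HC
centroid's distance from the pillar-cell row and `∇_i y_cm = ŷ/N` for
the vertex-mean centroid. η > 0 shears the band along the row axis with
a linear gradient; ζ < 0 is the restoring sign of a quadratic energy in
`y_cm` and compresses HCs toward the pillar row.

Vertices move by explicit gradient descent,
`x(t+1) = x(t) + ε(−∇E + F_ext + F_noise)`, with a uniform
per-component fluctuation force redrawn every `k_noise` steps. A step
that would invert a cell is retried with a halved step size (8 times),
then the offending cells' vertices are frozen for that step.

Topological moves run interleaved with the mechanics, at most one per
step, shortest junction first: a junction below the threshold length
`l_min` collapses and re-extends perpendicular at `1.5 l_min` (a T1
intercalation; re-attempted at half lengths inside thin cells), after
which it is immune to further T1s for a lockout window; a cell below the
threshold area `A_min` is first shrunk to a triangle through forced T1s
and then removed, its vertices merged at the centroid (T2 delamination).
T2 is restricted to cells with supporting-cell (SC) morphology unless HC
removal is explicitly enabled (ablation does enable it when the target
is a HC). Junctions touching the pre-formed pillar/inner-hair-cell (IHC)
rows never intercalate. On the 3-valent meshes produced here both moves
preserve 3-valence, and the mesh invariants (each junction shared by
exactly two cells, positive areas, toroidal Euler characteristic) are
audited in the tests after every event type.

## Initial condition

A 12×12 hexagonal lattice tiles the torus (all vertices 3-valent).
Stripes along y assign regions: two rows of generic outside cells, one
IHC row (alternating IHC/SC), one pillar row, a five-row lateral-
inhibition (OHC) zone, and three more outside rows on top. Junctions
separating pillar cells from non-pillar cells carry a high tension so
relaxation straightens the boundary into the reference line used by the
shear force. The lattice is then melted by re-drawing every junction
tension in [0.1, 3]×γ₀ and every preferred area in [0.3, 1.7]×Ā every 80
steps for 15 cycles with T1s active, which yields the heterogeneous
polygon-class distribution of the undifferentiated epithelium; the
pillar/IHC rows keep their parameters throughout. Finally HC fate is
assigned in the OHC zone by random sequential adsorption: random SCs
with no HC neighbour differentiate until none remain — a maximal
independent set of the zone adjacency graph — subject to the three-row
budget below.

Differentiation continues during the simulation under the same rule (an
SC in the zone with no HC neighbour may convert), with two constraints:

* a cap of `3·⌈cols/2⌉` HCs (18 for the default width), the number that
  fits exactly three checkerboard rows on the periodic strip (no two HCs
  may share a junction, so at most every other cell of a row carries HC
  fate) — without it, extra HCs nucleate a fourth row, an artifact of
  the periodic boundary;
* a clearance condition: no existing HC centroid within the repulsion
  range `D`. A cell that differentiates while wedged between two
  repelling HCs is crushed to zero area, and since HC delamination is
  forbidden this stalls the integrator. Physically this is the packing
  constraint of the HC nuclear layer.

## Protocols

**Stage 1 (compaction, 8000 steps).** Shear, compression and repulsion
act on HCs; HC apices are stiffer (α = 4 vs 1) and more contractile
(Γ = 0.2 vs 0.04) than SCs and prefer a larger area. All junction
classes share the default tension except the pillar boundary and a
moderate interfacial tension toward the outside region that keeps the
band cohesive while SCs are squeezed out. At completion, outside cells
bordering the zone are relabelled top-boundary cells, and only then are
statistics taken from the endpoint.

**Stage 2 (refinement, 8000 steps).** SC:SC junction tension rises well
above HC:SC tension (1.6 vs 0.12) and the OHC-facing top-boundary
junctions are tensioned to constrict the band. This shortens SC:SC
contacts, converts residual five-contact configurations into the
checkerboard topology (HC quadrilaterals whose corners are short SC:SC
junctions), and raises the HC/SC apical area ratio.

**Myosin inhibition (blebbistatin).** From a stage-2 endpoint: all
junction tensions are reduced and equated (γ = 0.5 γ₀ for every class,
including the pillar boundary, following the description of the
perturbation), contractility is halved, and shear/compression are
switched off. The control arm continues with unmodified stage-2
parameters.

**Ablation.** From a stage-2 endpoint, one cell's contractility is
multiplied by 100; it shrinks through forced T1s and delaminates. The
first-ring neighbours are frozen at ablation time and their relative
area change is recorded at a fixed step (400) after the perturbation.

**Adhesion-only alternative model.** The same initializer, but η = ζ = 0,
σ = 0, no HC/SC difference in α or Γ, and the stage-2 differential
tensions active from the start — the organisation, if any, must come
from the tensile differences alone. (A variant that keeps the nuclear
repulsion orders nearly as well as the full model, because the repulsion
is itself an ordering field; it is therefore not a meaningful
"local-forces-only" control.)

## Order parameters

* **SC-neighbour count** of each analysed HC (junction-sharing SC
  neighbours in the mesh; Voronoi adjacency for bare centroid tables).
  Analysed HCs are those touching neither the pillar row nor the
  top/outside border.
* **ψ₆\*** — bond-orientational hexagonal order corrected for the row-
  axis stretch: neighbours of a HC are its Voronoi neighbours among HC
  centroids; the local row axis is a total-least-squares line through
  the cell and its middle-row (OHC2) neighbours; an ellipse fit
  (direct least-squares, second-moment fallback, axis ratio capped at 3)
  gives the stretch ratio r_e ≥ 1; neighbour positions are compressed by
  r_e along the axis and scored with |ψ₆| ∈ [0, 1]. Cells with fewer
  than three neighbours or unbounded Voronoi regions are excluded.
* **HC/SC area ratio** — mean over (analysed HC, adjacent SC) pairs of
  the area quotient.
* **Row classification** — OHC1 border the pillar row, OHC3 border the
  top/outside region, the rest are OHC2. The row *count* uses 1D gap
  clustering of HC y-centroids with a gap threshold of 0.5× the median
  HC nearest-neighbour spacing, after subtracting the collective tilt of
  the lattice. The tilt is estimated from the median angle of
  near-horizontal neighbour bonds and then refined over a ±4° scan to
  the value whose projection decomposes most cleanly into bands (a
  1-parameter fit of the helical pitch). The correction is needed
  because sustained shear on a torus slides the ordered rows into a
  slightly tilted — in the extreme, helical — state whose rows have no
  gaps in raw y; a one-degree tilt error alone smears the projected
  bands by half a cell width across the default box.
* **Structure factor** S(q) = (1/N)|Σ exp(−iq·r)|² of HC centroids on a
  square q-grid, after iterative straightening of the row axis when the
  pattern is curved (origin walks the OHC2 backbone base-to-apex,
  rotating apex-ward cells by the local tilt estimated from nearby
  apex-ward neighbours).
* **Event rates** — T1/T2/differentiation counts per zone cell per unit
  time, and displacement profiles of medial/lateral HCs and SCs in the
  pillar-row frame.

## Parameters, units, and problem sizes

Lengths are in units of the initial hexagon side (cell area
3√3/2 ≈ 2.6), energies in units of the area modulus; one step is ε = 0.02
of gradient-descent time. The published description of this system does
not include its numerical parameter table, so all defaults here are the
package's own calibration, chosen once so that the default pipeline
reproduces the qualitative phenomenology: compaction of the HC mosaic,
falling SC-neighbour counts with a modal value of 4, rising ψ₆\*, a
rising HC/SC area ratio in stage 2, and the documented responses to the
perturbation protocols. The defaults are listed in
`corti_vertex.params` and every one is a config key.

Replicate counts in the tests and the acceptance script (typically 10–30
simulations, 80–200 ablations) are the package's own study sizes, chosen
so the complete suite runs on a single CPU in minutes while retaining
direction-plus-significance statistics for every claim.

## What the synthetic tissue does and does not capture

The generator emulates: a disordered epithelial mosaic with realistic
polygon-class spread, pre-formed straight boundary rows, a
salt-and-pepper fate pattern from lateral inhibition, and the documented
morphological transitions (intercalation, delamination, squeeze-out,
ongoing differentiation). It does not capture: curved cell boundaries
and internal pressure (cells are straight-sided polygons, so HCs end up
rectangular rather than round), the third dimension (nuclear-layer
forces enter only as effective apical forces), cochlear curvature or
base-to-apex gradients (the straightening routine exists for real,
curved data), cell division/death (absent in this tissue at these
stages), and Notch-pathway dynamics (lateral inhibition is rule-based).
Passing tests therefore validate the mechanics, the transitions and the
order-parameter pipeline — not any molecular mechanism.

## Numerical choices and known limitations

* Explicit gradient descent with fixed ε and inversion guards; no
  adaptive integrator. Strict monotone energy descent holds for
  ε ≲ 0.005 on melted lattices; the production ε = 0.02 trades strict
  monotonicity for speed, as usual for vertex models driven by noise.
* One topological event per step, shortest junction first, avoids
  conflicting rewires; a T1 whose both rewirings would invert a polygon
  is skipped and retried later.
* Ties in the Voronoi adjacency (co-circular points) follow Qhull's
  deterministic triangulation; zero-length ridges on degenerate grids
  are filtered by the positive-ridge-length rule.
* The three HC rows of the final state are wavy. The gap-based row
  count is sensitive to this: along a run it can flicker between 1
  (rows merged by meander/tilt) and 3, and individual seeds land on 2
  or 4; the modal count across replicates is 3. A crisper row
  crystallisation presumably needs the original (unpublished) parameter
  table.
* In the adhesion-only alternative model the failure to pattern shows up
  as HC-HC clustering (forbidden contacts) and excess delaminations;
  the centroid-based ψ₆\* of that model nonetheless stays moderate,
  because clustered HCs still pack hexagonally, so ψ₆\* alone does not
  separate the two models under this calibration.
* With sustained shear the ordered band slowly tilts; runs much longer
  than the default schedules drift into the helical state and degrade
  the row statistics rather than improving them.
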