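# Methods

`pedfem` simulates medial displacement calcaneal osteotomy (MDCO) on
parametric synthetic flatfoot models with a quasi-static finite-element
solver, and reproduces the full evaluation protocol of a patient-specific
simulation study: balanced-standing loading, virtual surgery at three
translation distances, simulated-radiograph morphometry, region-partitioned
stress scoring, and validation/comparison statistics.  This note records the
model, its assumptions, the numerical choices, and what the synthetic data
can and cannot show.

## The synthetic foot

Patient CT geometry is replaced by a parametric right foot built from lofted
convex primitives (capsules and ellipsoids) for 16 bone solids — tibia,
fibula, talus, calcaneus, navicular, cuboid, three cuneiforms, five
metatarsals and two toe blocks (hallux and lesser toes, matching the two toe
areas of the plantar partition).  Anatomical fidelity is *not* a goal: the
generator only guarantees that the structures the analysis touches exist and
respond correctly — morphometric landmarks and bone axes, articular facet
element sets, ligament attachment points, and a plantar footprint.

A single `severity` parameter in [0, 1] collapses the medial longitudinal
arch along a sagittal template: planted calcaneal pitch falls from ~22° to
~8°, the talar axis plunges (planted Meary's angle from ~0° to ~ −22°), the
navicular subluxes laterally (talonavicular coverage grows), the forefoot
abducts, and the medial sole concavity flattens.  Per-seed Gaussian jitter
on the template angles and the metatarsal splay reproduces between-subject
dispersion comparable to a clinical flatfoot cohort (SDs of ~3–7° per
radiographic angle).  Cohort defaults: 8 feet, severities evenly spanning
0.5–0.9, body weight 600 N (cohort body masses are not individually
reported anywhere; 600 N is a representative adult value), foot length
250 mm, width 95 mm.

### Meshing

No tetrahedralizer is available, so the foot is meshed on a structured voxel
grid (default spacing 6.5 mm): every occupied cube is split into six
tetrahedra sharing its main diagonal, which makes neighbouring cubes conform
exactly.  Voxels are classified bone / joint-layer ("cartilage") / soft
tissue by signed-distance functions.  Three cleanup passes make the
classification usable at this resolution:

* voxels of *different* bones that touch anywhere in the 26-neighbourhood
  are demoted to the joint layer (they would otherwise weld through shared
  nodes); the cell closer to its own bone surface loses, and a bone is never
  demoted below a survival floor of 10 voxels;
* each bone keeps its largest connected component and is made
  edge-manifold, first by adding bridging voxels (never adjacent to another
  bone), then by pruning; every bone surface is verified watertight;
* every bone below the ankle is buried under at least one voxel shell of
  soft tissue, so no bone pokes through the skin.

Bones, joint layers and soft tissue share interface nodes on the conforming
grid — this realizes the bone–soft-tissue "tie" as a mesh property.  The
ground is a separate hex-meshed slab (10 mm cells, two layers, top face on
Z = 0); the sole starts in grazing contact (1 µm penetration) so the contact
active set exists from the first load increment.

### Joints

Articulations are bridged by the compliant joint layer instead of sliding
bone-to-bone contact: multi-body frictionless contact between thirteen
coarsely voxelized bones is not robust at desk scale, and the stress
*redistribution* the analysis measures is carried by normal load transfer,
which a compliant layer reproduces.  The layer is one voxel (~4–7 mm) thick
— several times anatomical cartilage — so its modulus is scaled up (class
default E = 150 MPa, ν = 0.4, i.e. a thickness/E compliance equivalent to a
~1.5 mm articular layer at ~45 MPa) to keep the joint columns realistically
stiff; with a soft layer the arch columns barely transmit and the forefoot
never loads (the preoperative plantar pattern was the calibration target).
Penalty contact itself
(normal penalty + Coulomb friction with separation) is fully implemented and
exercised by the sole–ground pair and by the solver test suite.

## Materials and loads

Units are mm / N / MPa.  Bones (E = 7300, ν = 0.3), ligaments (260, 0.4),
plantar fascia (350, 0.4) and ground (17000, 0.1) are linear elastic; the
bulk soft tissue is a second-order polynomial hyperelastic solid
(C10 = 0.08556, C01 = −0.05841, C20 = 0.039, C11 = −0.02319, C02 = 0.00851,
D1 = 3.65273, D2 absent), following the established foot-FE material card;
cortical/trabecular distinction is deliberately ignored.  Ligaments and the
five fascia slips are two-node trusses (cross-sections 18.4 and 58.6 mm²)
bound to landmark nodes; they are tension-only by default (compressive
ligaments are nonphysical; `strict_paper_mode`/`tension_only=False` disables
the rectification).  The fascia slips insert on the toe blocks (proximal
phalanx bases), which closes the windlass loop heel → toes.

Balanced standing on one foot: ground reaction Fr = body weight / 2;
Achilles tension Fa = Fr/2 applied as a concentrated +Z force at the
insertion node; leg load Ft + Ff = (3/2) Fr split 6:1 between tibia and
fibula as −Z body forces over the bone elements.  Tibia and fibula nodes may
translate only along Z; the ground base is fully fixed.

## Solver

Quasi-static incremental solve (default 2 increments with automatic
bisection of a failed step, up to 4 halvings).  The residual uses the full
nonlinear internal forces: finite-strain polynomial stress for the soft
tissue (deformation gradient per tet, deviatoric invariants of B̄, volumetric
pressure from (J−1) terms), small-strain elasticity for everything else,
tension-only truss forces, and penalty contact.  The tangent combines the
exact linear stiffness, a consistent finite-difference tangent of the
hyperelastic group (vectorized, symmetrized, cached until the displacement
state moves > 0.2 mm), active tension-only trusses and the current contact
stiffness; it is refactorized (sparse LU) when the contact/truss active set
changes or convergence stagnates, up to `max_refactor` times per increment.
Newton steps are capped at 5 mm/node and backtracking line search guards the
nonsmooth events.

Contact: node-to-triangle penalty with normal stiffness
k_n = penalty_scale · E_soft · h (penalty_scale 1000, h the mesh size), a
quadratic smoothing band of 0.005 h penetration that makes the force C¹, a
weak regularization spring (0.02 N/mm) that keeps open-contact states
nonsingular, and Coulomb friction μ = 0.6 against the ground with a
compliant stick spring k_t = k_n/50 saturated smoothly at μ·f_n (tanh law);
stick anchors accumulate slip once per converged increment.  Bone–bone
articular pairs would be frictionless (μ = 0); the default model carries
them through the joint layer instead.

Convergence: ‖Pᵀ(f_ext − f_int)‖ ≤ rtol · ‖Pᵀ f_ext‖.  The library default
is rtol = 1e−6; the cohort pipeline runs at rtol = 1e−3, which already
closes the global vertical force balance to ≲0.05 % of Fr (the acceptance
bound is 1 %).  Tie couplings (equal-displacement or weighted multi-point
constraints) are eliminated exactly through the projection P, so tied pairs
have zero relative displacement by construction.

## Virtual MDCO

The cut plane contains a line parallel to X, passes 10 mm posterior to the
calcaneofibular-ligament insertion, and is tilted 45° from the ground plane
sloping posterosuperior→anteroinferior.  Calcaneal elements are assigned to
the anterior/posterior fragment by centroid side — the cut is jagged at
voxel scale rather than re-triangulated on the plane, which conserves
element count and volume exactly and avoids hanging nodes on the conforming
grid; the tie couplings absorb the jagged interface.  Interface nodes are
duplicated, the posterior fragment (tuberosity, heel pad attachments,
Achilles insertion, fascia origins) is rigidly translated along +X by the
requested distance, and each translated cut node is tied to an
inverse-distance blend of its nearest anterior partners *at the shifted
position* — pairing after translation is essential: pairing back to the
pre-translation partners would transmit the healed-interface force at the
old location and cancel the varus moment that drives every downstream
effect.  Soft tissue and joint-layer nodes near the fragment follow it with
a smoothstep falloff (30 mm radius), locally reduced until no reference
element inverts; tissue trapped between the sliding fragment and another
bone that cannot deform compatibly is surgically released (those few
elements are removed from the load path and orphaned nodes pinned).

## Measurement and scoring

Simulated radiographs are orthographic projections: the AP beam is −Z
rotated 15° about X toward posterior (weight-bearing dorsoplantar
technique), the lateral beam is along X.  Metatarsal axes are principal axes
of the projected outline's area moments; talar and calcaneal axes and the
talonavicular chords use the generator's planted axis landmarks carried
through the displacement field (a declared surrogate for the radiographic
protocols, which avoids voxel-snapping bias).  Calcaneal pitch comes from
the inferior tangent of the projected calcaneal outline against the ground
line; C5MH is the vertical distance between the lowest medial-cuneiform and
fifth-metatarsal points in 3-D.  All measurements are taken on the deformed
(loaded) configuration; left feet are mirrored to the right-foot convention
first.

Region scoring: plantar areas live on the ground top-layer hex cells under
the sole outline (area 1 hallux, 2 lesser toes; the toe-excluded footprint
in three equal-length thirds, the forefoot third in three equal-width bands
medial→lateral = areas 3–5, the midfoot in two = 6–7, hindfoot = 8); the
talar trochlea elements form a 3×3 equal-count grid (medial 1–3, middle 4–6,
lateral 7–9; anterior rows 1,4,7); the posterior subtalar facet splits into
2×2 equal-count quadrants (medial 1,2; anterior 1,3).  Facet element sets
are trimmed to exact multiples at generation so the equal-count partitions
come out exactly equal.  A region's score is the unweighted sum of element
von Mises stresses as a percentage of the partition total; plantar
partitions are built once per foot (preoperatively) and reused across
conditions so pre/post comparisons score identical sets.

## Statistics

Lin's concordance correlation coefficient uses population (divide-by-n)
moments per the original estimator (`sample_moments` flag for n−1), graded
excellent/good/moderate/poor at 0.99/0.95/0.90 with boundary values falling
to the lower grade.  The Wilcoxon signed-rank test is exact: zeros dropped,
midranks for tied magnitudes, full 2ⁿ enumeration (n ≤ 25), two-sided p by
doubling the smaller tail (capped at 1); at n = 8 the smallest attainable
two-sided p is 2/256 = 0.00781.  Bonferroni over the three translation
distances gives the 0.05/3 → 0.0167 threshold.  Cohort tables report median
(IQR) per condition and the exact p against preop per distance.

Model validation on synthetic data compares measured morphometry against
the generator's planted ground truth via per-parameter CCC — with real
radiographs this slot would hold the clinical measurements.

## Problem sizes and defaults

The default mesh (6.5 mm voxels) yields ~22 k tetrahedra / ~18 k free DOFs
per foot and solves balanced standing in about a minute; the full
8-foot × 4-condition study is ~32 solves.  The test suite exercises a
reduced 3-foot profile (severities 0.5/0.7/0.9, 12 solves) for the
directional cohort checks; the `run_cohort` pipeline default remains 8
feet.  Mesh size, materials, solver tolerances, penalty parameters,
increments and the cut-plane pose are all configuration, since the study
this emulates used a commercial solver whose internals are not reported.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* the analysis needs —
flatfoot morphometry that responds to severity, a plantar footprint with
realistic regional shares, articular facets, and a fragment/tie mechanism
whose medialization produces the clinically reported directions of change
(arch indices up; medial plantar and anterior/medial joint loads up,
lateral/posterior down).  Directional cohort checks on these models test the
mechanical plausibility of the pipeline, not patient-specific accuracy: the
real study's CT geometries, absolute stress magnitudes, and per-patient
medians are not reproducible from synthetic primitives.

Known limitations: no muscle forces other than the Achilles; no bone-bone
sliding at the joints (compliant bonded layers instead); voxel-scale
(6.5 mm) geometric noise in outline-based angles (a few degrees, constant
within a foot so paired comparisons are unaffected); quasi-static stance
only.  Two clinically reported directions are *not* reproduced by the
bonded-joint model and their checks fail honestly in the suite: the
absolute rise of the middle-forefoot plantar share (the medial-column load
shed by the osteotomy flows into the heel here instead of the middle rays —
re-seating of the transverse arch requires sliding joints), and the small
anterior migration of pressure within the posterior subtalar facet (a flat
voxel facet rolls its pressure centroid posteriorly as the calcaneus
pitches up, where the real saddle-shaped facet, oblique to the subtalar
axis, converts inversion into anteromedial migration).  The strong medial
shifts at both joints and the within-forefoot lateralization are
reproduced.
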