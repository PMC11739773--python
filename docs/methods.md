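# Methods

This note documents the models, discrete operators, parameter choices and
known limitations of `reentry-scout`. Everything stated here is exercised
by the test suite or `scripts/acceptance.py`; nothing is asserted that the
code does not compute.

## Tissue model and units

Ventricular anatomy is a conforming simplicial mesh (triangles in 2D,
tetrahedra in 3D) with element-wise tissue labels: HEALTHY, BZ (border
zone — partially viable peri-infarct tissue with slowed conduction) and
CORE (dense scar, electrically non-conducting). Labels live on elements,
not nodes, so an interface facet's status is unambiguous: it is defined by
its two incident elements. Units are mm, ms and mm/ms (numerically equal
to m/s); masses are reported in grams using a myocardial density of
1.053 g/cm³ (configurable), interface areas in cm².

2D models are first-class: every downstream algorithm runs on triangle
meshes, the transmural coordinate is defined as 0 everywhere, and masses /
interface areas use a nominal 1 mm slab thickness, flagged
`masses_2d_nominal` in the output. This keeps the entire pipeline testable
at desk scale against analytic geometry.

## Geometry builders

Slabs (2D/3D), discs, annuli and a truncated-ellipsoid LV shell are
produced by deterministic structured meshers (3D cubes split into six
tetrahedra sharing the main diagonal, which conforms across the grid; the
LV is a layered spherical-coordinate grid collapsed at the apex). Scar is
painted from a parametric `ScarSpec`: element centroids inside a core
region become CORE, centroids within the rim width become BZ, and channel
polylines relabel CORE back to BZ to carve conducting corridors. The
ellipsoid distance used for rims is the scaled-radius approximation
(exact for spheres); rims a few mm wide do not resolve the difference.

Fiber orientation follows the standard rule-based prescription: the
in-plane helix angle rotates linearly across the wall from α_endo at the
endocardium to α_epi at the epicardium. The endpoint angles are not fixed
by any data used here; the defaults ±60° are the textbook values and are
configurable, with the angle measured from +x on slabs and in the local
(circumferential, longitudinal) frame on the LV (frame from the transmural
coordinate gradient; the circumferential direction falls back to +x at the
apex where the frame degenerates). 2D models receive the constant α_endo.

AHA-style segmentation on the LV uses the long-axis coordinate (basal /
mid / apical thirds, apex cap below 15% of the length) and equal-angle
sectors with the anterior reference at +x — the standard 17-segment model
without imaging landmarks, which the idealized geometry cannot supply.
Pacing sites are the conducting node nearest each segment centroid; a
segment that is entirely core loses its site with a warning. Slab and disc
models get n uniformly spaced boundary sites instead (default 8).

## Eikonal propagation

With fiber f and velocities (v_f, v_t), a planar front with normal d
travels at v(d) = √(v_f²(f·d)² + v_t²(1−(f·d)²)), i.e. the quadratic form
√(dᵀMd) with M = v_t²I + (v_f²−v_t²)ffᵀ. The first-arrival time from a
point source is the geodesic distance in the dual metric N = M⁻¹: the
travel time along a straight segment e is √(eᵀNe). The two speeds agree
on- and cross-fiber and differ off-axis (phase vs. group velocity of an
elliptical wavefront); all point-to-point times in this package —
including `edge_travel_time` and both solver modes — use the group-time
√(eᵀNe), which is the physically correct arrival time and makes the
edge-restricted Dijkstra mode a true node-wise upper bound on the
element-wise solver.

The primary solver is an active-list fast-iterative scheme. Per element
and target vertex, candidate arrivals come from the two-point update:
minimize over λ∈[0,1] of T(λ·a+(1−λ)·b) + √((c−x_λ)ᵀN(c−x_λ)), solved in
closed form (clamped quadratic roots plus the two endpoint candidates).
Tetrahedra use the three edge and three pair updates of each face rather
than the full facial minimization — first order, like the scheme itself;
the analytic accuracy checks run on 2D meshes where the triangle update
is complete. Point sources are seeded exactly within a fixed 2 mm ball
(through conducting mesh edges only, and only inside single-tissue
neighbourhoods), which removes the dominant rarefaction-fan error of
first-order schemes: max relative error on the homogeneous 40 mm slab is
1.1% at 0.5 mm edges, halving under one refinement step. Convergence
tolerance is 10⁻³ ms; node order is deterministic, so activation maps are
bit-reproducible. Core is removed from the update stencils (exact
non-conduction), never approximated by a small velocity. Arrival ties in
the steepest-descent predecessor tree break toward the lowest node index.

Conduction-velocity defaults — healthy (0.6, 0.3), BZ (0.25, 0.125)
mm/ms, 2:1 anisotropy — are literature-typical surrogates; the BZ slowing
is what turns anatomical corridors into slow reentry isthmuses. They are
parameters of `VelocityModel`, not claims about any specific dataset.

## Virtual induction

**Collision detection.** After solving one pacing site, the discrete
front direction at a node is the vector from its steepest-descent
predecessor. A conducting edge (a,b) is a head-on collision seed when both
front directions point into the edge (90° cones), oppose each other
(negative dot product — this rejects grazing fronts shearing past obstacle
corners), and the arrival times differ by less than the edge travel time.
Seeds are clustered by midpoint proximity (radius 3 mean edge lengths;
the discrete locus drifts across mesh columns and node-sharing alone
fragments it).

**Line closure.** Beyond the collision zone the two branches merge, and
the crease between them continues until it terminates on scar or the mesh
boundary. On the crease the later branch's front runs parallel to the
line (zero into-edge component) while the other still points across it —
a signature a smooth oblique front never produces — so each cluster is
grown along such "shear" edges, and finally closed by blocking every edge
that joins the two assigned sides directly (the discrete locus jogs across
mesh columns). Without closure the circulating front slips around the free
end of the block line and the measured RTT collapses to a few ms; such
leaked circuits, when they still occur (strongly tilted creases — see
limitations), fall below the 50 ms cutoff and are discarded rather than
miscounted.

**Scar gating.** A cluster is retained only if the loop formed by the
representative edge's two descent paths encloses core tissue (2D:
point-in-polygon test on core element centroids; 3D: the loop passes
within d_scar = 2 mean edge lengths of core). A model without core
therefore yields zero isthmuses by construction.

**RTT.** For each retained isthmus and each direction, all line edges are
blocked, the near side is paced at t = 0, and the eikonal problem
re-solved. The RTT is the minimum over line-spanning edges of the far-side
arrival plus that edge's crossing time, so it is a full-loop time — the
computational cycle length. An unreachable far side is reported as
non-inducible, not an error. On the canonical annular geometry (disc
r = 11 mm with a 9 mm core, isotropic 0.5 mm/ms) the measured RTT is
113.09 ms against the analytic inner-circumference value 113.10 ms, and
doubling all velocities halves it.

**Filter and deduplication.** Circuits with RTT ≤ 50 ms are discarded
(the cutoff is deliberately low: the aim is to catch every focus that
could sustain a small circuit). Total VTs are counted after the filter
and before deduplication; deduplication runs across all circuits,
including same-site duplicates. Two circuits are duplicates when the
maximum Pearson correlation of their cyclically aligned reentry maps
reaches ρ = 0.9: both maps are wrapped modulo their own RTT into loop
phase (two inductions of one circuit differ by a constant phase — where
along the loop the block line sat — which the shift search over a RTT/64
grid absorbs), and the correlation is evaluated on nodes near either
circuit's loop, where a circuit's identity lives; opposite traversal
directions anti-correlate under every shift and never merge. Merging is
union-find; each group is represented by its lowest-RTT member. Per model
the result is the four vulnerability metrics: total VTs, unique VTs, mean
and max RTT over unique circuits (all zero, flagged, when nothing is
inducible). No upper RTT cutoff is applied by default; `rtt_max_ms` exists
for sensitivity analyses.

## Imaging metrics

**FWHM labeling.** Element intensity is the mean of its node intensities;
an element is CORE at ≥ 60% of the maximum intensity, BZ in [40%, 60%),
HEALTHY below. The (0.40, 0.60) defaults are the convention of the
clinical segmentation-software family for enhancement maps; the maximum
is the 100th percentile by default with a robust-percentile option for
noisy fields.

**Corridors.** A conduction corridor is a facet-connected BZ component
that touches CORE and has at least two disjoint patches of BZ–HEALTHY
facets (an entrance and an exit); its weight is component volume times
density. This is a volumetric operationalization of "border zone
surrounded by scar core"; proprietary shell-based corridor definitions
used by clinical software may count differently.

**Interface areas.** An internal facet belongs to an interface when its
two incident elements fall on opposite sides of the partition (healthy vs
BZ∪core, or BZ vs core); boundary facets never count. The raw facet sum
overestimates a smooth interface by a direction-dependent corrugation
factor (measured 1.6× for a sphere on 0.75 mm tetrahedra) that refinement
does not remove, so each facet contributes its area projected onto a
locally fitted interface plane (area-weighted PCA of facet centroids
within 3 facet diameters). Mesh-aligned planar interfaces remain exact
(4.00 cm² on the canonical block), the r = 10 mm sphere comes out 3.2%
high, and the healthy|BZ and healthy|core areas are computed from the same
fitted contributions as healthy|scar, making their additivity exact by
construction. The raw sum is available via `orientation_corrected=False`.

## Cohort statistics

Continuous variables: Mann-Whitney U, exact for groups of ≤ 20 without
ties, tie-corrected normal approximation otherwise — without continuity
correction, so exactly symmetric samples give p = 1. Categorical: Fisher's
exact test. Cox models use lifelines (Efron tie handling, Wald CIs);
hazard ratios are reported on stated per-unit scales (per 10 cm² for
interfaces), and HR(per 10) = HR(per 1)¹⁰ exactly by log-linearity.
Degenerate covariates and non-converged fits are returned flagged, never
silently dropped. The multivariable model is composed automatically:
univariably significant candidates (p < .05) plus LVEF and LV
end-diastolic volume as standard clinical covariates, overridable. ROC
cutoffs are the largest observed-value threshold keeping event sensitivity
at or above the target (default 90%), on the empirical grid for
reproducibility; Kaplan-Meier curves use the product-limit estimator with
a two-group log-rank test. All tests are two-sided; no multiple-testing
correction is applied, and the output headers say so.

## Synthetic cohort

Each subject is a 40 × 40 mm slab (1 mm edges) with a core band anchored
at the left wall (height ~ U(8, 12) mm) and k ∈ {0..3} vertical BZ
channels (width U(2.5, 4) mm, ≥ 8 mm apart; P(k) = 0.20/0.35/0.30/0.15).
Anchoring leaves a conducting margin at the right wall so every channel
participates in at least one loop and unique VTs grow with channel count.
The nodal intensity field encodes the geometry (core 100, BZ 50, healthy
10, optional Gaussian noise), and the model's labels are *defined* as the
FWHM output of that field — the label/intensity round trip is exact in
noise-free mode by construction. Channels are wide enough (≥ 2 element
columns) that element-mean thresholding preserves corridor topology.

Imaging and induction metrics come from the full pipeline per subject
("pipeline" mode, used for the 20-subject end-to-end determinism run) or,
for large-n statistical validation where meshing every subject adds
nothing to the property under test, from parametric distributions with
magnitudes comparable to a post-infarct ICD cohort ("sampled" mode).
Event histories follow an exponential proportional-hazards model: hazard
λ₀·exp(βᵀz) with λ₀ = 0.15/yr, z the chosen metrics standardized over the
realized cohort, default β = {log 1.8 per SD of healthy–scar interface,
log 1.6 per SD of mean RTT}, and uniform censoring over a 6-year window —
together giving a ~30–45% event fraction, matching a contemporary ICD
cohort. The exponential baseline keeps closed-form truth for recovery
tests (Weibull would add a shape parameter without adding testable
structure). Clinical covariates (LVEF ~ N(32, 8)%, LVEDV ~ N(220, 55) mL,
35% secondary prevention) are drawn from a child random stream so they are
independent of scar anatomy. One global seed expands to per-subject
streams via `SeedSequence((seed, subject))`; cohort CSVs are written at
fixed precision and are byte-identical across runs.

What the generator does *not* emulate: realistic LGE texture or scanner
noise, 3D transmural scar architecture, population realism of clinical
covariates, or any correlation structure between anatomy and clinical
covariates. Passing tests therefore demonstrate algorithmic correctness
and statistical calibration under the stated generative model, not
clinical performance.

## Problem sizes

The validation suite runs desk-scale problems chosen for tight analytic
control: 40 mm slabs at 0.25–1 mm edges (1.7k–26k nodes), a 3k-node
annular disc, 200k-tetrahedron interface blocks, 8 pacing sites per slab,
cohorts of 20 (full pipeline) to 2000 (sampled metrics) subjects, and 100
replicates for coverage checks.

## Known limitations

- The collision/closure operators are robust on the canonical fixture
  family but can still leak on strongly tilted creases (e.g. corner pacing
  of an off-axis channel); leaked circuits have near-zero RTT and are
  removed by the 50 ms filter, i.e. the failure mode is a conservative
  missed induction, not a spurious VT.
- The two-point tetrahedral update omits the facial three-point
  minimization; 3D activation maps are first-order accurate with a
  modestly larger constant than 2D.
- Isthmus detection on 3D shells uses the proximity ("abuts core") gate
  rather than a true enclosure test.
- Interface orientation correction assumes the interface is locally
  planar at the 3-facet-diameter scale; features smaller than that are
  smoothed over.
- The duplicate-filter threshold ρ = 0.9 and the RTT/64 shift grid are
  surrogate conventions; the induction engine's internals are this
  package's own discrete operators, documented above, not a re-statement
  of any proprietary tool.
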