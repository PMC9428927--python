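# Methods

`osteorom` maps the osteologically possible range of motion (ROM) of a
ball-and-socket joint from triangle meshes of the two articulating
elements. All lengths are millimetres and all angles degrees.

## Model and procedure

**Shape fitting and rearticulation.** Spheres are fitted to the socket
(acetabulum) and head articular surfaces, cylinders to long-bone shafts.
The sphere fit is the Coope algebraic linear solve (|p|² = 2p·c + k is
linear in the centre c and k = r² − |c|²) followed by Levenberg–Marquardt
refinement of the orthogonal distances |dist(pᵢ, c) − r|; the cylinder fit
initializes its axis from the leading principal component and refines
axis, position and radius jointly. A disarticulated joint is rearticulated
by the pure translation that superimposes the two fitted sphere centres;
orientation is deliberately left to the anatomical coordinate system
(ACS) step, since centroid superimposition alone carries no orientation
information. The difference between socket and head radii is the *joint
spacing*, the standard osteology-only proxy for maximum articular
cartilage thickness (for the default synthetic joint: 20.000 − 17.552 =
2.448 mm).

**Anatomical coordinate system.** The ACS origin is the superimposed
sphere centre; X is abduction(+)/adduction(−), Y flexion(+)/extension(−),
Z long-axis rotation (external +), with the femur hanging toward the
ground in the neutral (0°, 0°, 0°) posture so that Z is the ground
normal. Because the head centre and a long axis parallel to Z cannot fix
the transverse axes, `build_acs` takes an anterior reference direction
(default world +X) and projects it orthogonal to Z to obtain the ABAD
axis; it errors when that reference is parallel to the ground normal, and
also when the fitted long axis is more than 15° away from ±Z (i.e. the
rig is not actually in neutral). The fitted long axis therefore acts as a
neutral-posture check rather than as an axis source.

**Pose model.** Rotations compose in the fixed "XYZ" order with X applied
first, R = R_z(lar) · R_y(fe) · R_x(abad), about ACS axes held fixed in
the proximal (pelvis) frame; the pose grid is defined on these fixed-axis
angle triples. A pose may carry a translational offset t expressed in ACS
axes; the posed vertices are

    v' = R (v − o) + o + t

with o the joint centre. The offset stays fixed in the proximal frame
(it does not rotate with the pose). This single formula serves every
regime: rotating the pre-translated mesh about the displaced centre
o + t — the "rotation centre moved to the offset vertex" picture of the
6-DOF regime — expands to exactly the same map, which is also what makes
the 6-DOF viable set a strict union over its offset vertices.

**Sampling and viability.** The default grid spans FE and LAR −180°..180°
and ABAD −90°..90° inclusive at 5° steps: 73 × 37 × 73 = 197,173 poses.
Each pose is tested for bone-mesh interpenetration and discarded if the
meshes interpenetrate. Regimes:

* `3dof` — rotations only (zero offset);
* `4dof` — rotations plus one static translation (joint-spacing sweeps
  translate along the ACS Y axis, with the sign chosen automatically as
  the one that opens the joint from neutral);
* `6dof` — rotations plus dynamic translation: the offsets are the 26
  vertices of a coarse UV sphere (8 longitude divisions × 4 latitude
  bands → 32 faces) whose radius equals the fitted-radii difference, and
  a pose is viable iff it is collision-free at *at least one* vertex.
  The sphere centre is excluded by default (`include_center` adds it):
  the zero-offset test is the 3-DOF map and is reported separately.

**Collision test.** Two meshes interpenetrate iff a triangle edge of one
strictly pierces the open interior of a triangle of the other, a coplanar
triangle pair overlaps with positive area, or one closed mesh contains
the other entirely (ray-parity containment, tested only when the surfaces
are disjoint and one axis-aligned bounding box nests inside the other).
Touching-but-not-crossing contact — shared vertices, edge-on-edge or
edge-in-plane grazing — is *not* a collision: interpenetration, not
contact, is the criterion, with strict inequalities at tolerance 0 (a
configurable contact tolerance in mm adds a clearance margin). The broad
phase hashes per-triangle AABBs into a uniform grid whose cell edge is
twice the 90th-percentile triangle size, with direct AABB overlap as the
fallback for oversized triangles; the narrow-phase predicate applied to
the surviving candidate pairs is identical to the one used by the
brute-force all-pairs oracle, so the accelerated result equals brute
force by construction (and is verified against it on random instances).
During classification, distal triangles whose distance band from the
rotation centre (widened by the largest offset) cannot overlap any fixed
triangle's band are culled once for all poses; rotation about the centre
preserves these bands, so the cull is exact.

**Cosine-corrected shape space and volumes.** Euler coordinates distort
near gimbal alignment: with R = R_z·R_y·R_x, the first-applied (ABAD) and
last-applied (LAR) axes collapse onto each other as FE approaches ±90°.
The default correction maps a viable pose (abad, fe, lar) to
(abad·cos fe, fe, lar); alternative axis pairings are selectable for
sensitivity checks since cited implementations differ. The ROM volume
(degree³) is the volume of the 3-D alpha complex over the corrected
cloud: Delaunay tetrahedra with circumradius ≤ α are kept and their
volumes summed. α → ∞ recovers the convex hull; the default α is 1.5 ×
the grid step (7.5 at the 5° default), small enough to preserve
concavities and disconnected "islands", large enough to connect
diagonally adjacent grid cells. α is a required, logged parameter of
every reported volume because reported volumes are only comparable at
equal α. Angles are treated as a flat box (the sampled ranges are closed
intervals); a wraparound option duplicates points shifted ±360° along
toroidal axes for topology inspection, at the cost of over-counted
volume. Island counting uses shared-vertex connectivity of the kept
tetrahedra, which is robust to the sliver tetrahedra that gridded inputs
produce.

**Joint-spacing sweep and trends.** `scan_spacing` reruns the 4-DOF
classification at each configured spacing and records viable count and
alpha volume; `fit_trends` reports an OLS linear fit (slope, adjusted R²,
two-sided slope p-value via statsmodels) and a quadratic fit whose
stationary point, when inside the swept range, is one plateau indicator;
a second, scale-free indicator is the first spacing whose count increment
falls below 1% of the grid size. Plateau detection is deliberately
descriptive (the claim it supports is visual, not inferential).
Comparative cartilage thicknesses are transferred between specimens as a
percentage of femoral length, reported to 3 decimals.

**Trace comparison.** An empirical joint-angle trace (time, fe, abad,
lar; flexion +, abduction +, external rotation +) is compared to a ROM
map by snapping each frame to the nearest grid pose (exact half-step ties
break toward zero on each axis, so the comparison never inflates an
excursion) and reading off that pose's viability; frames outside the grid
ranges are flagged and counted unviable. The report gives per-frame
flags, the viable fraction, and contiguous unviable excursions. Nearest-
cell membership (not interpolation) is used because the map is a binary
set on a 5° lattice.

## Synthetic fixtures

The generator builds a parametric hip-like joint with known ground truth
so that every stage is testable without external data: a spherical cup
truncated at a coverage angle, thickened into a closed 2 mm shell and
backed by a plate (standing in for the rest of the pelvis — its only role
is to make "femur through the body wall" poses unviable); and a femur
analogue of head sphere + neck cylinder + wider shaft along −Z. Default
dimensions mimic a small hominin hip: head radius 17.552 mm, cup radius
20.0 mm (spacing 2.448 mm), femoral length 289 mm for the scaling
arithmetic. Cylinder side triangles are subdivided to the head's edge
length so triangle sizes are uniform across the element, as in scanned
bone meshes. Meshes are emitted watertight (verified), with vertex masks
marking the two articular surfaces; optional Gaussian surface noise
displaces vertices along normals under a fixed seed.

For the axially symmetric joint (cup pole +Z) the rotational clearance
has a closed form: the neck (radius r_n, through the centre) reaches the
inner cup rim (polar angle = coverage, distance r_cup) when the femur
tilts by

    180° − coverage − asin(r_n / r_cup)

from −Z. With the defaults (coverage 120°, r_n 8, r_cup 20) this is
36.42°; the collision-based boundary must agree within one grid step.
This is the generator's strongest oracle because it exercises mesh
construction, posing and collision jointly.

The joint-spacing sweep fixture tilts the cup pole to +Y (the socket
faces laterally, as an acetabulum does) with coverage 70° and a nearly
congruent 0.05 mm radial gap, so that Y-translation is the direction that
opens the joint. At 15° grid step and ~300-vertex articular surfaces, the
Table-of-thicknesses sweep (0.764–5.321 mm) yields a monotone viable-pose
curve that stalls around 2.6–3.1 mm and ticks up again at the largest
spacing as the head begins to leave the socket — the same
growth/plateau/disarticulation progression reported for real hips. The
gait-trace generator emits sinusoids with per-axis amplitudes, phase
offsets and Gaussian jitter clipped at 3σ (so amplitude bounds are exact),
deterministic under a fixed seed.

What the synthetic fixtures do *not* emulate: lunate (horseshoe) articular
surfaces, surface roughness and segmentation artefacts of CT meshes,
anatomical asymmetries of a real acetabulum, or soft tissue of any kind.
Passing tests therefore demonstrate that the machinery is correct on
geometry with known answers, not that any particular fossil's viable-pose
counts are reproduced — those require the original specimen meshes.

## Numerical choices

* Mesh load: vertex de-duplication at 1e-8 mm; zero-area faces dropped;
  polygonal OBJ faces fan-triangulated with a warning. Units are taken
  as-is (mm); no autodetection.
* Rigid transforms validated orthonormal with det +1 at 1e-8.
* Collision: strict inequalities with determinant guard 1e-12; coplanarity
  threshold 1e-9 × coordinate scale; shapely decides coplanar overlap.
  Ray-parity uses canned ray directions and retries with the next
  direction when a hit grazes a triangle boundary.
* Sphere/cylinder fits reject inputs whose smallest singular value is
  below 1e-9 × scale (coplanar/collinear degeneracy).
* Cylinder axis sign is canonicalized to a positive Z (then Y, then X)
  component, since ±axis describe the same cylinder.
* Alpha complex: tetrahedra with near-singular circumsphere systems
  (|det| ≤ 1e-12) get infinite circumradius and are never kept.
* Grid divisibility is checked at 1e-9; pose CSV round-trips through
  plain decimal text.
* Problem sizes in the shipped tests and in `scripts/acceptance.py` are
  chosen to keep a full run in the minutes range on a single CPU:
  ~300–1000-vertex articular surfaces, 5° line grids for boundary checks,
  a 15° grid for the six-spacing sweep, 90° grids for set-semantics
  tests. The classification core is O(poses × offsets) with a few
  milliseconds per collision query at these sizes; the full 5° production
  grid (197,173 poses) is the same code path and scales linearly.

## Known limitations

* Rotations about pelvis-fixed ACS axes are assumed (the map lives on a
  fixed grid of angle triples); femur-following axes would need a
  different grid semantics.
* The collision test reports a boolean only — no penetration depth or
  contact area.
* Alpha-shape volumes depend on α; absolute volumes are only meaningful
  with the α logged alongside them.
* The plateau estimate is descriptive, not a formal changepoint test.
* Soft-tissue constraints (ligaments, muscles, capsule) are out of scope
  throughout; all reported envelopes are osteology-only upper bounds.
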