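# Methods

## Physical model and assumptions

The package solves the quasi-static volume-conductor problem
∇·(σ∇φ) = 0 with E = −∇φ. At the 10 Hz stimulation frequency the
capacitive and inductive terms are negligible, so an alternating-current
channel is solved exactly like a direct-current one and phase enters only
through the superposition step. Conductivity is linear and isotropic per
tissue. Electrodes are modelled as equipotential surface patches
(Dirichlet ±0.5 V on the contact nodes, homogeneous Neumann elsewhere);
there is no gel/sponge volume and no contact impedance — a deliberate
simplification that matches the boundary-condition description of the
simulation this package re-implements, and a known limitation for
absolute field magnitudes near the contact edge.

Each channel is calibrated post hoc: the delivered current is evaluated
from the nodal reactions (the entries of K·φ on the electrode node sets,
i.e. the variationally consistent discrete boundary flux) and φ and E are
rescaled linearly so it equals 1 mA. The reaction form makes the anode
and cathode currents agree to solver precision (~1e−12 relative); the
naive per-face σ∇φ·n surface integral is also computed as a diagnostic
but is only first-order accurate and is not used for calibration.

Multichannel stimulation with currents I_i (mA) and phases θ_i is the
phasor sum A = Σ I_i cosθ_i E_i, B = Σ I_i sinθ_i E_i per element; the
reported scalar is the peak-over-cycle norm sqrt(λ_max) of the 2×2 Gram
matrix of (A, B). For the surveyed phases {0°, 180°} the quadrature
component vanishes identically and the scalar reduces to ‖Σ ±I_i E_i‖.
Phase factors at multiples of 90° are table-exact so a polarity flip is
bit-identical.

## Synthetic head geometry

The head is a stand-in, not an anatomical reconstruction: five concentric
shells (white matter 74, gray matter 78, CSF 80, bone 82, skin 85 mm
outer radii) with two 12 mm eyeball spheres centred at (±31, 65, 5) mm.
The eye centres echo the x-range of the reference eyeball-surface
observation coordinates (≈ ±24…44 mm) at an anatomically plausible
anterior position; each eye reaches 84.2 mm from the head centre, i.e.
into the skin shell but not through it.

A cylindrical plug (radius 0.75 of the eye radius) in front of each eye
is carved out so the anterior cap — the cornea region — borders air.
This choice was tested explicitly: filling the plug with skin-conductivity
tissue instead lets surface-borne current bypass the eye through the
film, flattening the eyeball-surface profiles 3–5× and tripling
contralateral cross-talk. The carve reproduces the anatomy that matters
here: facial skin ends at the lid margins, so periocular surface current
is funnelled into the conductive exposed eye surface. The funnel makes
the exposure rim a conductor/insulator junction with a field singularity,
which drives several sampling decisions below.

Meshing: a background lattice (default 6 mm) refined to 2.5 mm in a box
around each eye, plus deterministic ring-sampled points on every tissue
interface sphere (eye surfaces at 1.5 mm), a seeded uniform jitter of
0.03·h to break lattice degeneracies, and a Delaunay tetrahedralisation.
Elements are labeled by centroid membership; hull slivers outside the
skin sphere and the exposure plugs are dropped, and a repair pass
restores the largest dropped tetrahedron at any non-manifold exterior
edge so the boundary stays watertight. Identical parameters and seed give
byte-identical meshes. At the default resolution the head has ~25k nodes
and ~160k tets; total volume is within 0.2% of the analytic ball and
per-tissue volumes in the two x-halves agree within 2% (statistical
mirror symmetry).

## Conductivities

The reference table (S/m at 10 Hz): white matter 0.027656, gray matter
0.027512, CSF 2.0000, bone 0.020028, skin 2.0000·10⁻⁴, eyeball 0.41113.
The skin value is three orders of magnitude below common literature
values; it is nonetheless the reference condition and is kept as the
default. Overrides exist (`ConductivityTable(overrides=...)`,
`conductivity_overrides` in the study config) but are never applied
silently. Two numerical consequences of the quasi-insulating skin are
handled explicitly: the conductivity contrast of ~10⁴ defeats
ILU-preconditioned conjugate gradients (see Solvers), and fields sampled
inside the skin shell are dominated by the ~100× amplified normal
component, which at element scale is discretisation noise (see
Observation points).

## Electrode stations and montage families

Stations are parametric on the synthetic scalp: azimuth from the anterior
+y axis toward +x and elevation above the horizontal, scaled to the 85 mm
skin radius. Forehead stations sit at ±18/±28/±39° azimuth (elevation
20°) from nasal to temporal, a far-temporal station at ±48° (elevation
17°, the normalized direction of the corresponding reference placement),
cheek stations at ±30° (−22°) and low-cheek at ±48° (−56°). Patches are
42 mm × 42 mm squares projected onto the exterior skin surface in
geodesic tangent coordinates; triangles are selected when all three
vertices fall in the (slightly expanded) square, which keeps neighbouring
patches node-disjoint whenever the squares are disjoint. Projected areas
are within 20% of the nominal square at 3 mm resolution.

The azimuths were spread just enough that every pair of simultaneously
driven patches is disjoint — the disjointness invariant is validated for
every montage in the test suite. On a real head the reference coordinates
place some simultaneous patches closer than one edge length (overlapping
at 42 mm); the one-eye family therefore uses its own far-temporal station
at ±56° so that both same-side channels fit.

Families: `separation_sweep` (6 single pairs, nasal/mid/temporal per
side, and the 9 right×left two-pair combinations), `intended_region`
(i–iv single placements targeting one visual-field direction and pairs
I = i+iv, II = i+iii, III = ii+iv), `one_eye` (both channels on one face
side) and `center_boost` (II and III with the centre-targeting channel at
1.5 mA). Anti-phase assigns 180° to the right-side channel of a two-pair
montage (and to the single channel of a one-pair montage), matching the
convention that the cheek electrode becomes the anode.

## Observation points and sampling

Fifteen points: seven per eye on the equatorial (z = eye-centre) arc of
the exposed cap, ids 1–7 temporal→nasal on the right eye and 9–15
nasal→temporal on the left (both orderings are by descending x, the
shared profile axis), plus the nose-bridge point (id 8) on the anterior
midline at eye height. Zones per eye: the outermost two points are the
temporal zone, the 3rd and 4th from the nasal side the central zone, the
remaining three the nasal group. The nose point is reported but excluded
from eye-zone peak classification.

Three sampling rules depart from the naive "containing element" choice,
each forced by a convergence diagnostic:

- the arc is inset 30% from the exposure rim, because the rim is a
  singular conductor/insulator junction where the discrete field grows
  under refinement rather than converging;
- eye points sample the regular interior element found 2 mm inside the
  eye surface; the literal containing element of a surface point can be a
  boundary sliver whose field value scatters ~3× between seeds;
- the nose value is a volume-weighted average over the 12 nasal-bone
  elements beneath the surface point. Inside the quasi-insulating skin a
  single element's norm is noise (the sign of the same-vs-anti-phase
  comparison flips between neighbouring elements); the bone-region
  average is stable across seeds and resolutions.

No inter-point smoothing of any kind is applied to profiles.

Peak finding operates per eye along the nasal→temporal ordering: a point
is a local maximum if strictly greater than its neighbours (endpoints
qualify against their single neighbour); plateaus are reported once,
resolved toward the temporal end and flagged as ties.

## Solvers

The assembled P1 stiffness matrix is symmetric positive-semidefinite with
zero row sums (constant nullspace) before constraints. Dirichlet nodes
are eliminated by reduction. For conductivity contrast below 100 (the
homogeneous oracle geometries) the reduced system is solved by conjugate
gradients with Jacobi preconditioning to a relative residual of 1e−10
(note: SuperLU's incomplete-LU factors are nonsymmetric because of
pivoting and can stall CG, so they are not used). At the head model's
~10⁴ contrast with thin-shell elements CG stagnates, and the solver
switches to a sparse direct factorisation (residual ~1e−13). Both paths
sit far inside the 1e−8 residual contract, which is asserted after every
solve. A degenerate element or an unconverged solve raises with
diagnostics rather than returning silently.

## Oracles

`two_monopole_potential` implements V = (I/4πσ)(1/r₊ − 1/r₋).
`finite_difference_box_solver` is an independent 7-point
flux-conservative discretisation on a regular grid (edge conductances
from the cell conductivity; a layered slab reproduces the 1-D
series-conductance divider exactly) iterated to 1e−10.

The standard cross-validation uses a 320 mm homogeneous box (σ = 0.43)
with two 8 mm ball electrodes 60 mm apart and eight probes at grid nodes
≥30 mm from both electrode surfaces and ≥60 mm from every wall. The box
size is a deliberate numerical choice: the closed form assumes an
unbounded medium, and an image-charge estimate shows the insulating walls
of a 200 mm box would alone shift compliant-probe potentials by 9–15%,
swamping the 5% agreement band, while at 320 mm the wall contribution is
2.5–3.5%. Measured agreement at the default resolution: 3.5% vs the
closed form (tolerance 5%) and 0.7% FEM vs FD at matched node lattices
(tolerance 3%). Both tolerances are fixed in the oracle configuration and
reported alongside the measured errors; a verification failure blocks the
pipeline's study stages.

## Study stages and their problem sizes

All stages run on the default head (6 mm background/2.5 mm eye
refinement; ~25k nodes) and share one solver cache; the full set of 12
unique channels solves in ~1.5 minutes on one CPU, and each stage's
superposition and sampling is seconds. Stage outputs are CSV tables plus
a JSON summary that embeds the resolved configuration and the mesh
content hash.

- Step 1 (separation sweep): 15 placements × {same, anti} × {1, 2} mA.
  Establishes exact 2× linearity (the doubling is floating-point exact
  because scaling by 2 is exact in IEEE arithmetic), peak-location
  invariance under current, non-positive composed anti-phase differences
  (triangle inequality), and the anti-phase nose-point depression for all
  nine two-pair placements.
- Step 2 (intended regions): i–iv and I–III under both phases, peak-zone
  classification against each montage's intended zones, and an
  interference score (max off-target norm / min on-target peak norm).
- Mitigation: one-eye placements at same phase (cross-talk on the
  unstimulated eye compared against the single-pair cross-talk baseline,
  i.e. the largest off-eye/on-eye ratio among the one-direction
  placements — about 0.19 on this geometry), and the centre-boost
  condition (anti phase, centre channel 1.5 mA), which raises the
  central-zone peak by ~1.5× relative to the all-1 mA anti-phase run.

## What the synthetic model does and does not show

The generator emulates the layered conductivity structure, the
eye-exposure geometry and the electrode layout of a periocular
stimulation study, and it reproduces the study's structural findings:
linearity, phase-flip invariance, anti-phase cancellation along the face
midline, temporal-peak placement of the bilateral montage, one-eye
confinement and the centre-boost recovery. It does not reproduce
anatomical detail (orbit shape, eyelids, skull foramina, a protruding
nose), tissue anisotropy, or absolute field magnitudes comparable to an
MRI-derived head; profile values in V/m are reported without asserting
numeric agreement with any subject-specific model.

One semantic discrepancy is expected and reported rather than hidden: on
this geometry the centre-targeting placements (ii, iii, and hence the
central component of II/III) classify their eye-wise maximum at the arc
endpoints instead of the central zone. The carved exposure channel
isolates the cap centre — current enters the eye around the rim, so the
rim-adjacent points always dominate a single-channel profile. The
centre-boost comparison is unaffected (it compares the central zone with
itself across conditions). Zone-hit classifications are emitted
faithfully in the step-2 reports.

## Degenerate inputs and error behaviour

Geometry parameters are validated eagerly (non-increasing radii,
non-positive eye radius, overlapping or buried eyes). Meshes are
validated for positive volumes, label coverage, watertightness and patch
disjointness; validation is report-only, but the pipeline refuses to run
on a failing mesh. Electrode patches that select no surface, overlap, or
sit >30 mm from the surface raise montage errors; observation points
farther than two edge lengths from an admissible element raise sampling
errors. Configurations fail fast (unknown tissue overrides, unknown
families, unknown keys) before any solve.
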