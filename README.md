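# ocufield

Quasi-static finite-element modelling of the electric field that periocular
transcranial alternating-current stimulation (tACS) produces on the human
eyeball surface — the physical quantity that governs where phosphenes
(electrically evoked flashes of light) appear in the visual field.

Phosphene-based walking aids for blind users need to present flashes in at
least two directions at once, which requires driving two electrode pairs
simultaneously. Because the eyeball surface is small, the two channels
interfere: their fields superpose, and depending on the relative phase the
superposition amplifies or cancels. This package reproduces that
interference study end-to-end on a self-contained synthetic head model —
no external imaging data is needed.

## Model

At 10 Hz the quasi-static approximation applies, so each electrode pair is
a conduction problem: the potential satisfies

    ∇·(σ ∇φ) = 0   in Ω,     E = −∇φ,

with Dirichlet values on the electrode contact patches (±0.5 V) and
homogeneous Neumann conditions elsewhere. The domain Ω is a five-layer
concentric-sphere head (white matter, gray matter, CSF, bone, skin; outer
radii 74/78/80/82/85 mm; conductivities for 10 Hz from a standard tissue
table, e.g. CSF 2.0 S/m, bone 0.020 S/m, skin 2.0·10⁻⁴ S/m) with two
12 mm eyeball spheres (0.411 S/m) whose anterior caps are exposed through
carved channels, like the real eye opening. The mesh is a labeled
first-order (P1) tetrahedral discretisation built from a jittered lattice
plus interface-sphere sampling and a Delaunay tetrahedralisation; it is
byte-reproducible from its parameters and seed.

Each channel is solved once and rescaled so the delivered current —
computed from the variationally consistent nodal reactions, which makes
anode and cathode flux agree to machine precision — is exactly 1 mA
("unit solution"). A montage (set of channels with currents I_i in mA and
phases θ_i) then has the per-element field phasor

    A = Σ I_i cos(θ_i) E_i,   B = Σ I_i sin(θ_i) E_i,

and the reported scalar is the peak-over-cycle norm (largest singular
value of the [A B] pair), which for the surveyed phases {0°, 180°}
reduces to ‖Σ ±I_i E_i‖. Profiles are sampled at 15 eyeball-surface
observation points (7 per eye along the exposed equatorial arc, ordered
temporal→nasal on the right eye by descending x, plus one nose-bridge
point between the eyes).

The solver is cross-validated against two independent oracles on a
homogeneous box — the closed-form two-monopole potential
V = (I/4πσ)(1/r₊ − 1/r₋) and a 7-point finite-difference scheme — before
any study runs.

## Worked example

```python
from ocufield import (HeadGeometryParams, generate_layered_head,
                      default_conductivities, build_study_montages,
                      apply_phase_condition, ChannelSolver,
                      default_observation_points,
                      locate_observation_elements, sample_norm_profile)

mesh = generate_layered_head(HeadGeometryParams(seed=0))
solver = ChannelSolver(mesh, default_conductivities())
points = default_observation_points(mesh)
elements = locate_observation_elements(mesh, points)

pair = {m.id: m for m in build_study_montages("separation_sweep")}["electrode_7"]
for phase in ("same", "anti"):
    field = solver.combined_field(apply_phase_condition(pair, phase))
    prof = sample_norm_profile(field, points, elements)
    print(phase, f"nose point: {prof.value(8):.2f} V/m")
```

prints (default geometry, seed 0):

```
same nose point: 1.36 V/m
anti nose point: 1.03 V/m
```

Placement 7 drives the two nasal forehead electrodes against the cheeks;
in the same-phase condition both channels push current down the face
midline and their nose-bridge fields add, while in anti-phase the common
midline components cancel and the value drops by about a quarter — the
central depression that makes anti-phase stimulation the safer choice
when presenting two phosphenes at once. The same comparison holds for
all nine two-pair placements of the separation sweep.

The numbered drivers under `analysis/` run the full study and write their
tables to `results/`: `01_build_head_model.py` (mesh + validation),
`02_verify_oracles.py` (FEM/FD/closed-form cross-check),
`03_separation_sweep.py` (interference vs electrode separation),
`04_intended_regions.py` (two-direction presentation), `05_mitigation.py`
(one-eye and centre-boost conditions). A `ocufield` command-line interface
exposes the same stages (`ocufield mesh/solve/montages/evaluate/verify/run`).

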