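# Methods

`exogait` is a virtual gait laboratory for exoskeletal-assisted locomotion
(EAL): a human + exoskeleton multibody model, marker-based inverse
kinematics (IK), Newton–Euler inverse dynamics (ID), and the measurement
pipeline (ground reaction forces, EMG, gait events, ensemble statistics)
that a motion-capture study of a powered lower-limb exoskeleton requires.
This note documents the models, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Multibody models

**Human.** 24 rigid segments, 37 generalized coordinates: a six-DoF joint
(three translations, then three rotations) from the ground to the pelvis; a
spherical (ball) torso–pelvis joint (3); per leg a ball hip (3), a one-DoF
coupled knee, and revolute ankle, subtalar, and metatarsal joints (7 total);
per arm a ball shoulder (3), revolute elbow and forearm pronation, and a
two-DoF universal wrist (7 total). The patella is welded to the femur, and
left/right clavicles are welded to the torso (carrying the shoulder joints),
which brings the segment count to 24 without adding coordinates. The coupled
knee exposes one coordinate (flexion); an optional coupling table prescribes
tibia translation as a cubic spline of knee angle. The default table is
empty (a pure hinge): the cited generic models' spline values are not
public, and a hinge preserves the one-DoF contract. A nonzero table
propagates exactly through FK, the IK Jacobian, and the velocity/acceleration
recursions.

Ball joints are intrinsic flexion → adduction → internal-rotation sequences
with per-joint axis triples in the config; flexion and dorsiflexion are
positive internally (the reporting layer negates to print
extension/plantarflexion peaks as positive magnitudes). Units are SI
throughout (m, kg, s, rad); degrees appear only at I/O boundaries. Gravity
is 9.81 m/s² along −Z of the Z-up world frame (configurable).

Generic geometry — segment lengths, mass fractions, gyration radii, marker
offsets (a CGM-2.5-flavoured template of 54 markers) — is an editable,
clearly approximate config (`default_human_config`): these numbers stand in
for the anthropometric tables of published generic models and are not
measured data. Generic totals: 1.70 m, 75.16 kg.

**Exoskeleton.** 7 segments, 4 coordinates: a pelvic band (root), pin hips
and knees, and foot plates welded to the shanks. Segment masses are a
placeholder distribution summing to a configurable device mass (default
23.0 kg); real device inertial parameters are proprietary and must be
supplied for quantitative work. A custom 20-marker template tracks the
device.

**Coupling and lumping.** The device is anchored to the pelvis through a
six-DoF pelvic-band joint (37 + 4 + 6 = 47 coordinates); a `locked` option
welds the anchor (41). For ID the exoskeleton is folded into the human
segments: mapped pairs combine mass (sum), COM (mass-weighted mean), and
inertia (parallel-axis transfer of both tensors to the combined COM,
expressed in the human segment frame at the coupled neutral pose). The
lumped model keeps the human topology, so net joint moments are reported at
the human coordinates; the separated-chain solution with explicit
interaction forces is out of scope, and unmeasured externals (crutches)
land in the six base residuals, which are reported, never distributed.

**Scaling.** Per-segment length factors from subject segment lengths (or
the height ratio as fallback) scale COM offsets, joint frames, and marker
positions; masses are rescaled to the subject total preserving generic
fractions; inertia scales by (mass ratio)·(length ratio)². The default
subject is 1.76 m, 89.4 kg.

## Kinematics

Every joint compiles to a chain of primitive transforms (fixed, revolute,
prismatic, spline-coupled translation). FK composes these and records each
coordinate's world axis and anchor point, giving geometric Jacobians
(revolute column `u × (p − o)`, prismatic column `u`, plus the spline
derivative for the coupled knee) with no numerical differentiation.

IK minimises the weighted squared distance between model and observed
markers per frame by damped Gauss–Newton: solve
`(JᵀWJ + λI) Δq = JᵀW r`, accept only non-increasing objectives, λ ×10 on
rejection and ×0.3 on acceptance; converged when the step ∞-norm < 1e-8 or
the objective change < 1e-12, max 100 iterations. Frames warm-start from
the previous solution; the first frame from the neutral pose plus a Kabsch
fit of the pelvis markers for the base pose. Occluded markers are dropped
from that frame's objective (no gap-filling); a coordinate with no visible
marker anywhere in its subtree is flagged unobservable and held at the warm
start; a frame with fewer residuals than free coordinates is flagged
under-determined. Marker weights default to 1 and human and exoskeleton
markers are solved jointly in one objective.

Differentiation: optional zero-phase low-pass on the coordinates (default
6 Hz, 4th order — the cutoff is a documented choice; the processing chain
this emulates does not state one) followed by central differences
(one-sided at the ends). Human-vs-robot angle comparison removes a constant
offset taken as the trial-mean difference (the offset convention is
otherwise unspecified; a static-pose offset is the alternative) and reports
mean ± SD absolute difference; IK-vs-encoder comparison linearly resamples
the encoder stream onto the IK clock and reports offset-removed RMS.

## Dynamics

ID evaluates, per frame, the Newton–Euler balance of every body mapped
through the Jacobians:

    τ = Σᵢ [ Jvᵢᵀ mᵢ(a_cᵢ − g) + Jwᵢᵀ (Iᵢαᵢ + ωᵢ×Iᵢωᵢ) ]
        − Σ_ext [ J_pᵀ F + Jwᵀ M_free ]

with body ω, α, and COM accelerations propagated exactly along the
primitive chains — algebraically the recursive Newton–Euler solution for a
tree. External loads are a force at the COP plus a free moment. The six
base-coordinate entries are residuals, reported separately;
`check_residuals` verifies the translational residuals equal
`m_total(a_com − g) − ΣF_ext` frame by frame. Moments normalise to subject
mass (unassisted) or subject + device mass (assisted); forces to the
corresponding weight.

The forward-dynamics oracle assembles the mass matrix from the same
Jacobians (`M = Σ JvᵀmJv + JwᵀI Jw`), the bias vector from one
zero-acceleration ID pass, and integrates `M q̈ = τ − bias` with DOP853 at
rtol 1e-10 / atol 1e-12. It exists to verify ID by round trip on small
chains (≤ ~10 DoF) and is not meant for the full model.

## Signal processing

GRF: 4th-order Butterworth low-pass at 15 Hz on the force components of the
2000 Hz plate streams, optional resampling to the 100 Hz marker clock.
EMG, in exactly this order: subtract the resting mean (quiet standing) →
30 Hz 4th-order high-pass (assumed Butterworth; the stated design gives
only order and cutoff) → full-wave rectification → 6 Hz 4th-order
Butterworth low-pass (the linear envelope) → divide by the muscle's MVC,
the envelope peak over its five isometric maximum-contraction trials. All
offline filters are zero-phase (forward–backward) by default, which squares
the magnitude response — the −3 dB point of the design becomes −6 dB; a
flag selects single causal passes, and "4th order" always means the design
order per pass.

## Events and statistics

Foot strike / toe-off are upward / downward 20 N crossings of each foot's
filtered vertical GRF with a 50 ms debounce (both thresholds configurable;
standard laboratory practice). Stance splits into braking and propulsion at
the last posterior→anterior zero crossing of the AP shear — an operational
choice, since braking/propulsion boundaries are conventionally described
but rarely defined. Powered sit-to-stand and stand-to-sit segment into
positioning / ~3 s hold / rise-or-descend phases, preferring the device's
motor-activation timestamp and falling back to torso-pitch plateau
detection (0.5° settling band). Curves are time-normalised to a 101-point
0–100 % grid; ensembles are pointwise mean ± sample SD (n−1) over trials;
peak summaries are the mean ± SD of per-trial extrema, never the extremum
of the mean curve.

## Synthetic fixtures

The generator emulates a two-condition walking study: assisted (0.47 m/s,
2.0 s cycles, peak knee flexion exactly 50.1°, hips biased into flexion
with peak extension 3.1°, small 6.9° ankle excursion, exoskeleton hip/knee
pins driven to the human angles, a small six-DoF anchor wobble, encoder
streams with a constant 12° frame offset and 1° noise) and unassisted
(1.11 m/s, 1.1 s cycles, peak knee flexion 68.6°, peak hip extension 27.2°,
15° ankle excursion, arm swing). Waveforms are truncated cosine series with
analytic first and second derivatives; left/right run half a cycle apart;
stance occupies 60 % of the cycle with a raised-cosine double-support blend
of 10 %. Markers are FK positions plus i.i.d. 5 mm Gaussian noise and 2 %
random occlusions; EMG is band-limited noise (50–450 Hz) amplitude-modulated
by phase-locked bursts over a 0.02 resting offset, with plantarflexor and
tibialis bursts attenuated in the assisted condition; MVC trials carry a
known maximum above the gait-trial activation.

Ground loads are constructed, not simulated: the whole-body Newton–Euler
resultant wrench demanded by the commanded accelerations is split between
the feet by the stance-weight blend (equal split for standing), applied at
a COP under each foot with a free moment closing the balance. ID on these
loads therefore returns base residuals at machine precision, which is the
acceptance surface for the dynamics chain.

What the fixtures are not: physiologically shaped gait curves, realistic
EMG spectra, foot–ground contact, crutch loads, soft-tissue artifact, or
model-geometry error. Passing tests establish that each algorithm recovers
known ground truth under the stated noise, not that the defaults reproduce
any particular subject's data — headline values from single-subject studies
(e.g. 1.3 cm marker RMS, 0.10 vs 0.64 N·m/kg knee moments) depend on
unshared raw captures and appear here only as commanded defaults and
qualitative patterns.

## Verification conditions and problem sizes

Chosen once as the package's study conditions:

- IK recovery: 6 trials per condition, 2 gait cycles each at 100 Hz
  (400/220 frames), 5 mm noise. Joint-angle RMSE is evaluated on the
  6 Hz-filtered IK trajectory — the form in which joint kinematics are
  consumed and reported everywhere in the pipeline — for the angles the
  study design reports (hip/knee/ankle flexion–extension, both legs).
  Raw per-frame IK noise on a 5 mm cloud is ~1.2–1.6° for hip and ankle.
- ID↔FD round trip: 20 random 3–5-DoF chains with 0.6–0.9 m links, driven
  by small (0.05–0.2 N·m) torques at 0.3–1.0 Hz about the hanging
  equilibrium, so all chain modes stay below ~2.5 Hz and a 100 Hz /
  6 Hz-filtered differentiation can represent the motion (large-amplitude
  swinging puts real signal above the 6 Hz band, where no 100 Hz scheme
  recovers torques to 2 %). Trials are 3 s; the torque comparison uses the
  0.5–2.5 s interior, excluding the zero-phase filter's edge transients.
- The load-zeroing residual identity ("remove the GRFs and the vertical
  residual shifts by exactly one model weight") is exact only for static
  poses and is verified on the standing fixture.

## Known limitations

- No muscle paths or muscle-force computation; net moments only.
- No contact model; generated COPs sit under the foot by construction.
- Euler-sequence ball joints can gimbal-lock at ±90° of the middle
  rotation; gait-range motions stay far from it.
- The coarse first-frame pose fit assumes the base joint's rotation axes
  are the principal triad (true for the shipped configs); exotic base
  parameterisations fall back to a neutral-orientation start.
- Encoder streams and maneuver phase detection are exercised on walking
  and ramp fixtures; no full sit-to-stand trial generator is included.
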