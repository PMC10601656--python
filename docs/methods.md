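# Methods

## Plant: planar skeletal dynamics

The walker is a 7-segment sagittal-plane chain (HAT = head–arms–trunk–pelvis,
thigh/shank/foot per side) with 9 generalized coordinates: a planar floating
base (pelvis x, y, pitch) plus hip, knee and ankle flexion–extension per leg.
The base parameterization is a modeling choice: the 6 internal joints are the
physiological DOF, and the 3 base coordinates make up the remainder of the
9-DOF state.  Sign conventions are hip flexion, knee flexion and ankle
dorsiflexion positive, pelvis pitch positive = anterior tilt.

Equations of motion `M(q) q̈ = Q(q, q̇)` are assembled from per-segment
center-of-mass Jacobians (equivalent to a composite-rigid-body / Lagrangian
derivation; the test suite verifies the assembly against a nested
finite-difference evaluation of the Lagrangian, and against closed-form
ballistic and energy-conservation limits).  Defaults describe a ≈ 1.80 m /
75 kg adult with the HAT carrying ≈ 53% of body mass; all segment parameters
are plain config values and can be overridden per run.

Foot–ground contact uses two contact points per foot (heel, toe) with a
Hunt–Crossley normal force `k δ^1.5 (1 + c δ̇)` clamped at zero
(k = 8·10⁴ N/m^1.5, c = 1 s/m) and Coulomb friction regularized by
`−μ N tanh(v/v_s)` (μ = 0.9, v_s = 0.05 m/s).  Joint limits
(hip −30°…120°, knee 0°…120° with a hyperextension stop at 0°, ankle
−60°…40°) are enforced by penalty torques (300 N·m/rad, 3 N·m·s/rad) active
only outside the range.

Integration is fixed-step semi-implicit Euler at h = 1 ms, 10 substeps per
0.01 s control interval.  One numerical subtlety matters: the regularized
friction near zero slip velocity acts as a viscous damper whose coefficient
(μN/v_s, several kN·s/m in stance) exceeds the explicit stability limit at
h = 1 ms.  The contact law's force–velocity Jacobian (negative semidefinite
by construction) is therefore treated linearly implicitly — the velocity
update solves `(M − hD) Δq̇ = h·Q` — which is unconditionally stable for the
dissipative terms, leaves the continuous dynamics unchanged, and keeps the
integrator deterministic.  A `locked_dofs` option freezes base coordinates
for suspended-pendulum conservation tests.  Divergence (non-finite state)
raises an error carrying the simulation time.

## Muscles

18 Hill-type MTUs with rigid tendons: fiber length = MTU length − tendon
slack length, and the fiber sees the full MTU velocity.  Curves: active
force–length Gaussian `exp(−((l̃−1)/0.45)²)`; force–velocity with a Hill
hyperbola on the shortening side (zero at ṽ = −1, curvature 0.25) and a
saturating lengthening branch with plateau 1.5; passive exponential engaging
beyond optimal length, reaching 1 at 60% stretch.  Pennation is neglected
(2D model, rigid tendon; a second-order effect).  Activation dynamics are
first-order with τ_act = 10 ms and τ_deact = 40 ms (conventional values),
integrated exactly within each step.  Maximum shortening velocity is 10
optimal lengths/s for all muscles.

MTU lengths are affine in the joint angles with constant signed moment arms
(`l_MT = l_ref − Σ r_j Δq_j`; e.g. SOL ankle −0.05 m, TA ankle +0.04 m,
VAS knee −0.045 m, HAM hip −0.06 / knee +0.03 m, GAS knee +0.02 /
ankle −0.05 m), the same arms mapping forces to torques by virtual work —
so a muscle's length and torque conventions can never disagree.  ILPSO and
GMAX are uniarticular hip muscles; HAM, RF and GAS are biarticular.
Reference MTU lengths are normalized so the upright standing posture puts
every fiber at l̃ = 1 (the normalization utility accepts other targets and
the suite checks l̃ ∈ [0.7, 1.1] at standing).  The shipped strength table
makes SOL the strongest plantarflexor (4000 N vs GAS 1500 N), which is what
gives the weakness protocol its asymmetric compensation behavior.

## Reflex controller (37 parameters)

The policy is deterministic and bilaterally shared; per leg the laws are
gated by a stance/swing flag derived from the vertical GRF (20 N threshold).
Muscle force and length readouts carry a uniform one-control-step (10 ms)
delay, standing in for spinal transport latency.  Stance: positive force
feedback on SOL, GAS, VAS, HAM, GMAX; VAS inhibition near knee
overextension and knee-extension-velocity damping; TA stretch reflex with
reciprocal inhibition from SOL force; a trunk PD signal
`kp(θ − θ_tgt) + kd·θ̇` scaled by leg load share and routed to HAM/GMAX
(forward lean) or ILPSO (backward lean); a constant push-off boost on the
trailing leg's SOL/GAS/ILPSO during double support.  Swing: ILPSO length
feedback, HAM force feedback, BFSH extension-velocity damping, and PD
drives toward knee/ankle target angles through the VAS/BFSH and TA/SOL
antagonist pairs.  Co-stimulation baselines (one per muscle group) apply in
all phases.  Outputs are clamped to [0.01, 1]; the floor is a small tonic
drive that keeps muscles numerically alive.

The canonical 37-slot layout is fixed in `controller.PARAM_NAMES` and
round-trips through `pack_params`/`unpack_params`.  The trailing leg during
double support is identified by the smaller load share.

## MDP and reward

Control runs at Δt = 10 ms.  Episodes start from a 12-parameter initial
state (forward/rightward speed, pelvis height, trunk lean, and bilateral
hip/knee/ankle angles; the rightward speed and hip ab/adduction slots are
planar no-ops kept for interface compatibility).  Activations initialize at
the controller's co-stimulation baselines.  Termination: horizon reached or
pelvis below 0.6 m; an initial pelvis height at or below 0.6 m is rejected
outright.

Reward: survival (Δt per executed step) plus, per completed footstep,
`w_steps·Σdt − w_vel·|Σ(v_pel − v_tgt)dt| − w_pel·Σθ²dt − w_mul·ΣΣe²dt`
with weights (10, 60, 20, 1).  Two deliberate readings of ambiguous pieces:
the velocity cost penalizes the *signed integrated* deviation (distance
shortfall), not the per-step absolute deviation — the per-step variant is
exposed as the `j_vel_per_step` switch on `RewardWeights`; and the survival
term is unweighted.
When no target speed is set (self-selected protocol) the velocity cost is
omitted entirely.  A footstep is the interval between initial contacts
(vertical GRF rising through 20 N after ≥ 50 ms unloaded — the debounce
suppresses contact chatter) of alternating feet; the trailing partial
footstep earns nothing.  Accounting is exact: total = R_alive + Σ footstep
rewards to machine precision, checked on every trace.

## Optimization

CMA-ES in its standard (μ/μ_w, λ) form — log-decreasing positive recombination
weights, cumulative step-size adaptation, rank-1 + rank-μ covariance update —
implemented in `optimize.CMAES` and validated by known-optimum recovery,
monotone best-ever bookkeeping and seeded determinism.  The 49 search
dimensions (37 controller + 12 initial state) live in a normalized [0,1]
box mapped affinely to physical bounds (gains [0,3], length offsets
[0.5,1.5] l_opt, baselines [0,0.3], target angles within joint limits,
initial speeds [0.5,2.0] m/s, pelvis height [0.85,1.05] m); out-of-box
samples are repaired by clipping.  σ₀ = 0.25 cold, 0.05 warm-started.
Candidate evaluation is deterministic given the vector, so the optional
process-parallel evaluation (order-preserving map) cannot change results —
the suite asserts bit-identical runs at 1 and 8 workers.  A diverging
simulation scores −10⁶, strictly worse than any legitimate episode, and the
search continues.  The full-scale budget is population 16 × 1000
generations per protocol, run single-process; a multi-restart option
(independent seeded searches, best-of) stands in for cloud-parallel
multi-start schemes without sacrificing determinism.

## Protocols and analysis

Self-selected speed: velocity cost removed, 20 s horizon, settled speed
measured over the final half of the best episode (excludes the startup
transient; the averaging window is a documented choice).  Speed sweep:
anchor 1.45 m/s solved cold, neighbors warm-started outward over
{1.10, 1.27, 1.45, 1.62, 1.80} m/s; 1.62 is the symmetric interpolant
completing the five-speed range.
Weakness: SOL or GAS MIF × 0.8 or 0.6 bilaterally (exactly one muscle per
run, verified by config diff), warm-started from the 1.45 m/s solution,
never cold.

Gait cycles are bounded by successive ipsilateral initial contacts using
the same 20 N / 50 ms rule (GRF is exact in simulation, so kinematic event
heuristics are unnecessary); the first cycle (startup) and trailing partial
are discarded.  Kinematics are resampled by linear interpolation onto the
conventional 101-point 0–100% grid; the vertical GRF is normalized to the
stance phase and reported in body-weight units by default.  Ensembles use
the pointwise mean and sample SD (ddof = 1).  Toe-off is the last unloading
within a cycle not followed by reloading.  Pearson's R compares ensemble
means with user-supplied reference curves; zero-variance inputs raise
rather than returning 0.

## Synthetic traces

`fixtures.make_trace` builds episodes with alternating square-wave GRFs,
constant (or sinusoidal-tilt) pelvis profiles and constant excitations, with
initial-contact indices, footstep partitions, toe-off fractions and reward
components all known in closed form.  These traces exercise the reward and
analysis bookkeeping in isolation from the physics; they are deliberately
*not* dynamically consistent, so passing them says nothing about simulation
realism — that burden falls on the physics property tests (energy
conservation, force balance, Lagrangian cross-check) and, at full scale, on
the protocols themselves.

## Problem sizes and limitations

The test suite and the acceptance script run the training loop at a reduced
scale chosen as the smallest budget at which a learning signal is reliably
measurable: population 8, 30 generations, 4 s horizon, target 1.3 m/s
(240 episodes).  At this scale the optimizer demonstrably improves reward
and survival; producing steady 1.45 m/s walking with human-like kinematics
requires the full budget (population 16, 1000 generations, hours per
protocol), reachable through the CLI's `--full` flag.

Known limitations: strictly planar (no frontal/transverse DOF, no arms);
constant moment arms (no posture-dependent geometry); rigid tendons; no
metabolic cost; contact response is a generic compliant model, not a match
for any specific engine; ankle kinematics in this model family are known to
reproduce less faithfully than hip/knee.
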