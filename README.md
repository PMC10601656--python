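# neurogait

Predictive simulation of planar human walking with a reflex-controlled
musculoskeletal model, for biomechanists and motor-control researchers who
want gait to *emerge* from physics, muscle properties and simple spinal
feedback laws — with no motion-capture reference data anywhere in the loop.

## What it simulates

The plant is a sagittal-plane biped: a lumped head–arms–trunk–pelvis (HAT)
segment plus thigh, shank and foot per leg — 7 segments, 9 degrees of
freedom (planar floating base `x, y, θ` and hip/knee/ankle
flexion–extension per side), with compliant Hunt–Crossley foot–ground
contact.  It is actuated by 18 Hill-type muscle–tendon units (ILPSO, GMAX,
HAM, RF, VAS, BFSH, GAS, SOL, TA per leg) with rigid tendons:

```
F = F_max · ( a · f_L(l̃) · f_V(ṽ) + f_PE(l̃) ),    τ_j = Σ_k r_kj F_k
```

where `a` follows first-order activation dynamics with separate rise/decay
time constants, and constant signed moment arms `r` map joint angles to MTU
lengths and muscle forces to joint torques.

The policy is a deterministic, phase-dependent reflex controller with
exactly **37 bilaterally shared parameters**: stance force feedback on the
anti-gravity muscles, a TA stretch reflex with reciprocal inhibition, a
trunk-balance PD distributed by leg load, swing leg length feedback and
antagonist PD drives toward knee/ankle swing targets, co-stimulation
baselines, and a double-support push-off boost.

Training solves the Markov decision process with CMA-ES over 49 parameters
(37 controller + 12 initial-state) against the reward

```
r = R_alive + Σ_steps ( w_steps·r_steps − w_vel·J_vel − w_pel·J_pel − w_mul·J_mul ),
    (w_steps, w_vel, w_pel, w_mul) = (10, 60, 20, 1)
```

accrued per footstep (interval between initial contacts of alternating
feet): step duration reward, distance-tracking deviation `|Σ(v_pel −
v_tgt)Δt|`, squared pelvis tilt, and squared muscle excitations.  Episodes
run at Δt = 0.01 s and terminate when the pelvis drops below 0.6 m.

Three evaluation protocols are built in: self-selected speed (velocity cost
removed, 20 s horizon), a five-speed sweep (1.10–1.80 m/s, anchored at
1.45 m/s with neighbor warm-start seeding) and plantarflexor weakness
(SOL or GAS maximum isometric force at 80%/60%, re-optimized from the
normal-strength solution).  Analysis utilities segment gait cycles from the
GRF, normalize kinematics to the 101-point % gait-cycle grid, compute
toe-off timing, stance-phase GRF and ensemble mean ± SD, and correlate
against user-supplied reference curves (Pearson R).

## Worked example

A desk-scale training run (population 8, 30 generations, 4 s horizon,
target 1.3 m/s — the full-scale budget is population 16 × 1000
generations behind `--full`):

```bash
neurogait train --target-speed 1.3 --seed 1 --out runs/demo
```

which logs, generation by generation:

```
INFO gen    0  best 4.000  mean 1.664  best-ever 4.000  sigma 0.238
INFO gen    1  best 4.000  mean 1.487  best-ever 4.000  sigma 0.229
...
INFO gen   29  best 4.299  mean 3.734  best-ever 4.763  sigma 0.118
WARNING best solution is not a stable gait (0 cycles, fell=False)
INFO results written to runs/demo
```

`best-ever 4.763` is the episode reward of the best candidate: it survived
the full 4 s horizon (R_alive = 4.0) and completed a footstep whose reward
exceeded its costs — at this budget the optimizer has learned to stay
upright and begin stepping, not yet to walk steadily (hence the honest
warning that no full gait cycles exist to analyze).  `runs/demo/`
contains `manifest.json` (config hash + seed, sufficient to reproduce the
run), `params.json` (named + flat 37-vector), `optimization.json` (reward
history) and `trace.csv` / `trace_meta.json` (the best episode).  A walking
trace can then be analyzed with

```bash
neurogait analyze --trace runs/demo/trace.csv --out runs/demo/analysis
```

which writes 101-point ensemble curves (`cycles.csv`) and scalars
(`summary.json`: cycle count, mean toe-off %, mean speed, and R values when
`--reference your_curves.csv` is supplied).

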