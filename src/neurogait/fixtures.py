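"""Synthetic episode traces with analytically known ground truth.

These traces deliberately bypass the physics: alternating square-wave GRFs,
prescribed pelvis speed/tilt and constant excitations exercise the footstep,
reward and gait-analysis bookkeeping in isolation, with footstep boundaries,
toe-off fractions and reward components known in closed form.  They are not
dynamically consistent motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import DT, EpisodeTrace, FootstepRecord
from .skeleton import NQ


@dataclass(frozen=True)
class SyntheticTraceSpec:
    duration: float = 12.0        # s
    step_period: float = 1.1      # s, one gait cycle (per-foot period)
    duty_cycle: float = 0.6       # stance fraction of the cycle
    pelvis_speed: float = 1.3     # m/s, constant
    pelvis_tilt: float = 0.05     # rad, constant (or amplitude, see tilt_freq)
    tilt_freq: float | None = None  # Hz; sinusoidal tilt when set
    excitation_level: float = 0.2   # constant for all 18 muscles
    grf_level: float = 750.0      # N while loaded
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must be in (0, 1)")
        if self.duration < 2 * self.step_period:
            raise ValueError("duration must cover at least 2 step periods")


@dataclass
class SyntheticGroundTruth:
    """Closed-form labels for the generated trace."""

    contact_steps_R: list[int]
    contact_steps_L: list[int]
    footsteps: list[tuple[int, int, str]]   # (start, end, leading_foot)
    toe_off_pct: float
    n_cycles_R_after_discard: int
    r_alive: float
    footstep_components: dict = field(default_factory=dict)


def _square_wave(t: np.ndarray, period: float, duty: float,
                 offset: float, level: float) -> np.ndarray:
    phase = np.mod(t - offset + 1e-9, period)  # epsilon keeps grid-aligned edges exact
    return np.where(phase < duty * period, level, 0.0)


def make_trace(spec: SyntheticTraceSpec, dt: float = DT,
               v_tgt: float | None = None
               ) -> tuple[EpisodeTrace, SyntheticGroundTruth]:
    """Build a synthetic trace and its analytic labels.

    The right foot first loads after one unloaded interval,
    at t = (1 - duty) * period, the left half a period later, so every
    initial contact (including the first) is a detectable rising crossing.
    """
    P, duty = spec.step_period, spec.duty_cycle
    n = int(round(spec.duration / dt))
    t = np.arange(n) * dt

    off_R = (1.0 - duty) * P
    off_L = off_R + P / 2.0
    grf = np.zeros((n, 4))
    grf[:, 0] = _square_wave(t, P, duty, off_R, spec.grf_level)
    grf[:, 2] = _square_wave(t, P, duty, off_L, spec.grf_level)

    q = np.zeros((n, NQ))
    qdot = np.zeros((n, NQ))
    q[:, 0] = spec.pelvis_speed * t
    q[:, 1] = 0.92
    if spec.tilt_freq:
        q[:, 2] = spec.pelvis_tilt * np.sin(2 * np.pi * spec.tilt_freq * t)
    else:
        q[:, 2] = spec.pelvis_tilt
    qdot[:, 0] = spec.pelvis_speed

    exc = np.full((n, 18), spec.excitation_level)

    # analytic initial contacts: first sample index at/after each offset + k*P
    def contacts(offset):
        out = []
        k = 0
        while True:
            tc = offset + k * P
            idx = int(np.ceil(tc / dt - 1e-9))
            if idx >= n:
                break
            out.append(idx)
            k += 1
        return out

    c_R, c_L = contacts(off_R), contacts(off_L)
    events = sorted([(i, "R") for i in c_R] + [(i, "L") for i in c_L])
    footsteps = []
    start, leading = None, None
    for i, side in events:
        if start is None:
            start, leading = i, side
        elif side != leading:
            footsteps.append((start, i, side))
            start, leading = i, side

    trace = EpisodeTrace(time=t + dt, q=q, qdot=qdot, excitations=exc,
                         activations=exc.copy(), grf=grf)
    for s, e, side in footsteps:
        trace.footsteps.append(FootstepRecord(
            s, e, (e - s) * dt, side, qdot[s:e, 0], q[s:e, 2], exc[s:e]))

    # per-footstep reward components for the constant-profile case
    comps = {}
    if spec.tilt_freq is None:
        m = footsteps[0][1] - footsteps[0][0] if footsteps else 0
        comps = {
            "r_steps": m * dt,
            "J_vel": (abs(m * (spec.pelvis_speed - v_tgt) * dt)
                      if v_tgt is not None else 0.0),
            "J_pel": m * spec.pelvis_tilt ** 2 * dt,
            "J_mul": m * 18 * spec.excitation_level ** 2 * dt,
        }

    gt = SyntheticGroundTruth(
        contact_steps_R=c_R,
        contact_steps_L=c_L,
        footsteps=footsteps,
        toe_off_pct=100.0 * duty,
        n_cycles_R_after_discard=max(0, len(c_R) - 2),
        r_alive=n * dt,
        footstep_components=comps,
    )
    return trace, gt


def handbook_footstep(n_steps: int = 50, v_pel: float = 1.2,
                      theta_pel: float = 0.1,
                      excitation: float = 0.2) -> FootstepRecord:
    """The hand-computable footstep: 50 steps of 0.01 s at v = 1.2 m/s,
    tilt 0.1 rad, all 18 excitations 0.2.  Against v_tgt = 1.45 and the
    default weights its components are r_steps = 0.5, J_vel = 0.125,
    J_pel = 0.005, J_mul = 0.36 and the weighted reward is -2.96."""
    return FootstepRecord(
        0, n_steps, n_steps * DT, "R",
        np.full(n_steps, v_pel), np.full(n_steps, theta_pel),
        np.full((n_steps, 18), excitation))
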