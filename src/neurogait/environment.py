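"""MDP wrapper: episode lifecycle, footstep bookkeeping and reward.

The control loop runs at dt = 0.01 s.  Each control step advances the muscle
activation dynamics once and the mechanical state through 10 integrator
substeps.  An episode ends when the horizon is reached or the pelvis falls
below 0.6 m.

The reward is survival plus footstep terms,

    r = R_alive + R_steps
      = sum_i r_alive + sum_steps (w_steps*r_steps - w_vel*J_vel
                                   - w_pel*J_pel - w_mul*J_mul)

where r_alive = dt per executed step and, within one footstep of t_step
control steps,

    r_steps = sum dt                      (step duration)
    J_vel   = | sum (v_pel - v_tgt) dt |  (distance-tracking deviation)
    J_pel   = sum theta_pel^2 dt          (pelvis-tilt cost)
    J_mul   = sum sum_k e_k^2 dt          (muscle-effort cost)

A footstep is the interval between successive initial contacts of
alternating feet (vertical GRF rising through 20 N after at least 50 ms
unloaded).  The trailing partial footstep of an episode earns no reward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import controller as ctl
from .muscle import MuscleSet, activation_step
from .skeleton import NQ, Q_LABELS, SkeletonModel, SystemState

DT = 0.01          # s, control interval
N_SUBSTEPS = 10    # mechanical substeps per control step (h = 1 ms)
FALL_HEIGHT = 0.6  # m, pelvis height terminating the episode
DEBOUNCE = 0.05    # s, minimum unloaded time before a new initial contact

INIT_STATE_NAMES = (
    "forward_speed", "rightward_speed", "pelvis_height", "trunk_lean",
    "hip_abduction_R", "hip_abduction_L", "hip_flexion_R", "hip_flexion_L",
    "knee_flexion_R", "knee_flexion_L", "ankle_R", "ankle_L",
)
N_INIT = 12


@dataclass(frozen=True)
class RewardWeights:
    w_steps: float = 10.0
    w_vel: float = 60.0
    w_pel: float = 20.0
    w_mul: float = 1.0
    #: velocity-cost form: the default penalizes the signed integrated
    #: deviation |sum (v - v_tgt) dt| (a distance shortfall); the per-step
    #: variant sum |v - v_tgt| dt is exposed as a config switch
    j_vel_per_step: bool = False

    def __post_init__(self):
        if min(self.w_steps, self.w_vel, self.w_pel, self.w_mul) < 0:
            raise ValueError("reward weights must be non-negative")


@dataclass(frozen=True)
class InitialStateParams:
    """The 12 optimized initial-state scalars.  ``rightward_speed`` and the
    hip ab/adduction angles are carried for interface compatibility but have
    no effect on the planar model (documented no-ops)."""

    forward_speed: float = 1.3       # m/s
    rightward_speed: float = 0.0     # m/s (planar no-op)
    pelvis_height: float = 0.92      # m
    trunk_lean: float = 0.05         # rad, anterior-positive
    hip_abduction_R: float = 0.0     # rad (planar no-op)
    hip_abduction_L: float = 0.0     # rad (planar no-op)
    hip_flexion_R: float = 0.2       # rad
    hip_flexion_L: float = -0.1      # rad
    knee_flexion_R: float = 0.1      # rad
    knee_flexion_L: float = 0.05     # rad
    ankle_R: float = 0.0             # rad
    ankle_L: float = 0.0             # rad

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in INIT_STATE_NAMES])

    @classmethod
    def from_array(cls, v: np.ndarray) -> "InitialStateParams":
        v = np.asarray(v, dtype=float).ravel()
        if v.shape != (N_INIT,):
            raise ValueError(f"initial-state vector must have length {N_INIT}")
        return cls(**dict(zip(INIT_STATE_NAMES, v)))


@dataclass
class FootstepRecord:
    start_step: int
    end_step: int               # exclusive
    duration: float             # s
    leading_foot: str           # side that struck at the *end* of the step
    v_pel: np.ndarray           # per-step horizontal pelvis velocity
    theta_pel: np.ndarray       # per-step pelvis tilt
    excitations: np.ndarray     # per-step (n, 18)


@dataclass
class EpisodeTrace:
    time: np.ndarray
    q: np.ndarray               # (n, 9)
    qdot: np.ndarray            # (n, 9)
    excitations: np.ndarray     # (n, 18)
    activations: np.ndarray     # (n, 18)
    grf: np.ndarray             # (n, 4): R_vert, R_horiz, L_vert, L_horiz
    footsteps: list[FootstepRecord] = field(default_factory=list)
    terminated_early: bool = False
    total_reward: float = 0.0
    reward_components: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.time)

    @property
    def v_pel(self) -> np.ndarray:
        return self.qdot[:, 0]

    @property
    def theta_pel(self) -> np.ndarray:
        return self.q[:, 2]


# ---------------------------------------------------------------------------
# footstep detection
# ---------------------------------------------------------------------------

def initial_contacts(grf_vertical: np.ndarray, dt: float = DT,
                     threshold: float = ctl.CONTACT_THRESHOLD,
                     debounce: float = DEBOUNCE) -> list[int]:
    """Indices where a foot's vertical GRF rises through the contact
    threshold after being unloaded for at least the debounce time."""
    g = np.asarray(grf_vertical, dtype=float)
    events = []
    loaded = g[0] > threshold
    unloaded_time = np.inf if not loaded else 0.0
    for i in range(1, len(g)):
        if g[i] > threshold:
            if not loaded and unloaded_time >= debounce - 1e-12:
                events.append(i)
            loaded = True
            unloaded_time = 0.0
        else:
            if loaded:
                unloaded_time = dt
            else:
                unloaded_time += dt
            loaded = False
    return events


def detect_footsteps(grf_R: np.ndarray, grf_L: np.ndarray,
                     dt: float = DT) -> list[tuple[int, int, str]]:
    """Partition the stepping period into footsteps.

    Returns (start, end, leading_foot) index triples; a footstep completes at
    each initial contact of the foot opposite the previous leading foot.  The
    trailing partial footstep is discarded.
    """
    events = sorted(
        [(i, "R") for i in initial_contacts(grf_R, dt)]
        + [(i, "L") for i in initial_contacts(grf_L, dt)])
    steps = []
    start = None
    leading = None
    for i, side in events:
        if start is None:
            start, leading = i, side
        elif side != leading:
            steps.append((start, i, side))
            start, leading = i, side
    return steps


class _FootstepMachine:
    """Online version of :func:`detect_footsteps` for the control loop."""

    def __init__(self, dt: float = DT,
                 threshold: float = ctl.CONTACT_THRESHOLD,
                 debounce: float = DEBOUNCE):
        self.dt = dt
        self.threshold = threshold
        self.debounce = debounce
        self._loaded = [None, None]      # None until the first sample
        self._unloaded_time = [np.inf, np.inf]
        self.window_start: int | None = None
        self.leading: str | None = None

    def update(self, step_index: int, grf_R: float, grf_L: float):
        """Feed one control-step GRF sample; returns a completed (start, end,
        leading_foot) triple or None."""
        completed = None
        for leg, (g, side) in enumerate(((grf_R, "R"), (grf_L, "L"))):
            is_loaded = g > self.threshold
            prev = self._loaded[leg]
            if prev is None:  # first sample defines the baseline, no event
                self._loaded[leg] = is_loaded
                self._unloaded_time[leg] = 0.0 if is_loaded else np.inf
                continue
            if is_loaded:
                if (not prev) and self._unloaded_time[leg] >= self.debounce - 1e-12:
                    # initial contact
                    if self.window_start is None:
                        self.window_start, self.leading = step_index, side
                    elif side != self.leading:
                        completed = (self.window_start, step_index, side)
                        self.window_start, self.leading = step_index, side
                self._loaded[leg] = True
                self._unloaded_time[leg] = 0.0
            else:
                self._unloaded_time[leg] = (self.dt if prev
                                            else self._unloaded_time[leg] + self.dt)
                self._loaded[leg] = False
        return completed


# ---------------------------------------------------------------------------
# reward
# ---------------------------------------------------------------------------

def footstep_reward(fs: FootstepRecord, weights: RewardWeights,
                    v_tgt: float | None, dt: float = DT):
    """Weighted footstep reward and its components.

    ``v_tgt = None`` omits the velocity cost entirely (the self-selected
    speed protocol).
    """
    r_steps = fs.v_pel.size * dt
    if v_tgt is None:
        j_vel = 0.0
    elif weights.j_vel_per_step:
        j_vel = float(np.sum(np.abs(fs.v_pel - v_tgt))) * dt
    else:
        j_vel = abs(float(np.sum(fs.v_pel - v_tgt)) * dt)
    j_pel = float(np.sum(fs.theta_pel ** 2)) * dt
    j_mul = float(np.sum(fs.excitations ** 2)) * dt
    total = (weights.w_steps * r_steps - weights.w_vel * j_vel
             - weights.w_pel * j_pel - weights.w_mul * j_mul)
    return total, {"r_steps": r_steps, "J_vel": j_vel,
                   "J_pel": j_pel, "J_mul": j_mul}


def episode_reward(trace: EpisodeTrace, weights: RewardWeights,
                   v_tgt: float | None, dt: float = DT) -> float:
    """Survival reward plus all completed-footstep rewards."""
    total = dt * trace.n_steps
    for fs in trace.footsteps:
        r, _ = footstep_reward(fs, weights, v_tgt, dt)
        total += r
    return total


# ---------------------------------------------------------------------------
# the environment
# ---------------------------------------------------------------------------

class EpisodeDone(RuntimeError):
    pass


class InvalidInitialState(ValueError):
    pass


class WalkingEnv:
    """reset/step interface over the musculoskeletal plant."""

    def __init__(self, skeleton: SkeletonModel | None = None,
                 muscles: MuscleSet | None = None,
                 weights: RewardWeights | None = None,
                 horizon: float = 10.0,
                 v_tgt: float | None = 1.3,
                 dt: float = DT,
                 n_substeps: int = N_SUBSTEPS):
        self.skeleton = skeleton or SkeletonModel()
        self.muscles = muscles or MuscleSet()
        self.weights = weights or RewardWeights()
        self.horizon = horizon
        self.v_tgt = v_tgt
        self.dt = dt
        self.n_substeps = n_substeps
        self.state: SystemState | None = None
        self.done = True

    # -- lifecycle --------------------------------------------------------

    def reset(self, init: InitialStateParams,
              baseline_excitations: np.ndarray | None = None) -> np.ndarray:
        if init.pelvis_height <= FALL_HEIGHT:
            raise InvalidInitialState(
                f"initial pelvis height {init.pelvis_height} m is at or below "
                f"the fall threshold {FALL_HEIGHT} m")
        q = np.zeros(NQ)
        q[1] = init.pelvis_height
        q[2] = init.trunk_lean
        q[3] = init.hip_flexion_R
        q[4] = init.knee_flexion_R
        q[5] = init.ankle_R
        q[6] = init.hip_flexion_L
        q[7] = init.knee_flexion_L
        q[8] = init.ankle_L
        qdot = np.zeros(NQ)
        qdot[0] = init.forward_speed
        if baseline_excitations is None:
            baseline_excitations = np.full(18, ctl.EXC_MIN)
        a0 = np.clip(baseline_excitations, ctl.EXC_MIN, ctl.EXC_MAX)
        self.state = SystemState(q, qdot, a0.astype(float))
        self.done = False
        self._rows = {k: [] for k in
                      ("time", "q", "qdot", "exc", "act", "grf")}
        self._machine = _FootstepMachine(self.dt)
        self._step_index = 0
        self._r_alive = 0.0
        self._footsteps: list[FootstepRecord] = []
        self._footstep_rewards: list[float] = []
        self._prev_f_norm = np.zeros(18)
        self._prev_l_norm = self.muscles.norm_fiber_length(q[3:])
        self._last_grf = self.skeleton.compute_contact(self.state)
        return self.observe()

    def step(self, action: np.ndarray):
        """Advance one control interval; returns (obs, reward_increment,
        done, info)."""
        if self.done or self.state is None:
            raise EpisodeDone("step() called on a finished episode")
        e = np.asarray(action, dtype=float)
        if e.shape != (18,) or np.any(e < -1e-9) or np.any(e > 1 + 1e-9):
            raise ValueError("action must be an 18-vector of excitations in [0, 1]")
        e = np.clip(e, 0.0, 1.0)

        st = self.state
        # sensory memory for the next step's (delayed) readout
        q_j, qd_j = st.q[3:], st.qdot[3:]
        l_mt, v_mt = self.muscles.mtu_kinematics(q_j, qd_j)
        F = self.muscles.forces(st.activations, l_mt, v_mt)
        self._prev_f_norm = F / self.muscles.mif
        self._prev_l_norm = (l_mt - self.muscles.l_slack) / self.muscles.l_opt

        st.activations = activation_step(st.activations, e, self.dt,
                                         self.muscles.tau_act,
                                         self.muscles.tau_deact)
        h = self.dt / self.n_substeps
        grf_acc = np.zeros(4)
        for _ in range(self.n_substeps):
            l_mt, v_mt = self.muscles.mtu_kinematics(st.q[3:], st.qdot[3:])
            F = self.muscles.forces(st.activations, l_mt, v_mt)
            tau = self.muscles.joint_torques(F)
            st, gr = self.skeleton.step(st, tau, h)
            grf_acc += [gr.right_vertical, gr.right_horizontal,
                        gr.left_vertical, gr.left_horizontal]
        self.state = st
        self._last_grf = gr
        grf_mean = grf_acc / self.n_substeps

        self._rows["time"].append(st.time)
        self._rows["q"].append(st.q.copy())
        self._rows["qdot"].append(st.qdot.copy())
        self._rows["exc"].append(e.copy())
        self._rows["act"].append(st.activations.copy())
        self._rows["grf"].append(grf_mean)

        reward = self.dt  # survival reward for this executed step
        self._r_alive += self.dt
        info = {"footstep": None}

        completed = self._machine.update(self._step_index, grf_mean[0], grf_mean[2])
        if completed is not None:
            fs = self._make_record(*completed)
            self._footsteps.append(fs)
            r_fs, comps = footstep_reward(fs, self.weights, self.v_tgt, self.dt)
            self._footstep_rewards.append(r_fs)
            reward += r_fs
            info["footstep"] = comps
        self._step_index += 1

        fell = st.q[1] < FALL_HEIGHT
        out_of_time = st.time >= self.horizon - 1e-9
        if fell or out_of_time:
            self.done = True
            info["terminated_early"] = bool(fell)
        return self.observe(), reward, self.done, info

    def _make_record(self, start: int, end: int, leading: str) -> FootstepRecord:
        v = np.array([qd[0] for qd in self._rows["qdot"][start:end]])
        th = np.array([q[2] for q in self._rows["q"][start:end]])
        ex = np.array(self._rows["exc"][start:end])
        return FootstepRecord(start, end, (end - start) * self.dt, leading, v, th, ex)

    # -- observation / readout -------------------------------------------

    def load_share(self) -> np.ndarray:
        gr = self._last_grf
        tot = gr.right_vertical + gr.left_vertical
        if tot <= 0.0:
            return np.zeros(2)
        return np.array([gr.right_vertical / tot, gr.left_vertical / tot])

    def readout(self) -> ctl.SensoryReadout:
        """Sensory readout for the reflex controller; muscle force/length
        channels are delayed by one control step (neural transport delay)."""
        st = self.state
        return ctl.SensoryReadout(
            f_norm=self._prev_f_norm.copy(),
            l_norm=self._prev_l_norm.copy(),
            trunk_pitch=float(st.q[2]),
            trunk_pitch_vel=float(st.qdot[2]),
            load_share=self.load_share(),
            joint_angles=st.q[3:].copy(),
            joint_velocities=st.qdot[3:].copy(),
        )

    def observe(self) -> np.ndarray:
        st = self.state
        gr = self._last_grf
        contact = np.array([gr.right_vertical > ctl.CONTACT_THRESHOLD,
                            gr.left_vertical > ctl.CONTACT_THRESHOLD], dtype=float)
        return np.concatenate([
            [st.q[1], st.q[2], st.qdot[0], st.qdot[1], st.qdot[2]],
            st.q[3:], st.qdot[3:], contact, self.load_share(),
            self._prev_f_norm, self._prev_l_norm,
        ])

    # -- episode assembly -------------------------------------------------

    def trace(self) -> EpisodeTrace:
        n = len(self._rows["time"])
        tr = EpisodeTrace(
            time=np.array(self._rows["time"]),
            q=np.array(self._rows["q"]).reshape(n, NQ),
            qdot=np.array(self._rows["qdot"]).reshape(n, NQ),
            excitations=np.array(self._rows["exc"]).reshape(n, 18),
            activations=np.array(self._rows["act"]).reshape(n, 18),
            grf=np.array(self._rows["grf"]).reshape(n, 4),
            footsteps=list(self._footsteps),
            terminated_early=bool(self.state.q[1] < FALL_HEIGHT),
        )
        comps = {"R_alive": self._r_alive,
                 "footstep_rewards": list(self._footstep_rewards)}
        tr.total_reward = self._r_alive + float(np.sum(self._footstep_rewards))
        tr.reward_components = comps
        return tr


# ---------------------------------------------------------------------------
# closed-loop rollout
# ---------------------------------------------------------------------------

def rollout(params: ctl.ControllerParams, init: InitialStateParams,
            env: WalkingEnv) -> EpisodeTrace:
    """Run one full episode under the reflex policy."""
    env.reset(init, baseline_excitations=params.baselines())
    phases = (ctl.LegPhase(), ctl.LegPhase())
    done = False
    while not done:
        gr = env._last_grf
        phases = ctl.update_phases((gr.right_vertical, gr.left_vertical),
                                   phases, env.dt)
        e = ctl.compute_excitations(env.readout(), phases, params)
        _, _, done, _ = env.step(e)
    return env.trace()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def trace_to_dataframe(trace: EpisodeTrace) -> pd.DataFrame:
    cols = {"time": trace.time}
    for i, lab in enumerate(Q_LABELS):
        cols[f"q_{lab}"] = trace.q[:, i]
    for i, lab in enumerate(Q_LABELS):
        cols[f"qdot_{lab}"] = trace.qdot[:, i]
    for i, lab in enumerate(("grf_R_vertical", "grf_R_horizontal",
                             "grf_L_vertical", "grf_L_horizontal")):
        cols[lab] = trace.grf[:, i]
    for i in range(18):
        cols[f"e_{i}"] = trace.excitations[:, i]
    return pd.DataFrame(cols)


def save_trace(trace: EpisodeTrace, csv_path, json_path=None) -> None:
    """CSV time series plus a JSON sidecar (rewards, footsteps, termination)."""
    trace_to_dataframe(trace).to_csv(csv_path, index=False)
    if json_path is not None:
        sidecar = {
            "total_reward": trace.total_reward,
            "reward_components": trace.reward_components,
            "terminated_early": trace.terminated_early,
            "footsteps": [
                {"start_step": fs.start_step, "end_step": fs.end_step,
                 "duration": fs.duration, "leading_foot": fs.leading_foot}
                for fs in trace.footsteps],
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)


def load_trace(csv_path, json_path=None) -> EpisodeTrace:
    df = pd.read_csv(csv_path)
    n = len(df)
    q = np.stack([df[f"q_{lab}"].to_numpy() for lab in Q_LABELS], axis=1)
    qdot = np.stack([df[f"qdot_{lab}"].to_numpy() for lab in Q_LABELS], axis=1)
    grf = np.stack([df[lab].to_numpy() for lab in
                    ("grf_R_vertical", "grf_R_horizontal",
                     "grf_L_vertical", "grf_L_horizontal")], axis=1)
    exc = np.stack([df[f"e_{i}"].to_numpy() for i in range(18)], axis=1)
    tr = EpisodeTrace(df["time"].to_numpy(), q, qdot, exc,
                      np.zeros((n, 18)), grf)
    if json_path is not None:
        with open(json_path) as fh:
            side = json.load(fh)
        tr.total_reward = side["total_reward"]
        tr.reward_components = side["reward_components"]
        tr.terminated_early = side["terminated_early"]
        for fs in side["footsteps"]:
            s, e = fs["start_step"], fs["end_step"]
            tr.footsteps.append(FootstepRecord(
                s, e, fs["duration"], fs["leading_foot"],
                tr.qdot[s:e, 0], tr.q[s:e, 2], tr.excitations[s:e]))
    return tr
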