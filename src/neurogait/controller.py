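"""Phase-dependent reflex controller: 37 parameters, 18 muscle excitations.

A deterministic policy maps delayed proprioceptive signals (normalized muscle
forces and fiber lengths), trunk orientation and foot loading to muscle
excitations through simple spinal-reflex-style laws:

* stance: positive force feedback on the plantarflexors (SOL, GAS) and the
  anti-gravity muscles (VAS, HAM, GMAX), a stretch reflex on TA with
  reciprocal inhibition from SOL force, knee-overextension inhibition of VAS,
  and a trunk-balance PD signal distributed to HAM/GMAX (forward lean) or
  ILPSO (backward lean) in proportion to the leg's load share;
* swing: length feedback on ILPSO for leg swing initiation, PD drives of the
  knee and ankle toward swing target angles through antagonist muscle pairs,
  force feedback on HAM and velocity damping via BFSH;
* a constant co-stimulation baseline per muscle group and a double-support
  push-off boost on the trailing leg.

All 37 parameters are shared bilaterally.  Excitations are clamped to
[0.01, 1]: the floor is a small tonic drive that keeps muscles numerically
alive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .muscle import MUSCLE_GROUPS, N_MUSCLES

N_PARAMS = 37
EXC_MIN = 0.01
EXC_MAX = 1.0
CONTACT_THRESHOLD = 20.0  # N, vertical GRF defining foot loading

#: canonical parameter order (names match the attributes of ControllerParams)
PARAM_NAMES = (
    "theta_tgt_trunk",           # 1  rad, trunk-lean target
    "theta_tgt_knee_swing",      # 2  rad
    "theta_tgt_ankle_swing",     # 3  rad
    "g_f_sol",                   # 4  force-feedback gains (F normalized by MIF)
    "g_f_gas",                   # 5
    "g_f_vas",                   # 6
    "g_f_ham_stance",            # 7
    "g_f_gmax_stance",           # 8
    "g_f_ham_swing",             # 9
    "g_l_ta",                    # 10 TA stretch-reflex gain (1/l_opt)
    "l_off_ta",                  # 11 TA length offset (l_opt units)
    "g_solta",                   # 12 SOL->TA reciprocal inhibition
    "g_l_ilpso_swing",           # 13
    "l_off_ilpso",               # 14
    "g_v_bfsh_swing",            # 15 knee-extension velocity damping in swing
    "g_v_knee_stance",           # 16 knee-extension velocity damping in stance
    "k_overext",                 # 17 VAS inhibition near knee overextension
    "phi_knee_off",              # 18 rad, overextension threshold angle
    "kp_trunk",                  # 19
    "kd_trunk",                  # 20
    "w_ham",                     # 21 trunk-PD distribution weights
    "w_gmax",                    # 22
    "w_ilpso",                   # 23
    "c0_ilpso",                  # 24 co-stimulation baselines, [0, 1]
    "c0_gmax",                   # 25
    "c0_ham",                    # 26
    "c0_rf",                     # 27
    "c0_vas",                    # 28
    "c0_bfsh",                   # 29
    "c0_gas",                    # 30
    "c0_sol",                    # 31
    "c0_ta",                     # 32
    "kp_ankle_swing",            # 33
    "kd_ankle_swing",            # 34
    "kp_knee_swing",             # 35
    "kd_knee_swing",             # 36
    "e_ds",                      # 37 double-support push-off boost
)

_BASELINE_NAMES = tuple(f"c0_{g.lower()}" for g in MUSCLE_GROUPS)


@dataclass(frozen=True)
class ControllerParams:
    """The 37 reflex-control parameters (bilaterally shared)."""

    theta_tgt_trunk: float = 0.05
    theta_tgt_knee_swing: float = 1.0
    theta_tgt_ankle_swing: float = 0.0
    g_f_sol: float = 1.0
    g_f_gas: float = 1.0
    g_f_vas: float = 1.0
    g_f_ham_stance: float = 0.3
    g_f_gmax_stance: float = 0.3
    g_f_ham_swing: float = 0.3
    g_l_ta: float = 1.0
    l_off_ta: float = 1.0
    g_solta: float = 0.5
    g_l_ilpso_swing: float = 1.0
    l_off_ilpso: float = 0.9
    g_v_bfsh_swing: float = 0.2
    g_v_knee_stance: float = 0.2
    k_overext: float = 1.0
    phi_knee_off: float = 0.15
    kp_trunk: float = 1.0
    kd_trunk: float = 0.3
    w_ham: float = 0.5
    w_gmax: float = 0.5
    w_ilpso: float = 0.5
    c0_ilpso: float = 0.05
    c0_gmax: float = 0.05
    c0_ham: float = 0.05
    c0_rf: float = 0.05
    c0_vas: float = 0.08
    c0_bfsh: float = 0.05
    c0_gas: float = 0.05
    c0_sol: float = 0.05
    c0_ta: float = 0.05
    kp_ankle_swing: float = 1.0
    kd_ankle_swing: float = 0.2
    kp_knee_swing: float = 1.0
    kd_knee_swing: float = 0.2
    e_ds: float = 0.25

    def baseline(self, group: str) -> float:
        return getattr(self, f"c0_{group.lower()}")

    def baselines(self) -> np.ndarray:
        """Co-stimulation baselines in canonical 18-muscle order (R then L)."""
        per_group = np.array([self.baseline(g) for g in MUSCLE_GROUPS])
        return np.concatenate([per_group, per_group])


def pack_params(params: ControllerParams) -> np.ndarray:
    """Flatten named parameters into the canonical 37-vector."""
    return np.array([getattr(params, n) for n in PARAM_NAMES], dtype=float)


def unpack_params(vector: np.ndarray) -> ControllerParams:
    """Inverse of :func:`pack_params`; rejects wrong dimensionality."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.shape != (N_PARAMS,):
        raise ValueError(f"controller parameter vector must have length "
                         f"{N_PARAMS}, got {v.shape}")
    return ControllerParams(**dict(zip(PARAM_NAMES, v)))


def project_params(vector: np.ndarray) -> np.ndarray:
    """Project a raw 37-vector into the feasible region: gains non-negative,
    co-stimulation baselines in [0, 1].  Target angles pass through."""
    v = np.asarray(vector, dtype=float).copy()
    if v.shape != (N_PARAMS,):
        raise ValueError(f"expected length {N_PARAMS}, got {v.shape}")
    angle_idx = {PARAM_NAMES.index(n) for n in
                 ("theta_tgt_trunk", "theta_tgt_knee_swing",
                  "theta_tgt_ankle_swing", "phi_knee_off")}
    base_idx = [PARAM_NAMES.index(n) for n in _BASELINE_NAMES]
    for i in range(N_PARAMS):
        if i in angle_idx:
            continue
        v[i] = max(v[i], 0.0)
    v[base_idx] = np.clip(v[base_idx], 0.0, 1.0)
    return v


# ---------------------------------------------------------------------------
# gait phase bookkeeping
# ---------------------------------------------------------------------------

STANCE = "STANCE"
SWING = "SWING"


@dataclass
class LegPhase:
    phase: str = STANCE
    in_double_support: bool = True
    time_since_transition: float = 0.0


def update_phases(grf_vertical: tuple[float, float],
                  phases: tuple[LegPhase, LegPhase],
                  dt: float,
                  threshold: float = CONTACT_THRESHOLD) -> tuple[LegPhase, LegPhase]:
    """Advance per-leg stance/swing flags from the vertical GRFs (R, L)."""
    loaded = [g > threshold for g in grf_vertical]
    out = []
    for ph, ld in zip(phases, loaded):
        target = STANCE if ld else SWING
        if target != ph.phase:
            out.append(LegPhase(target, False, 0.0))
        else:
            out.append(LegPhase(ph.phase, False, ph.time_since_transition + dt))
    ds = loaded[0] and loaded[1]
    for ph in out:
        ph.in_double_support = ds
    return out[0], out[1]


# ---------------------------------------------------------------------------
# sensory readout
# ---------------------------------------------------------------------------

@dataclass
class SensoryReadout:
    """Inputs to the reflex laws (force/length channels carry the neural
    transport delay; one control step by default)."""

    f_norm: np.ndarray           # (18,) muscle force / MIF
    l_norm: np.ndarray           # (18,) fiber length / l_opt
    trunk_pitch: float           # rad, anterior-positive
    trunk_pitch_vel: float       # rad/s
    load_share: np.ndarray       # (2,) per-leg share of total vertical GRF
    joint_angles: np.ndarray     # (6,) hip/knee/ankle R then L
    joint_velocities: np.ndarray  # (6,)

    def validate(self):
        for name in ("f_norm", "l_norm", "load_share",
                     "joint_angles", "joint_velocities"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite sensory channel: {name}")
        if not (np.isfinite(self.trunk_pitch) and np.isfinite(self.trunk_pitch_vel)):
            raise ValueError("non-finite sensory channel: trunk_pitch")


def mirror_readout(r: SensoryReadout) -> SensoryReadout:
    """Swap left/right channels (bilateral-symmetry helper)."""
    sw18 = np.concatenate([r.f_norm[9:], r.f_norm[:9]])
    sl18 = np.concatenate([r.l_norm[9:], r.l_norm[:9]])
    return SensoryReadout(
        sw18, sl18, r.trunk_pitch, r.trunk_pitch_vel,
        r.load_share[::-1].copy(),
        np.concatenate([r.joint_angles[3:], r.joint_angles[:3]]),
        np.concatenate([r.joint_velocities[3:], r.joint_velocities[:3]]),
    )


# ---------------------------------------------------------------------------
# the reflex law set
# ---------------------------------------------------------------------------

_GI = {g: i for i, g in enumerate(MUSCLE_GROUPS)}


def compute_excitations(readout: SensoryReadout,
                        phases: tuple[LegPhase, LegPhase],
                        params: ControllerParams) -> np.ndarray:
    """Evaluate the reflex laws; returns 18 excitations in [0.01, 1]."""
    readout.validate()
    p = params
    e = np.tile([p.baseline(g) for g in MUSCLE_GROUPS], 2)

    for leg in (0, 1):  # 0 = right, 1 = left
        off = 9 * leg
        ph = phases[leg]
        f = readout.f_norm[off:off + 9]
        l = readout.l_norm[off:off + 9]
        knee = readout.joint_angles[3 * leg + 1]
        knee_vel = readout.joint_velocities[3 * leg + 1]
        ankle = readout.joint_angles[3 * leg + 2]
        ankle_vel = readout.joint_velocities[3 * leg + 2]
        chi = readout.load_share[leg]

        if ph.phase == STANCE:
            e[off + _GI["SOL"]] += p.g_f_sol * f[_GI["SOL"]]
            e[off + _GI["GAS"]] += p.g_f_gas * f[_GI["GAS"]]
            # VAS: force feedback, inhibited near overextension while the
            # knee is extending, plus extension-velocity damping
            extending = knee_vel < 0.0
            e[off + _GI["VAS"]] += (
                p.g_f_vas * f[_GI["VAS"]]
                - p.k_overext * max(0.0, p.phi_knee_off - knee) * extending
                - p.g_v_knee_stance * max(0.0, -knee_vel))
            # TA stretch reflex with reciprocal inhibition from SOL force
            e[off + _GI["TA"]] += (p.g_l_ta * max(0.0, l[_GI["TA"]] - p.l_off_ta)
                                   - p.g_solta * f[_GI["SOL"]])
            e[off + _GI["HAM"]] += p.g_f_ham_stance * f[_GI["HAM"]]
            e[off + _GI["GMAX"]] += p.g_f_gmax_stance * f[_GI["GMAX"]]
            # trunk balance PD, load-share weighted
            u = (p.kp_trunk * (readout.trunk_pitch - p.theta_tgt_trunk)
                 + p.kd_trunk * readout.trunk_pitch_vel)
            if u > 0.0:
                e[off + _GI["HAM"]] += p.w_ham * u * chi
                e[off + _GI["GMAX"]] += p.w_gmax * u * chi
            else:
                e[off + _GI["ILPSO"]] += p.w_ilpso * (-u) * chi
            # double-support push-off boost on the trailing (less loaded) leg
            if ph.in_double_support and chi <= readout.load_share[1 - leg]:
                e[off + _GI["SOL"]] += p.e_ds
                e[off + _GI["GAS"]] += p.e_ds
                e[off + _GI["ILPSO"]] += p.e_ds
        else:  # SWING
            e[off + _GI["ILPSO"]] += p.g_l_ilpso_swing * max(
                0.0, l[_GI["ILPSO"]] - p.l_off_ilpso)
            # knee PD toward the swing target through the VAS/BFSH pair
            u_k = (p.kp_knee_swing * (p.theta_tgt_knee_swing - knee)
                   - p.kd_knee_swing * knee_vel)
            e[off + _GI["BFSH"]] += max(0.0, u_k)
            e[off + _GI["VAS"]] += max(0.0, -u_k)
            # ankle PD toward the swing target through the TA/SOL pair
            u_a = (p.kp_ankle_swing * (p.theta_tgt_ankle_swing - ankle)
                   - p.kd_ankle_swing * ankle_vel)
            e[off + _GI["TA"]] += max(0.0, u_a)
            e[off + _GI["SOL"]] += max(0.0, -u_a)
            e[off + _GI["HAM"]] += p.g_f_ham_swing * f[_GI["HAM"]]
            e[off + _GI["BFSH"]] += p.g_v_bfsh_swing * max(0.0, -knee_vel)

    return np.clip(e, EXC_MIN, EXC_MAX)


def save_params_json(params: ControllerParams, path) -> None:
    """Persist both the named fields and the flat canonical vector."""
    import json
    payload = {
        "named": {n: float(getattr(params, n)) for n in PARAM_NAMES},
        "vector": [float(x) for x in pack_params(params)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_params_json(path) -> ControllerParams:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    if "named" in payload:
        return ControllerParams(**payload["named"])
    return unpack_params(np.array(payload["vector"]))
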