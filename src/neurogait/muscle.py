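"""18 Hill-type muscle-tendon units (MTUs) with rigid tendons.

Nine muscle groups per leg: iliopsoas (ILPSO), gluteus maximus (GMAX),
hamstrings (HAM), rectus femoris (RF), vasti (VAS), biceps femoris short
head (BFSH), gastrocnemius (GAS), soleus (SOL) and tibialis anterior (TA).
HAM, RF and GAS are biarticular; the rest span a single joint.

The contraction model is the standard phenomenological product form

    F = MIF * (a * f_L(l~) * f_V(v~) + f_PE(l~)),   F >= 0

with normalized fiber length l~ = l_fiber / l_opt and normalized velocity
v~ = v_fiber / (v_max * l_opt).  Tendons are non-compliant, so
l_fiber = l_MT - l_slack and the fiber sees the full MTU velocity.
MTU lengths are affine in the joint angles with constant signed moment
arms r:  l_MT = l_ref - sum_j r_j * (q_j - q_ref_j), and the same moment
arms map muscle forces to joint torques, tau_j = sum_k r_kj F_k.

Excitation-to-activation coupling is first-order with separate rise and
decay time constants (activation dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import JOINT_LABELS, N_INTERNAL

MUSCLE_GROUPS = ("ILPSO", "GMAX", "HAM", "RF", "VAS", "BFSH", "GAS", "SOL", "TA")
SIDES = ("R", "L")
N_MUSCLES = 18
BIARTICULAR = ("HAM", "RF", "GAS")

#: default per-group parameters: MIF (N), optimal fiber length (m),
#: signed moment arms (m) per spanned joint (flexion/dorsiflexion positive).
_DEFAULTS = {
    #          MIF    l_opt  {joint: moment arm}
    "ILPSO": (1500.0, 0.10, {"hip": +0.05}),
    "GMAX":  (1500.0, 0.11, {"hip": -0.06}),
    "HAM":   (3000.0, 0.10, {"hip": -0.06, "knee": +0.03}),
    "RF":    (1200.0, 0.08, {"hip": +0.04, "knee": -0.045}),
    "VAS":   (6000.0, 0.08, {"knee": -0.045}),
    "BFSH":  (350.0,  0.12, {"knee": +0.03}),
    "GAS":   (1500.0, 0.05, {"knee": +0.02, "ankle": -0.05}),
    "SOL":   (4000.0, 0.04, {"ankle": -0.05}),
    "TA":    (800.0,  0.06, {"ankle": +0.04}),
}

TAU_ACT = 0.01    # s, activation rise
TAU_DEACT = 0.04  # s, deactivation
V_MAX = 10.0      # optimal fiber lengths / s


@dataclass(frozen=True)
class MuscleParams:
    """One muscle-tendon unit (SI units; moment arms flexion-positive)."""

    name: str
    side: str
    max_isometric_force: float
    optimal_fiber_length: float
    tendon_slack_length: float
    moment_arms: dict[str, float]       # joint label (e.g. "ankle_R") -> m
    mtu_ref_length: float               # MTU length at the reference posture
    max_contraction_velocity: float = V_MAX
    tau_act: float = TAU_ACT
    tau_deact: float = TAU_DEACT

    def __post_init__(self):
        if self.max_isometric_force <= 0 or self.optimal_fiber_length <= 0:
            raise ValueError(f"{self.name}_{self.side}: MIF and l_opt must be positive")
        if not self.tau_act < self.tau_deact:
            raise ValueError(f"{self.name}_{self.side}: tau_act must be below tau_deact")
        n = len(self.moment_arms)
        expected = 2 if self.name in BIARTICULAR else 1
        if n != expected:
            raise ValueError(f"{self.name}: expected {expected} spanned joints, got {n}")


def muscle_order() -> list[tuple[str, str]]:
    """Canonical (group, side) order of the 18-vector: right leg then left."""
    return [(g, s) for s in SIDES for g in MUSCLE_GROUPS]


def default_muscles(standing_ltilde: float = 1.0) -> list[MuscleParams]:
    """Shipped default MTU table, bilaterally symmetric.

    ``mtu_ref_length`` is normalized so that the upright standing posture
    (reference posture, all internal joint angles zero) gives a normalized
    fiber length of ``standing_ltilde`` for every muscle.
    """
    out = []
    for group, side in muscle_order():
        mif, lopt, arms = _DEFAULTS[group]
        arms_side = {f"{j}_{side}": r for j, r in arms.items()}
        lslack = 2.0 * lopt  # generic tendon share; absolute value is inert with rigid tendons
        ref = lslack + standing_ltilde * lopt
        out.append(MuscleParams(group, side, mif, lopt, lslack, arms_side, ref))
    return out


class MuscleSet:
    """Vectorized container for the 18 MTUs of one model."""

    def __init__(self, muscles: list[MuscleParams] | None = None):
        muscles = muscles if muscles is not None else default_muscles()
        if len(muscles) != N_MUSCLES:
            raise ValueError(f"expected {N_MUSCLES} muscles, got {len(muscles)}")
        order = {f"{g}_{s}": i for i, (g, s) in enumerate(muscle_order())}
        by_key = {f"{m.name}_{m.side}": m for m in muscles}
        if set(by_key) != set(order):
            raise ValueError("muscle set must contain each group once per side")
        self.muscles = [by_key[k] for k in sorted(order, key=order.get)]
        self.names = list(sorted(order, key=order.get))
        self.mif = np.array([m.max_isometric_force for m in self.muscles])
        self.l_opt = np.array([m.optimal_fiber_length for m in self.muscles])
        self.l_slack = np.array([m.tendon_slack_length for m in self.muscles])
        self.l_ref = np.array([m.mtu_ref_length for m in self.muscles])
        self.v_max = np.array([m.max_contraction_velocity for m in self.muscles])
        self.tau_act = np.array([m.tau_act for m in self.muscles])
        self.tau_deact = np.array([m.tau_deact for m in self.muscles])
        # moment-arm matrix R (18 x 6): tau = R.T @ F, l_MT = l_ref - R @ dq
        self.R = np.zeros((N_MUSCLES, N_INTERNAL))
        jidx = {j: i for i, j in enumerate(JOINT_LABELS)}
        for k, m in enumerate(self.muscles):
            for joint, r in m.moment_arms.items():
                self.R[k, jidx[joint]] = r
        self.q_ref = np.zeros(N_INTERNAL)

    def index(self, group: str, side: str) -> int:
        return self.names.index(f"{group}_{side}")

    def scaled(self, group: str, factor: float) -> "MuscleSet":
        """New MuscleSet with the named group's MIF scaled bilaterally.

        This is the muscle-weakness mechanism: scaling MIF by s scales the
        isometric force, and hence the torque contribution, exactly by s.
        """
        from dataclasses import replace
        out = [replace(m, max_isometric_force=m.max_isometric_force * factor)
               if m.name == group else m for m in self.muscles]
        return MuscleSet(out)

    # -- kinematics -------------------------------------------------------

    def mtu_kinematics(self, q_joints: np.ndarray, qdot_joints: np.ndarray):
        """MTU lengths (m) and lengthening velocities (m/s) for all 18 units."""
        l_mt = self.l_ref - self.R @ (q_joints - self.q_ref)
        v_mt = -self.R @ qdot_joints
        return l_mt, v_mt

    def norm_fiber_length(self, q_joints: np.ndarray) -> np.ndarray:
        l_mt, _ = self.mtu_kinematics(q_joints, np.zeros(N_INTERNAL))
        return (l_mt - self.l_slack) / self.l_opt

    # -- force ------------------------------------------------------------

    def forces(self, a: np.ndarray, l_mt: np.ndarray, v_mt: np.ndarray) -> np.ndarray:
        """Muscle forces (N) under the rigid-tendon Hill model."""
        l_fiber = l_mt - self.l_slack
        bad = l_fiber <= 0.0
        ltilde = np.where(bad, 1.0, l_fiber / self.l_opt)
        vtilde = v_mt / (self.v_max * self.l_opt)
        active = a * force_length(ltilde) * force_velocity(vtilde)
        passive = force_passive(ltilde)
        F = self.mif * (active + passive)
        F[bad] = 0.0
        return np.maximum(F, 0.0)

    def joint_torques(self, forces: np.ndarray) -> np.ndarray:
        """Map 18 muscle forces to torques on the 6 internal DOF."""
        return self.R.T @ forces


# ---------------------------------------------------------------------------
# contraction curves
# ---------------------------------------------------------------------------

FL_WIDTH = 0.45
FV_SHAPE_CON = 0.25   # curvature of the concentric (shortening) hyperbola
FV_ECC_PLATEAU = 1.5  # eccentric saturation
PE_SHAPE = 4.0
PE_STRAIN = 0.6       # f_PE reaches 1 at 60% stretch beyond optimal


def force_length(ltilde: np.ndarray) -> np.ndarray:
    """Active force-length curve, Gaussian peaking at optimal length."""
    return np.exp(-((np.asarray(ltilde, dtype=float) - 1.0) / FL_WIDTH) ** 2)


def force_velocity(vtilde: np.ndarray) -> np.ndarray:
    """Force-velocity curve: Hill hyperbola for shortening (v~ < 0, zero at
    -1), saturating eccentric branch (plateau 1.5) for lengthening."""
    v = np.asarray(vtilde, dtype=float)
    con = np.clip(1.0 + v, 0.0, None) / (1.0 - np.minimum(v, 0.0) / FV_SHAPE_CON)
    k = FV_SHAPE_CON
    ecc = (FV_ECC_PLATEAU * v + k) / (v + k)
    return np.where(v <= 0.0, con, ecc)


def force_passive(ltilde: np.ndarray) -> np.ndarray:
    """Passive elastic curve, exponential, engaging beyond optimal length."""
    l = np.asarray(ltilde, dtype=float)
    stretch = np.clip(l - 1.0, 0.0, None)
    return (np.exp(PE_SHAPE * stretch / PE_STRAIN) - 1.0) / (np.exp(PE_SHAPE) - 1.0)


# ---------------------------------------------------------------------------
# activation dynamics
# ---------------------------------------------------------------------------

def activation_step(a, e, dt: float, tau_act=TAU_ACT, tau_deact=TAU_DEACT):
    """Advance first-order activation dynamics over ``dt``.

    da/dt = (e - a)/tau with tau = tau_act while excitation exceeds
    activation and tau_deact otherwise; integrated exactly (the ODE is linear
    within the step) and clamped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    tau = np.where(e > a, tau_act, tau_deact)
    out = e + (a - e) * np.exp(-dt / tau)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# single-muscle convenience (scalar API mirroring the vectorized MuscleSet)
# ---------------------------------------------------------------------------

def muscle_force(a: float, l_mt: float, v_mt: float, params: MuscleParams) -> float:
    """Force (N) of one MTU; returns zero active force if the rigid-tendon
    fiber length is non-positive (degenerate geometry)."""
    l_fiber = l_mt - params.tendon_slack_length
    if l_fiber <= 0.0:
        return 0.0
    ltilde = l_fiber / params.optimal_fiber_length
    vtilde = v_mt / (params.max_contraction_velocity * params.optimal_fiber_length)
    F = params.max_isometric_force * (
        a * float(force_length(ltilde)) * float(force_velocity(vtilde))
        + float(force_passive(ltilde)))
    return max(F, 0.0)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_CSV_COLS = ["name", "side", "max_isometric_force", "optimal_fiber_length",
             "tendon_slack_length", "joints", "moment_arms", "mtu_ref_length"]


def muscles_to_csv(muscles: list[MuscleParams], path) -> None:
    """Write a muscle parameter table (one row per MTU)."""
    import pandas as pd
    rows = []
    for m in muscles:
        joints = ";".join(m.moment_arms)
        arms = ";".join(f"{r:.6g}" for r in m.moment_arms.values())
        rows.append([m.name, m.side, m.max_isometric_force, m.optimal_fiber_length,
                     m.tendon_slack_length, joints, arms, m.mtu_ref_length])
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


def muscles_from_csv(path) -> list[MuscleParams]:
    import pandas as pd
    df = pd.read_csv(path)
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"muscle table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        joints = str(row["joints"]).split(";")
        arms = [float(x) for x in str(row["moment_arms"]).split(";")]
        out.append(MuscleParams(
            row["name"], row["side"], float(row["max_isometric_force"]),
            float(row["optimal_fiber_length"]), float(row["tendon_slack_length"]),
            dict(zip(joints, arms)), float(row["mtu_ref_length"])))
    return out
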