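"""Planar rigid-body dynamics of a 7-segment biped.

The walker is a sagittal-plane chain: a lumped head-arms-trunk-pelvis (HAT)
segment plus thigh, shank and foot on each side.  Its configuration is the
9-vector

    q = [pelvis_x, pelvis_y, pelvis_pitch,
         hip_R, knee_R, ankle_R, hip_L, knee_L, ankle_L]

with a planar floating base (x, y, pitch) and 6 internal revolute joints.
Sign conventions: hip flexion positive, knee flexion positive, ankle
dorsiflexion positive, pelvis pitch positive = anterior tilt.

Equations of motion M(q) q̈ = Q(q, q̇) are assembled from per-segment
centre-of-mass Jacobians (composite rigid-body / Lagrangian form) and
integrated with a fixed-step semi-implicit Euler scheme, which is symplectic
and stable with the stiff Hunt–Crossley foot-ground contact used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NQ = 9
N_INTERNAL = 6
#: index of each generalized coordinate
Q_LABELS = (
    "pelvis_x", "pelvis_y", "pelvis_pitch",
    "hip_R", "knee_R", "ankle_R", "hip_L", "knee_L", "ankle_L",
)
JOINT_LABELS = Q_LABELS[3:]


class SimulationDiverged(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(f"simulation diverged: non-finite state at t = {time:.4f} s")


@dataclass(frozen=True)
class SegmentParams:
    """Inertial and geometric parameters of one rigid segment (SI units)."""

    name: str
    mass: float          # kg
    length: float        # m
    com_offset: float    # m, proximal joint -> COM along the segment axis
    inertia: float       # kg m^2 about the COM, out-of-plane axis

    def __post_init__(self):
        if not (self.mass > 0 and self.length > 0 and self.inertia > 0):
            raise ValueError(f"segment {self.name}: mass/length/inertia must be positive")
        if not (0.0 <= self.com_offset <= self.length):
            raise ValueError(f"segment {self.name}: com_offset outside [0, length]")


@dataclass(frozen=True)
class ContactConfig:
    """Compliant foot-ground contact: two point contacts (heel, toe) per foot.

    Normal force follows a Hunt-Crossley law k*d^1.5*(1 + c*ddot), clamped at
    zero; friction is Coulomb with a tanh velocity regularization bounded by
    mu * normal.
    """

    heel_offset: tuple[float, float] = (-0.07, -0.07)  # m, foot frame (fwd, up) from ankle
    toe_offset: tuple[float, float] = (0.18, -0.07)
    normal_stiffness: float = 8.0e4   # N / m^1.5
    dissipation: float = 1.0          # s / m
    friction_mu: float = 0.9
    friction_vel_smoothing: float = 0.05  # m/s
    enabled: bool = True

    def __post_init__(self):
        if self.normal_stiffness <= 0:
            raise ValueError("normal_stiffness must be positive")
        if not (0.0 < self.friction_mu <= 2.0):
            raise ValueError("friction_mu must be in (0, 2]")
        if self.heel_offset[0] >= self.toe_offset[0]:
            raise ValueError("heel contact must be posterior to toe contact")


def _default_segments() -> tuple[SegmentParams, ...]:
    # ~1.80 m / 75 kg adult; HAT carries ~53% of body mass.
    hat = SegmentParams("HAT", mass=39.75, length=0.80, com_offset=0.30, inertia=4.0)
    thigh = dict(mass=11.55, length=0.44, com_offset=0.19, inertia=0.233)
    shank = dict(mass=4.65, length=0.43, com_offset=0.19, inertia=0.078)
    foot = dict(mass=1.425, length=0.25, com_offset=0.06, inertia=0.020)
    return (
        hat,
        SegmentParams("thigh_R", **thigh), SegmentParams("shank_R", **shank),
        SegmentParams("foot_R", **foot),
        SegmentParams("thigh_L", **thigh), SegmentParams("shank_L", **shank),
        SegmentParams("foot_L", **foot),
    )


#: physiological ranges (rad) for the 6 internal DOF, flexion/dorsiflexion positive
DEFAULT_JOINT_LIMITS = {
    "hip": (np.deg2rad(-30.0), np.deg2rad(120.0)),
    "knee": (0.0, np.deg2rad(120.0)),      # hyperextension stop at 0
    "ankle": (np.deg2rad(-60.0), np.deg2rad(40.0)),
}


@dataclass(frozen=True)
class SkeletonConfig:
    """Full plant description: 7 segments, joint limits, gravity."""

    segments: tuple[SegmentParams, ...] = field(default_factory=_default_segments)
    joint_limits: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(
            DEFAULT_JOINT_LIMITS[j] for j in ("hip", "knee", "ankle") * 2
        )
    )
    joint_limit_stiffness: float = 300.0  # N m / rad beyond the range
    joint_limit_damping: float = 3.0      # N m s / rad, active only in violation
    gravity: float = 9.81                 # m/s^2, downward

    def __post_init__(self):
        if len(self.segments) != 7:
            raise ValueError("exactly 7 segments required (HAT + 2x thigh/shank/foot)")
        if len(self.joint_limits) != N_INTERNAL:
            raise ValueError("exactly 6 internal joint limit pairs required")
        for lo, hi in self.joint_limits:
            if not lo < hi:
                raise ValueError("joint limit min must be below max")

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments)


@dataclass
class SystemState:
    """Generalized coordinates/velocities plus muscle activations."""

    q: np.ndarray                 # (9,)
    qdot: np.ndarray              # (9,)
    activations: np.ndarray       # (18,) in [0, 1]
    time: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(self.q.copy(), self.qdot.copy(),
                           self.activations.copy(), self.time)

    def validate(self):
        if self.q.shape != (NQ,) or self.qdot.shape != (NQ,):
            raise ValueError("q and qdot must be 9-vectors")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise SimulationDiverged(self.time)
        if np.any(self.activations < -1e-12) or np.any(self.activations > 1 + 1e-12):
            raise ValueError("activations must lie in [0, 1]")


@dataclass
class GroundReaction:
    """Per-point and per-foot ground reaction forces (N) and positions (m)."""

    normal: np.ndarray       # (4,) heel_R, toe_R, heel_L, toe_L
    tangential: np.ndarray   # (4,)
    position: np.ndarray     # (4, 2)
    right_vertical: float = 0.0
    right_horizontal: float = 0.0
    left_vertical: float = 0.0
    left_horizontal: float = 0.0

    @classmethod
    def zero(cls) -> "GroundReaction":
        return cls(np.zeros(4), np.zeros(4), np.zeros((4, 2)))


# ---------------------------------------------------------------------------
# Kinematic structure tables
#
# Seven absolute segment orientations, each a linear combination of q:
#   0 HAT = -pitch
#   1 thigh_R = -pitch + hip_R          4 thigh_L = -pitch + hip_L
#   2 shank_R = -pitch + hip_R - knee_R 5 shank_L = ...
#   3 foot_R  = shank_R + ankle_R       6 foot_L = ...
# A segment axis at angle 0 hangs straight down (legs) or points straight up
# (HAT); feet use a forward-pointing frame so angle 0 is a flat foot.
# ---------------------------------------------------------------------------

def _angle_matrix() -> np.ndarray:
    # Absolute angles are CCW-positive in the x-forward/y-up plane.  Anterior
    # pelvis tilt is clockwise there, hence the -1 on pelvis_pitch; flexion of
    # a downward-hanging segment is CCW, so hip flexion enters with +1.
    A = np.zeros((7, NQ))
    A[0, 2] = -1.0
    for ang0, hip, knee, ankle in ((1, 3, 4, 5), (4, 6, 7, 8)):
        A[ang0, 2] = -1.0
        A[ang0, hip] = 1.0
        A[ang0 + 1] = A[ang0]
        A[ang0 + 1, knee] = -1.0
        A[ang0 + 2] = A[ang0 + 1]
        A[ang0 + 2, ankle] = 1.0
    return A


def _rot(phi: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Rotate local vectors r (n,2) by angles phi (n,)."""
    c, s = np.cos(phi), np.sin(phi)
    return np.stack([c * r[:, 0] - s * r[:, 1], s * r[:, 0] + c * r[:, 1]], axis=1)


class SkeletonModel:
    """Precompiled dynamics of a :class:`SkeletonConfig` + :class:`ContactConfig`."""

    def __init__(self, config: SkeletonConfig | None = None,
                 contact: ContactConfig | None = None,
                 locked_dofs: tuple[int, ...] = ()):
        self.config = config or SkeletonConfig()
        self.contact = contact or ContactConfig()
        self.locked_dofs = tuple(locked_dofs)
        self._free = np.array([i for i in range(NQ) if i not in self.locked_dofs])
        segs = self.config.segments
        hat, thR, shR, ftR, thL, shL, ftL = segs
        self.ANG = _angle_matrix()

        def leg_terms(ang0, th, sh, ft):
            # (body-local term tables) body order: thigh, shank, foot
            return [
                # thigh COM
                [(ang0, (0.0, -th.com_offset))],
                # shank COM = knee + shank offset
                [(ang0, (0.0, -th.length)), (ang0 + 1, (0.0, -sh.com_offset))],
                # foot COM: forward frame, COM slightly forward of and below ankle
                [(ang0, (0.0, -th.length)), (ang0 + 1, (0.0, -sh.length)),
                 (ang0 + 2, (ft.com_offset, -0.03))],
            ]

        body_terms = [[(0, (0.0, hat.com_offset))]]
        body_terms += leg_terms(1, thR, shR, ftR)
        body_terms += leg_terms(4, thL, shL, ftL)

        tb, ta, tr = [], [], []
        for b, terms in enumerate(body_terms):
            for ang, r in terms:
                tb.append(b)
                ta.append(ang)
                tr.append(r)
        self._tb = np.array(tb)
        self._ta = np.array(ta)
        self._tr = np.array(tr, dtype=float)

        cc = self.contact
        pt_terms = []
        for ang0, th, sh in ((1, thR, shR), (4, thL, shL)):
            for off in (cc.heel_offset, cc.toe_offset):
                pt_terms.append([(ang0, (0.0, -th.length)),
                                 (ang0 + 1, (0.0, -sh.length)),
                                 (ang0 + 2, off)])
        pb, pa, pr = [], [], []
        for p, terms in enumerate(pt_terms):
            for ang, r in terms:
                pb.append(p)
                pa.append(ang)
                pr.append(r)
        self._pb = np.array(pb)
        self._pa = np.array(pa)
        self._pr = np.array(pr, dtype=float)

        self.masses = np.array([s.mass for s in segs])
        # rotational inertia contributes a constant term: each body spins at the
        # rate of its own absolute angle, a fixed linear function of qdot
        inertias = np.array([s.inertia for s in segs])
        self._M_rot = self.ANG.T @ (inertias[:, None] * self.ANG)
        self._jl_lo = np.array([lo for lo, _ in self.config.joint_limits])
        self._jl_hi = np.array([hi for _, hi in self.config.joint_limits])

    # -- kinematics -------------------------------------------------------

    def body_kinematics(self, q: np.ndarray, qdot: np.ndarray):
        """COM positions (7,2), Jacobians (7,2,9) and velocity-product
        accelerations (7,2) of all segments."""
        phi = self.ANG @ q
        phidot = self.ANG @ qdot
        Rr = _rot(phi[self._ta], self._tr)          # rotated term vectors
        perp = np.stack([-Rr[:, 1], Rr[:, 0]], axis=1)  # d/dphi of Rr

        p = np.zeros((7, 2))
        p[:, 0] = q[0]
        p[:, 1] = q[1]
        np.add.at(p, self._tb, Rr)

        J = np.zeros((7, 2, NQ))
        J[:, 0, 0] = 1.0
        J[:, 1, 1] = 1.0
        contrib = perp[:, :, None] * self.ANG[self._ta][:, None, :]
        np.add.at(J, self._tb, contrib)

        avp = np.zeros((7, 2))
        np.add.at(avp, self._tb, -Rr * (phidot[self._ta] ** 2)[:, None])
        return p, J, avp

    def contact_kinematics(self, q: np.ndarray, qdot: np.ndarray):
        """Positions (4,2), velocities (4,2) and Jacobians (4,2,9) of the four
        foot contact points (heel_R, toe_R, heel_L, toe_L)."""
        phi = self.ANG @ q
        Rr = _rot(phi[self._pa], self._pr)
        perp = np.stack([-Rr[:, 1], Rr[:, 0]], axis=1)

        p = np.zeros((4, 2))
        p[:, 0] = q[0]
        p[:, 1] = q[1]
        np.add.at(p, self._pb, Rr)

        J = np.zeros((4, 2, NQ))
        J[:, 0, 0] = 1.0
        J[:, 1, 1] = 1.0
        contrib = perp[:, :, None] * self.ANG[self._pa][:, None, :]
        np.add.at(J, self._pb, contrib)
        v = J @ qdot
        return p, v, J

    # -- forces -----------------------------------------------------------

    def compute_contact(self, state: SystemState) -> GroundReaction:
        """Ground reaction at the four contact points for the current state."""
        if not self.contact.enabled:
            return GroundReaction.zero()
        p, v, _ = self.contact_kinematics(state.q, state.qdot)
        return self._contact_forces(p, v)

    def _contact_forces(self, p: np.ndarray, v: np.ndarray) -> GroundReaction:
        cc = self.contact
        depth = -p[:, 1]
        ddot = -v[:, 1]
        pen = depth > 0.0
        normal = np.zeros(4)
        normal[pen] = (cc.normal_stiffness * depth[pen] ** 1.5
                       * (1.0 + cc.dissipation * ddot[pen]))
        np.maximum(normal, 0.0, out=normal)
        tangential = -cc.friction_mu * normal * np.tanh(
            v[:, 0] / cc.friction_vel_smoothing)
        gr = GroundReaction(normal, tangential, p.copy())
        gr.right_vertical = float(normal[0] + normal[1])
        gr.right_horizontal = float(tangential[0] + tangential[1])
        gr.left_vertical = float(normal[2] + normal[3])
        gr.left_horizontal = float(tangential[2] + tangential[3])
        return gr

    def joint_limit_torques(self, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
        """Penalty torque on the 6 internal DOF outside physiological range."""
        qj = q[3:]
        qjd = qdot[3:]
        over = np.maximum(qj - self._jl_hi, 0.0)
        under = np.maximum(self._jl_lo - qj, 0.0)
        tau = -self.config.joint_limit_stiffness * over \
            + self.config.joint_limit_stiffness * under
        viol = (over > 0) | (under > 0)
        tau -= self.config.joint_limit_damping * qjd * viol
        return tau

    def _assemble(self, q: np.ndarray, qdot: np.ndarray,
                  joint_torques: np.ndarray):
        """Mass matrix, generalized force, contact-damping Jacobian, GRF."""
        p, J, avp = self.body_kinematics(q, qdot)
        M = np.einsum("b,bij,bik->jk", self.masses, J, J) + self._M_rot
        bias = np.einsum("b,bij,bi->j", self.masses, J, avp)
        Q = np.zeros(NQ)
        Q -= self.config.gravity * (self.masses @ J[:, 1, :])
        Q[3:] += joint_torques + self.joint_limit_torques(q, qdot)

        D = np.zeros((NQ, NQ))
        qj, qjd = q[3:], qdot[3:]
        viol = ((qj > self._jl_hi) | (qj < self._jl_lo))
        if viol.any():
            d = -self.config.joint_limit_damping * viol
            D[3:, 3:][np.diag_indices(N_INTERNAL)] += d

        if self.contact.enabled:
            pc, vc, Jc = self.contact_kinematics(q, qdot)
            gr = self._contact_forces(pc, vc)
            F = np.stack([gr.tangential, gr.normal], axis=1)
            Q += np.einsum("pij,pi->j", Jc, F)
            # force-velocity Jacobian of the contact law (both terms are
            # dissipative, hence negative semi-definite); treating it
            # implicitly keeps the 1 ms integrator stable even where the
            # regularized friction is much stiffer than 2m/h
            cc = self.contact
            depth = -pc[:, 1]
            pen = (depth > 0) & (gr.normal > 0)
            kd = np.where(pen, cc.normal_stiffness * np.clip(depth, 0, None) ** 1.5, 0.0)
            th = np.tanh(vc[:, 0] / cc.friction_vel_smoothing)
            dfx = -cc.friction_mu * gr.normal * (1 - th ** 2) / cc.friction_vel_smoothing
            dfy = -kd * cc.dissipation
            dF = np.stack([dfx, dfy], axis=1)          # (4, 2) diagonal blocks
            D += np.einsum("pij,pi,pik->jk", Jc, dF, Jc)
        else:
            gr = GroundReaction.zero()

        return M, Q - bias, D, gr

    def _solve(self, A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        qddot = np.zeros(NQ)
        if len(self._free) == NQ:
            qddot[:] = np.linalg.solve(A, rhs)
        else:
            f = self._free
            qddot[f] = np.linalg.solve(A[np.ix_(f, f)], rhs[f])
        return qddot

    def dynamics(self, q: np.ndarray, qdot: np.ndarray,
                 joint_torques: np.ndarray):
        """Return (qddot, GroundReaction) for the instantaneous state."""
        M, rhs, _, gr = self._assemble(q, qdot, joint_torques)
        return self._solve(M, rhs), gr

    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        _, J, _ = self.body_kinematics(q, np.zeros(NQ))
        return np.einsum("b,bij,bik->jk", self.masses, J, J) + self._M_rot

    # -- integration ------------------------------------------------------

    def step(self, state: SystemState, joint_torques: np.ndarray,
             h: float) -> tuple[SystemState, GroundReaction]:
        """Advance the mechanical state by one semi-implicit Euler substep."""
        if h <= 0:
            raise ValueError("step size h must be positive")
        M, rhs, D, gr = self._assemble(state.q, state.qdot, joint_torques)
        qddot = self._solve(M - h * D, rhs)
        qdot = state.qdot + h * qddot
        q = state.q + h * qdot
        t = state.time + h
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qdot))):
            raise SimulationDiverged(t)
        return SystemState(q, qdot, state.activations, t), gr

    # -- instrumentation --------------------------------------------------

    def total_mechanical_energy(self, state: SystemState,
                                datum: float = 0.0) -> float:
        """Kinetic + gravitational potential energy (J) of all 7 segments."""
        p, J, _ = self.body_kinematics(state.q, state.qdot)
        v = J @ state.qdot
        phidot = self.ANG @ state.qdot
        inertias = np.array([s.inertia for s in self.config.segments])
        ke = 0.5 * float(self.masses @ np.sum(v * v, axis=1)
                         + inertias @ phidot ** 2)
        pe = float(self.config.gravity * self.masses @ (p[:, 1] - datum))
        return ke + pe


def forward_dynamics_step(state: SystemState, joint_torques: np.ndarray,
                          model: SkeletonModel, h: float) -> SystemState:
    """Functional wrapper around :meth:`SkeletonModel.step`."""
    new, _ = model.step(state, np.asarray(joint_torques, dtype=float), h)
    return new


def compute_contact(state: SystemState, model: SkeletonModel) -> GroundReaction:
    return model.compute_contact(state)


def total_mechanical_energy(state: SystemState, model: SkeletonModel,
                            datum: float = 0.0) -> float:
    return model.total_mechanical_energy(state, datum)


def standing_pose(model: SkeletonModel, pelvis_height: float | None = None,
                  n_muscles: int = 18) -> SystemState:
    """Upright double-support pose with straight legs and flat feet."""
    segs = model.config.segments
    leg = segs[1].length + segs[2].length
    ankle_h = -min(model.contact.heel_offset[1], model.contact.toe_offset[1])
    if pelvis_height is None:
        pelvis_height = leg + ankle_h
    q = np.zeros(NQ)
    q[1] = pelvis_height
    return SystemState(q, np.zeros(NQ), np.zeros(n_muscles))


def solve_static_equilibrium(model: SkeletonModel) -> SystemState:
    """Root-solve a symmetric double-support standing equilibrium.

    Unknowns are pelvis height and a common ankle angle; by left/right
    symmetry the remaining accelerations vanish when the vertical force and
    the ankle moment balance.
    """
    from scipy.optimize import fsolve

    base = standing_pose(model)

    def residual(x):
        st = base.copy()
        st.q[1] = x[0]
        st.q[5] = st.q[8] = x[1]
        qddot, _ = model.dynamics(st.q, st.qdot, np.zeros(N_INTERNAL))
        return [qddot[1], qddot[5]]

    x0 = [base.q[1] - 0.02, 0.0]
    sol = fsolve(residual, x0, full_output=False, xtol=1e-12)
    st = base.copy()
    st.q[1] = sol[0]
    st.q[5] = st.q[8] = sol[1]
    return st


def free_config(contact_enabled: bool = False,
                joint_limits: bool = False) -> tuple[SkeletonConfig, ContactConfig]:
    """Config variant for conservative-limit tests (no contact/limits)."""
    sk = SkeletonConfig()
    if not joint_limits:
        sk = replace(sk, joint_limit_stiffness=0.0, joint_limit_damping=0.0)
    ct = ContactConfig(enabled=contact_enabled)
    return sk, ct
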