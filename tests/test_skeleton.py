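"""Rigid-body dynamics: conservation, oracles, contact and symmetry."""

import dataclasses

import numpy as np
import pytest

from neurogait import skeleton as sk
from neurogait.skeleton import (ContactConfig, SegmentParams, SimulationDiverged,
                                SkeletonConfig, SkeletonModel, SystemState,
                                solve_static_equilibrium, standing_pose)


def _pendulum_state(m):
    s = standing_pose(m)
    s.q[3], s.q[6], s.q[5] = 0.6, -0.4, 0.2
    return s


class TestStructure:
    def test_default_model_has_7_segments_9_dof(self, model):
        assert len(model.config.segments) == 7
        assert model.ANG.shape == (7, sk.NQ)
        assert sk.NQ == 9
        assert len(model.config.joint_limits) == sk.N_INTERNAL == 6

    def test_segment_invariants_enforced(self):
        with pytest.raises(ValueError):
            SegmentParams("bad", mass=-1.0, length=0.4, com_offset=0.2, inertia=0.1)
        with pytest.raises(ValueError):
            SegmentParams("bad", mass=1.0, length=0.4, com_offset=0.5, inertia=0.1)

    def test_contact_geometry_invariant(self):
        with pytest.raises(ValueError):
            ContactConfig(heel_offset=(0.2, -0.07), toe_offset=(0.1, -0.07))


class TestMassMatrix:
    def test_symmetry_and_positive_definiteness(self, model, rng):
        for _ in range(100):
            q = rng.normal(0.0, 0.6, sk.NQ)
            M = model.mass_matrix(q)
            assert np.allclose(M, M.T, atol=1e-12)
            assert np.linalg.eigvalsh(M).min() > 0.0

    def test_lagrangian_finite_difference_oracle(self, free_model, rng):
        """The assembled EOM satisfy d/dt(dL/dqdot) - dL/dq = 0 for the
        unforced conservative model, checked by nested finite differences of
        the Lagrangian (an independent route to the dynamics)."""
        m = free_model
        inertias = np.array([s.inertia for s in m.config.segments])

        def lagrangian(q, qdot):
            p, J, _ = m.body_kinematics(q, qdot)
            v = J @ qdot
            phidot = m.ANG @ qdot
            T = 0.5 * (m.masses @ np.sum(v * v, axis=1) + inertias @ phidot ** 2)
            V = m.config.gravity * m.masses @ p[:, 1]
            return T - V

        def grad(f, x, eps):
            out = np.zeros(len(x))
            for i in range(len(x)):
                d = np.zeros(len(x))
                d[i] = eps
                out[i] = (f(x + d) - f(x - d)) / (2 * eps)
            return out

        q = rng.normal(0.0, 0.5, sk.NQ)
        qdot = rng.normal(0.0, 1.0, sk.NQ)
        qddot, _ = m.dynamics(q, qdot, np.zeros(6))
        eps, h = 1e-6, 1e-6
        p_plus = grad(lambda v: lagrangian(q + h * qdot, v), qdot + h * qddot, eps)
        p_minus = grad(lambda v: lagrangian(q - h * qdot, v), qdot - h * qddot, eps)
        resid = (p_plus - p_minus) / (2 * h) - grad(
            lambda x: lagrangian(x, qdot), q, eps)
        scale = max(1.0, np.max(np.abs(m.masses)) * m.config.gravity)
        assert np.max(np.abs(resid)) / scale < 1e-3


class TestConservation:
    def test_passive_pendulum_energy_drift(self):
        """Suspended conservative model (base locked, no contact/limits):
        energy drift below 0.1% over 5 s at h = 1e-4 s."""
        m = SkeletonModel(*sk.free_config(), locked_dofs=(0, 1, 2))
        s = _pendulum_state(m)
        e0 = m.total_mechanical_energy(s)
        for _ in range(50000):
            s, _ = m.step(s, np.zeros(6), 1e-4)
        e1 = m.total_mechanical_energy(s)
        assert abs(e1 - e0) / abs(e0) < 1e-3

    def test_free_fall_matches_ballistic_solution(self, free_model):
        """Doubled gravity, no contact: pelvis_y follows y0 - g t^2 within
        the first-order integrator tolerance."""
        cfg = dataclasses.replace(free_model.config, gravity=2 * 9.81)
        m = SkeletonModel(cfg, free_model.contact)
        s = standing_pose(m)
        y0 = s.q[1]
        h, n = 1e-3, 1000
        for _ in range(n):
            s, _ = m.step(s, np.zeros(6), h)
        t = n * h
        expected = y0 - 0.5 * (2 * 9.81) * t ** 2
        assert abs(s.q[1] - expected) <= 2 * 9.81 * h * t  # O(h) bound

    def test_rigid_translation_kinetic_energy(self, free_model):
        s = standing_pose(free_model)
        v = 1.7
        s.qdot[0] = v
        ke = free_model.total_mechanical_energy(s) - free_model.total_mechanical_energy(
            SystemState(s.q.copy(), np.zeros(sk.NQ), s.activations))
        assert ke == pytest.approx(0.5 * free_model.config.total_mass * v ** 2,
                                   rel=1e-12)

    def test_potential_energy_per_segment_hand_sum(self, free_model):
        """Zero velocity: energy equals an independent per-segment m*g*h sum."""
        s = _pendulum_state(free_model)
        p, _, _ = free_model.body_kinematics(s.q, s.qdot)
        hand = sum(seg.mass * free_model.config.gravity * p[i, 1]
                   for i, seg in enumerate(free_model.config.segments))
        assert free_model.total_mechanical_energy(s) == pytest.approx(hand, rel=1e-12)

    def test_energy_non_negative_above_datum(self, free_model):
        s = _pendulum_state(free_model)
        datum = float(min(free_model.body_kinematics(s.q, s.qdot)[0][:, 1])) - 1.0
        assert free_model.total_mechanical_energy(s, datum=datum) > 0.0


class TestContact:
    def test_airborne_feet_zero_force(self, model):
        s = standing_pose(model)
        s.q[1] += 0.5
        gr = model.compute_contact(s)
        assert np.all(gr.normal == 0.0) and np.all(gr.tangential == 0.0)

    def test_static_stance_grf_balances_weight(self, model):
        """At the root-solved standing equilibrium the summed vertical GRF
        equals body weight within 1%."""
        eq = solve_static_equilibrium(model)
        gr = model.compute_contact(eq)
        weight = model.config.total_mass * model.config.gravity
        total = gr.right_vertical + gr.left_vertical
        assert total == pytest.approx(weight, rel=0.01)

    def test_equilibrium_holds_for_one_second(self, model):
        eq = solve_static_equilibrium(model)
        s = eq.copy()
        for _ in range(1000):
            s, _ = model.step(s, np.zeros(6), 1e-3)
        assert np.linalg.norm(s.qdot) < 1e-3

    def test_sliding_friction_saturates_at_mu_normal(self, model):
        s = solve_static_equilibrium(model)
        s.qdot[0] = 2.0  # fast forward slide
        gr = model.compute_contact(s)
        mu = model.contact.friction_mu
        loaded = gr.normal > 0
        ratio = np.abs(gr.tangential[loaded]) / (mu * gr.normal[loaded])
        assert np.all(ratio > 0.99) and np.all(ratio <= 1.0)

    def test_normal_force_never_negative_on_trajectory(self, model, rng):
        s = standing_pose(model)
        s.qdot[0] = 1.0
        for i in range(300):
            tau = rng.normal(0.0, 20.0, 6)
            s, gr = model.step(s, tau, 1e-3)
            assert np.all(gr.normal >= 0.0)


class TestSymmetry:
    def test_leg_swap_symmetry(self, model, rng):
        """Swapping left/right joint states and torques swaps the resulting
        accelerations (legs are attached identically at the pelvis)."""
        q = rng.normal(0.0, 0.4, sk.NQ)
        qdot = rng.normal(0.0, 0.5, sk.NQ)
        tau = rng.normal(0.0, 30.0, 6)

        def swap9(x):
            y = x.copy()
            y[3:6], y[6:9] = x[6:9].copy(), x[3:6].copy()
            return y

        a1, _ = model.dynamics(q, qdot, tau)
        a2, _ = model.dynamics(swap9(q), swap9(qdot),
                               np.concatenate([tau[3:], tau[:3]]))
        assert np.allclose(swap9(a1), a2, atol=1e-9)

    def test_sagittal_mirror_symmetry(self, rng):
        """Reversing the walking direction (negate all angles and horizontal
        velocity) mirrors the accelerations up to sign.  Exact only when the
        segment geometry is itself fore-aft symmetric, so the feet use a
        centered COM here; contact and limits off (airborne limit)."""
        segs = list(SkeletonConfig().segments)
        for i in (3, 6):
            segs[i] = dataclasses.replace(segs[i], com_offset=0.0)
        cfg = dataclasses.replace(SkeletonConfig(), segments=tuple(segs),
                                  joint_limit_stiffness=0.0,
                                  joint_limit_damping=0.0)
        m = SkeletonModel(cfg, ContactConfig(enabled=False))
        q = rng.normal(0.0, 0.4, sk.NQ)
        qdot = rng.normal(0.0, 0.5, sk.NQ)
        tau = rng.normal(0.0, 30.0, 6)
        mirror = np.array([-1, 1] + [-1] * 7, dtype=float)
        a1, _ = m.dynamics(q, qdot, tau)
        a2, _ = m.dynamics(mirror * q, mirror * qdot, -tau)
        assert np.allclose(mirror * a1, a2, atol=1e-9)


class TestStepContract:
    def test_divergence_raises_with_time(self, model):
        s = standing_pose(model)
        s.qdot[:] = 1e160
        with pytest.raises(SimulationDiverged) as err:
            model.step(s, np.zeros(6), 1e-3)
        assert err.value.time > 0

    def test_nonpositive_step_rejected(self, model):
        with pytest.raises(ValueError):
            model.step(standing_pose(model), np.zeros(6), 0.0)

    def test_joint_limit_penalty_restoring(self, free_model):
        cfg = SkeletonConfig()  # limits enabled
        m = SkeletonModel(cfg, ContactConfig(enabled=False))
        q = np.zeros(sk.NQ)
        q[4] = np.deg2rad(130.0)  # knee beyond flexion stop
        tau = m.joint_limit_torques(q, np.zeros(sk.NQ))
        assert tau[1] < 0.0
        q[4] = np.deg2rad(-5.0)   # hyperextension
        tau = m.joint_limit_torques(q, np.zeros(sk.NQ))
        assert tau[1] > 0.0
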