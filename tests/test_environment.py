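"""MDP environment: reward accounting, termination, footstep detection."""

import dataclasses

import numpy as np
import pytest

from neurogait.controller import ControllerParams
from neurogait.environment import (DT, EpisodeDone, FALL_HEIGHT,
                                   InitialStateParams, InvalidInitialState,
                                   RewardWeights, WalkingEnv,
                                   detect_footsteps, episode_reward,
                                   footstep_reward, initial_contacts,
                                   load_trace, rollout, save_trace)
from neurogait.fixtures import SyntheticTraceSpec, handbook_footstep, make_trace


@pytest.fixture()
def env():
    return WalkingEnv(horizon=2.0, v_tgt=1.3)


class TestRewardFunction:
    def test_handbook_footstep_components(self):
        """50 steps at v=1.2 against v_tgt=1.45, tilt 0.1, excitations 0.2:
        r_steps=0.5, J_vel=0.125, J_pel=0.005, J_mul=0.36, total -2.96."""
        fs = handbook_footstep()
        total, comps = footstep_reward(fs, RewardWeights(), v_tgt=1.45)
        assert comps["r_steps"] == pytest.approx(0.5, abs=1e-12)
        assert comps["J_vel"] == pytest.approx(0.125, abs=1e-12)
        assert comps["J_pel"] == pytest.approx(0.005, abs=1e-12)
        assert comps["J_mul"] == pytest.approx(0.36, abs=1e-12)
        assert total == pytest.approx(-2.96, abs=1e-12)

    def test_default_weights(self):
        w = RewardWeights()
        assert (w.w_steps, w.w_vel, w.w_pel, w.w_mul) == (10.0, 60.0, 20.0, 1.0)
        with pytest.raises(ValueError):
            RewardWeights(w_vel=-1.0)

    def test_exact_tracking_zeroes_velocity_cost(self):
        fs = handbook_footstep(v_pel=1.45)
        _, comps = footstep_reward(fs, RewardWeights(), v_tgt=1.45)
        assert comps["J_vel"] == 0.0

    def test_zero_excitations_zero_effort(self):
        fs = handbook_footstep(excitation=0.0)
        _, comps = footstep_reward(fs, RewardWeights(), v_tgt=1.45)
        assert comps["J_mul"] == 0.0

    def test_no_velocity_cost_when_target_absent(self):
        fs = handbook_footstep()
        t_with, _ = footstep_reward(fs, RewardWeights(), v_tgt=1.45)
        t_without, comps = footstep_reward(fs, RewardWeights(), v_tgt=None)
        assert comps["J_vel"] == 0.0
        assert t_without > t_with

    def test_doubling_step_weight_doubles_step_component_only(self):
        fs = handbook_footstep()
        w1 = RewardWeights()
        w2 = RewardWeights(w_steps=20.0)
        t1, c = footstep_reward(fs, w1, 1.45)
        t2, _ = footstep_reward(fs, w2, 1.45)
        assert t2 - t1 == pytest.approx(10.0 * c["r_steps"], abs=1e-12)

    def test_reward_monotone_in_effort_and_speed_error(self, rng):
        base, _ = footstep_reward(handbook_footstep(), RewardWeights(), 1.45)
        worse_e, _ = footstep_reward(handbook_footstep(excitation=0.3),
                                     RewardWeights(), 1.45)
        worse_v, _ = footstep_reward(handbook_footstep(v_pel=1.0),
                                     RewardWeights(), 1.45)
        assert worse_e < base and worse_v < base

    def test_episode_accounting_identity_on_synthetic_trace(self):
        """total = R_alive + sum of footstep rewards, exactly."""
        trace, gt = make_trace(SyntheticTraceSpec(), v_tgt=1.3)
        w = RewardWeights()
        total = episode_reward(trace, w, v_tgt=1.3)
        parts = gt.r_alive + sum(
            footstep_reward(fs, w, 1.3)[0] for fs in trace.footsteps)
        assert total == pytest.approx(parts, abs=1e-12)
        assert gt.r_alive == pytest.approx(DT * trace.n_steps, abs=1e-12)


class TestLifecycle:
    def test_reset_passes_initial_angles_through(self, env):
        init = InitialStateParams(hip_flexion_R=0.3, knee_flexion_L=0.2)
        env.reset(init)
        assert env.state.q[3] == 0.3
        assert env.state.q[7] == 0.2
        assert env.state.qdot[0] == init.forward_speed

    def test_nonsagittal_entries_are_noops(self, env):
        a = InitialStateParams(rightward_speed=0.0, hip_abduction_R=0.0)
        b = InitialStateParams(rightward_speed=0.4, hip_abduction_R=0.15,
                               hip_abduction_L=-0.1)
        env.reset(a)
        qa = env.state.q.copy()
        env.reset(b)
        assert np.array_equal(qa, env.state.q)

    def test_reset_determinism(self, env):
        o1 = env.reset(InitialStateParams())
        o2 = env.reset(InitialStateParams())
        assert np.array_equal(o1, o2)

    def test_low_pelvis_init_rejected(self, env):
        with pytest.raises(InvalidInitialState):
            env.reset(InitialStateParams(pelvis_height=0.55))

    def test_initial_state_vector_has_12_entries(self):
        v = InitialStateParams().to_array()
        assert v.shape == (12,)
        assert InitialStateParams.from_array(v) == InitialStateParams()
        with pytest.raises(ValueError):
            InitialStateParams.from_array(np.zeros(11))

    def test_fall_terminates_episode(self):
        """Dropping from the air, the episode ends the step pelvis_y crosses
        0.6 m."""
        env = WalkingEnv(horizon=5.0, v_tgt=None)
        env.reset(InitialStateParams(pelvis_height=0.7))
        done, steps = False, 0
        while not done:
            _, _, done, info = env.step(np.zeros(18))
            steps += 1
        assert env.state.q[1] < FALL_HEIGHT
        assert env.trace().terminated_early
        assert steps < 500

    def test_survival_reward_counts_executed_steps(self):
        env = WalkingEnv(horizon=0.5, v_tgt=None)
        env.reset(InitialStateParams(pelvis_height=0.94, hip_flexion_R=0.0,
                                     knee_flexion_R=0.0, hip_flexion_L=0.0,
                                     knee_flexion_L=0.0, trunk_lean=0.0,
                                     forward_speed=0.0))
        n, done = 0, False
        while not done:
            _, _, done, _ = env.step(np.full(18, 0.01))
            n += 1
        tr = env.trace()
        assert tr.reward_components["R_alive"] == pytest.approx(0.01 * n, abs=1e-12)

    def test_step_after_done_raises(self):
        env = WalkingEnv(horizon=0.02, v_tgt=None)
        env.reset(InitialStateParams())
        done = False
        while not done:
            _, _, done, _ = env.step(np.zeros(18))
        with pytest.raises(EpisodeDone):
            env.step(np.zeros(18))

    def test_zero_excitation_decays_activations(self, env):
        env.reset(InitialStateParams(), baseline_excitations=np.full(18, 0.6))
        prev = env.state.activations.copy()
        for _ in range(10):
            env.step(np.zeros(18))
            a = env.state.activations
            assert np.all(a <= prev + 1e-15)
            prev = a.copy()

    def test_invalid_action_rejected(self, env):
        env.reset(InitialStateParams())
        with pytest.raises(ValueError):
            env.step(np.full(18, 1.5))
        with pytest.raises(ValueError):
            env.step(np.zeros(17))


class TestFootstepDetection:
    def test_synthetic_alternating_waves(self):
        """Boundaries at each alternating rising crossing of the constructed
        square waves (direct threshold-crossing oracle)."""
        trace, gt = make_trace(SyntheticTraceSpec())
        steps = detect_footsteps(trace.grf[:, 0], trace.grf[:, 2])
        assert steps == gt.footsteps
        assert len(steps) > 5
        # perfectly periodic alternation: every footstep spans half a cycle
        assert {e - s for s, e, _ in steps} == {gt.footsteps[0][1]
                                                - gt.footsteps[0][0]}

    def test_one_foot_never_loaded_gives_no_footsteps(self):
        n = 500
        g_r = np.zeros(n)
        g_r[50:] = 400.0
        assert detect_footsteps(g_r, np.zeros(n)) == []

    def test_chatter_within_debounce_is_single_event(self):
        g = np.zeros(300)
        g[100:] = 400.0
        g[120] = 0.0          # 10 ms dip, below the 50 ms debounce
        g[121] = 400.0
        assert initial_contacts(g) == [100]

    def test_initially_loaded_foot_is_not_an_event(self):
        g = np.full(200, 400.0)
        assert initial_contacts(g) == []


class TestTraceIO:
    def test_csv_json_roundtrip(self, tmp_path):
        trace, _ = make_trace(SyntheticTraceSpec(duration=4.0))
        csv, js = tmp_path / "t.csv", tmp_path / "t.json"
        save_trace(trace, csv, js)
        back = load_trace(csv, js)
        assert np.allclose(back.q, trace.q)
        assert np.allclose(back.grf, trace.grf)
        assert np.allclose(back.excitations, trace.excitations)
        assert back.total_reward == trace.total_reward
        assert len(back.footsteps) == len(trace.footsteps)

    def test_rollout_reward_matches_episode_reward(self):
        """The online accumulator agrees with the offline reward recompute."""
        env = WalkingEnv(horizon=1.5, v_tgt=1.3)
        trace = rollout(ControllerParams(), InitialStateParams(), env)
        recomputed = episode_reward(trace, env.weights, env.v_tgt)
        assert trace.total_reward == pytest.approx(recomputed, abs=1e-9)


class TestVelocityCostForms:
    def test_per_step_form_penalizes_oscillation(self):
        """A speed oscillating symmetrically about the target is free under
        the integrated (distance) form but penalized per step."""
        from neurogait.environment import FootstepRecord
        n = 50
        v = np.where(np.arange(n) % 2 == 0, 1.2, 1.7)  # mean 1.45
        fs = FootstepRecord(0, n, n * DT, "R", v, np.zeros(n),
                            np.zeros((n, 18)))
        _, integrated = footstep_reward(fs, RewardWeights(), 1.45)
        _, per_step = footstep_reward(
            fs, RewardWeights(j_vel_per_step=True), 1.45)
        assert integrated["J_vel"] == pytest.approx(0.0, abs=1e-12)
        assert per_step["J_vel"] == pytest.approx(0.25 * n * DT, abs=1e-12)
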