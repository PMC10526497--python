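import numpy as np
import pytest

from depthsim import environment as env
from depthsim import transforms as tf
from depthsim._fast import FastAgent
from depthsim.agent import (
    AgentConfig,
    DepthAgent,
    Phase,
    PhaseSchedule,
    eye_angles,
    schedule_phase,
)


def noiseless_obs(world):
    rng = np.random.default_rng(0)  # unused: noise is zero
    return env.observe(
        world, env.FoveaNoiseModel(mode=env.FoveaMode.UNIFORM), rng
    )


class TestPredictRelative:
    def test_trivial_geometry(self):
        cfg = AgentConfig(L=0.0)
        agent = DepthAgent(cfg, np.array([2.0, 0.3]), np.zeros(2))
        for i in range(2):
            np.testing.assert_allclose(
                agent.predict_relative(i), [2.0, 0.3, 1.0]
            )

    def test_offset_eye(self):
        agent = DepthAgent(AgentConfig(L=0.5), np.array([2.0, 0.3]), np.zeros(2))
        np.testing.assert_allclose(agent.predict_relative(0), [2.0, -0.2, 1.0])
        np.testing.assert_allclose(agent.predict_relative(1), [2.0, 0.8, 1.0])

    def test_mirror_symmetry(self, rng):
        cfg = AgentConfig()
        for _ in range(10):
            pos = np.array([rng.uniform(2, 6), rng.uniform(-2, 2)])
            a = DepthAgent(cfg, pos, np.zeros(2))
            b = DepthAgent(cfg, pos * np.array([1, -1]), np.zeros(2))
            np.testing.assert_allclose(
                a.predict_relative(0),
                b.predict_relative(1) * np.array([1, -1, 1]),
                atol=1e-12,
            )

    def test_matches_eye_transform(self, rng):
        cfg = AgentConfig()
        ang = rng.uniform(-0.3, 0.3, 2)
        pos = np.array([3.0, 1.0])
        agent = DepthAgent(cfg, pos, ang)
        th = eye_angles(ang)
        for i, l in enumerate((cfg.L, -cfg.L)):
            T = tf.make_eye_transform(th[i], l)
            np.testing.assert_allclose(
                agent.predict_relative(i), T @ np.array([3.0, 1.0, 1.0])
            )


class TestPredictProjection:
    def test_on_axis(self):
        agent = DepthAgent(AgentConfig(L=0.0), np.array([2.0, 0.0]), np.zeros(2))
        for i in range(2):
            np.testing.assert_allclose(agent.predict_projection(i), [1.0, 0.0])

    def test_substitution(self):
        agent = DepthAgent(AgentConfig(), np.array([2.0, 0.5]), np.zeros(2))
        agent.mu_r[0].mu = np.array([2.0, 1.0, 1.0])
        agent.mu_r[1].mu = np.array([2.0, -1.0, 1.0])
        np.testing.assert_allclose(agent.predict_projection(0), [1.0, 0.5])
        np.testing.assert_allclose(agent.predict_projection(1), [1.0, -0.5])


class TestAttractor:
    def test_zero_at_center(self):
        agent = DepthAgent(AgentConfig(L=0.0), np.array([2.0, 0.0]), np.zeros(2))
        np.testing.assert_allclose(agent.attractor_fc(0), [0.0, 0.0])

    def test_pulls_toward_center(self):
        agent = DepthAgent(AgentConfig(lam=1.0), np.array([2.0, 0.5]), np.zeros(2))
        agent.mu_c[0].mu = np.array([1.0, 0.4])
        v = agent.attractor_fc(0, lam=1.0)
        assert np.linalg.norm(v) == pytest.approx(0.4)
        assert v[1] == pytest.approx(-0.4)  # drift toward c = 0

    def test_linear_in_gain(self):
        agent = DepthAgent(AgentConfig(), np.array([2.0, 0.5]), np.zeros(2))
        agent.mu_c[1].mu = np.array([1.0, -0.3])
        np.testing.assert_allclose(
            agent.attractor_fc(1, lam=2.0), 2 * agent.attractor_fc(1, lam=1.0)
        )


class TestSchedule:
    def test_start_phase(self):
        sched = PhaseSchedule(cycle_length=100)
        assert schedule_phase(0, sched) is Phase.PERCEPTION

    def test_alternation(self):
        sched = PhaseSchedule(cycle_length=100)
        assert schedule_phase(100, sched) is Phase.ACTION
        assert schedule_phase(199, sched) is Phase.ACTION
        assert schedule_phase(200, sched) is Phase.PERCEPTION

    def test_phase_counts_in_1000_steps(self):
        sched = PhaseSchedule(cycle_length=100)
        phases = [schedule_phase(t, sched) for t in range(1000)]
        assert phases.count(Phase.PERCEPTION) == 500
        assert phases.count(Phase.ACTION) == 500
        # exactly 5 contiguous blocks of each
        blocks = sum(
            1 for i in range(1, 1000) if phases[i] is not phases[i - 1]
        )
        assert blocks == 9

    def test_action_start(self):
        sched = PhaseSchedule(cycle_length=10, start=Phase.ACTION)
        assert schedule_phase(0, sched) is Phase.ACTION
        assert schedule_phase(10, sched) is Phase.PERCEPTION

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            schedule_phase(-1, PhaseSchedule())

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            PhaseSchedule(cycle_length=0)
        with pytest.raises(ValueError):
            PhaseSchedule(start=Phase.SIMULTANEOUS)


class TestFixedPoint:
    @pytest.mark.parametrize("phase", [Phase.PERCEPTION, Phase.ACTION])
    def test_true_state_is_stationary(self, phase):
        cfg = AgentConfig()
        target = np.array([3.5, -0.8])
        ang = env.fixation_angles(target, cfg.L)
        world = env.WorldState(
            target=target, eye_angles_true=ang, L=cfg.L, cam=cfg.camera
        )
        agent = DepthAgent(cfg, target, ang)
        obs = noiseless_obs(world)
        before = np.concatenate(
            [agent.mu_a.mu, agent.mu_theta.mu, agent.mu_r[0].mu, agent.mu_c[0].mu]
        )
        agent.step(obs.sp, list(obs.sv), phase, obs.sp_prime)
        after = np.concatenate(
            [agent.mu_a.mu, agent.mu_theta.mu, agent.mu_r[0].mu, agent.mu_c[0].mu]
        )
        assert np.abs(after - before).max() < 1e-12

    def test_frozen_absolute_belief_in_action_phase(self, rng):
        cfg = AgentConfig()
        agent = DepthAgent(cfg, np.array([3.0, 0.5]), np.zeros(2))
        mu0 = agent.mu_a.mu.copy()
        sv = [np.array([1.0, rng.uniform(-1, 1)]) for _ in range(2)]
        for _ in range(10):
            agent.step(np.zeros(2), sv, Phase.ACTION, np.zeros(2))
        np.testing.assert_array_equal(agent.mu_a.mu, mu0)

    def test_homogeneous_components_pinned(self, rng):
        cfg = AgentConfig()
        agent = DepthAgent(cfg, np.array([3.0, 0.5]), np.zeros(2))
        for t in range(50):
            sv = [np.array([1.0, rng.uniform(-1, 1)]) for _ in range(2)]
            agent.step(np.zeros(2), sv, Phase.PERCEPTION, np.zeros(2))
        assert agent.mu_a.mu[2] == 1.0
        assert agent.mu_r[0].mu[2] == 1.0
        assert agent.mu_c[0].mu[0] == 1.0


class TestPerceptionRuns:
    def run_perception(self, cfg, target, init, n_steps, collect_f=False):
        world = env.WorldState(
            target=target, eye_angles_true=np.zeros(2), L=cfg.L, cam=cfg.camera
        )
        agent = DepthAgent(cfg, init, np.zeros(2))
        fs = []
        for _ in range(n_steps):
            obs = noiseless_obs(world)
            agent.step(obs.sp, list(obs.sv), Phase.PERCEPTION, obs.sp_prime)
            if collect_f:
                fs.append(agent.free_energy)
        return agent, fs

    def test_free_energy_decreases_over_windows(self):
        cfg = AgentConfig()
        agent, fs = self.run_perception(
            cfg, np.array([4.0, 1.2]), np.array([2.5, 0.0]), 2000, collect_f=True
        )
        fs = np.array(fs)
        # Euler tolerance band: compare 50-step windows after the initial
        # transient; allow a tiny relative margin
        for t in range(100, len(fs) - 50, 50):
            assert fs[t + 50] <= fs[t] * 1.05 + 1e-9

    def test_mirrored_targets_give_mirrored_trajectories(self):
        cfg = AgentConfig()
        a, _ = self.run_perception(
            cfg, np.array([3.0, 1.4]), np.array([4.0, 0.0]), 500
        )
        b, _ = self.run_perception(
            cfg, np.array([3.0, -1.4]), np.array([4.0, 0.0]), 500
        )
        np.testing.assert_allclose(
            a.estimate(), b.estimate() * np.array([1, -1]), atol=1e-10
        )

    def test_dynamic_error_units_stay_stable(self, gentle_cfg):
        agent, fs = self.run_perception(
            gentle_cfg, np.array([3.0, 0.5]), np.array([4.0, 0.0]), 2000,
            collect_f=True,
        )
        assert np.all(np.isfinite(agent.mu_a.mu))
        assert fs[-1] < fs[10]


class TestFastPathEquivalence:
    """The scalar fast path must reproduce the reference step bit-for-bit
    (up to float associativity)."""

    def test_stepwise_match_across_phases(self, rng):
        cfg = AgentConfig()
        init_p = np.array([3.0, 0.4])
        init_a = np.array([0.05, -0.1])
        ref = DepthAgent(cfg, init_p, init_a)
        fast = FastAgent(cfg, init_p, init_a)
        for t in range(400):
            phase = [Phase.PERCEPTION, Phase.ACTION, Phase.SIMULTANEOUS][
                (t // 50) % 3
            ]
            sp = rng.uniform(-0.3, 0.3, 2)
            spp = rng.uniform(-0.5, 0.5, 2)
            sv = rng.uniform(-0.8, 0.8, 2)
            ref.step(
                sp, [np.array([1.0, sv[0]]), np.array([1.0, sv[1]])], phase, spp
            )
            fast.step(sp[0], sp[1], spp[0], spp[1], sv[0], sv[1], phase)
            assert ref.mu_a.mu[0] == pytest.approx(fast.ax, abs=1e-12)
            assert ref.mu_a.mu[1] == pytest.approx(fast.ay, abs=1e-12)
            assert ref.mu_theta.mu[0] == pytest.approx(fast.tha, abs=1e-12)
            assert ref.mu_theta.mu[1] == pytest.approx(fast.thv, abs=1e-12)
            for i in range(2):
                assert ref.mu_r[i].mu[0] == pytest.approx(fast.rx[i], abs=1e-12)
                assert ref.mu_r[i].mu[1] == pytest.approx(fast.ry[i], abs=1e-12)
                assert ref.mu_c[i].mu[1] == pytest.approx(fast.c[i], abs=1e-12)
            assert ref.action.a[0] == pytest.approx(fast.aa, abs=1e-12)
            assert ref.action.a[1] == pytest.approx(fast.av, abs=1e-12)
            assert ref.free_energy == pytest.approx(fast.free_energy, rel=1e-10)

    def test_fast_agent_requires_instantaneous(self):
        with pytest.raises(ValueError):
            FastAgent(
                AgentConfig(instantaneous_errors=False),
                np.array([3.0, 0.0]),
                np.zeros(2),
            )


class TestBlockMechanism:
    def test_zero_proprio_precision_blocks_action_in_perception(self, rng):
        from depthsim.agent import BlockMechanism

        cfg = AgentConfig(mechanism=BlockMechanism.ZERO_PROPRIO_PRECISION)
        agent = DepthAgent(cfg, np.array([3.0, 0.5]), np.zeros(2))
        a0 = agent.action.a.copy()
        for _ in range(20):
            sv = [np.array([1.0, rng.uniform(-1, 1)]) for _ in range(2)]
            agent.step(np.array([0.2, 0.1]), sv, Phase.PERCEPTION, np.zeros(2))
        # motor signal untouched and treated as zero
        np.testing.assert_array_equal(agent.action.a, a0)
        assert not agent.action.enabled or np.allclose(agent.action.effective(), 0)

    def test_mechanisms_agree_in_action_phase(self, rng):
        from depthsim.agent import BlockMechanism

        cfgs = [
            AgentConfig(mechanism=BlockMechanism.ZERO_ATTRACTOR_GAIN),
            AgentConfig(mechanism=BlockMechanism.ZERO_PROPRIO_PRECISION),
        ]
        agents = [DepthAgent(c, np.array([3.0, 0.5]), np.zeros(2)) for c in cfgs]
        for _ in range(10):
            sv = [np.array([1.0, rng.uniform(-1, 1)]) for _ in range(2)]
            for a in agents:
                a.step(np.array([0.1, 0.0]), [s.copy() for s in sv], Phase.ACTION, np.zeros(2))
        np.testing.assert_allclose(agents[0].mu_a.mu, agents[1].mu_a.mu)
        np.testing.assert_allclose(agents[0].action.a, agents[1].action.a)
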