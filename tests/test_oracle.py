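import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from imitatebci.effector import ChainModel, Goal, Joint, forward_kinematics
from imitatebci.oracle import (
    ChainOracleSpec,
    MismatchSpec,
    OracleAction,
    apply_arc_mismatch,
    apply_intention_noise,
    apply_linear_mismatch,
    arc_rotation,
    chain_oracle,
    cursor_oracle,
)


def cursor_goal(p):
    return Goal(kind="cursor_point", positions=np.asarray(p, float)[None, :])


class TestCursorOracle:
    def test_scaled_unit_direction(self):
        o = cursor_oracle(np.zeros(3), cursor_goal([2, 0, 0]), speed=0.1)
        assert np.allclose(o.velocity, [0.1, 0, 0])

    def test_zero_at_goal(self):
        o = cursor_oracle(np.ones(3), cursor_goal([1, 1, 1]), speed=0.5)
        assert np.allclose(o.velocity, 0)

    def test_equal_length_vectors_toward_target(self, rng):
        # beyond one step of the goal every oracle velocity has norm == speed
        speed = 0.5
        for _ in range(1000):
            p, g = rng.uniform(-10, 10, (2, 3))
            if np.linalg.norm(g - p) <= speed:
                continue
            o = cursor_oracle(p, cursor_goal(g), speed=speed)
            assert np.linalg.norm(o.velocity) == pytest.approx(speed)
            cos = np.dot(o.velocity, g - p) / (speed * np.linalg.norm(g - p))
            assert cos == pytest.approx(1.0)

    def test_no_overshoot_inside_one_step(self):
        o = cursor_oracle(np.zeros(3), cursor_goal([0.2, 0, 0]), speed=0.5)
        assert np.allclose(o.velocity, [0.2, 0, 0])

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            cursor_oracle(np.zeros(3), cursor_goal([1, 0, 0]), speed=0.0)


def two_link():
    z = np.array([0.0, 0.0, 1.0])
    return ChainModel(
        joints=(Joint(z, 1.0), Joint(z, 0.8)),
        markers={"wrist": (1, 0.8), "thumb_tip": (1, 0.6), "mid_tip": (1, 0.8)},
    )


class TestChainOracle:
    spec = ChainOracleSpec(mu=1e-4, omega_max=0.2, delta=0.3, goal_tol=0.05)

    def test_zero_when_grasp_complete(self):
        chain = two_link()
        angles = np.array([0.3, -0.2])
        m = forward_kinematics(chain, angles)
        goal = Goal(kind="wand", positions=np.stack([m["wrist"], m["thumb_tip"], m["mid_tip"]]))
        o = chain_oracle(chain, angles, goal, self.spec)
        assert np.allclose(o.velocity, 0)

    def test_single_joint_sign_matches_cost_gradient(self):
        # finite-difference of the squared marker error determines the sign
        chain = ChainModel(
            joints=(Joint(np.array([0, 0, 1.0]), 1.0),),
            markers={"wrist": (0, 1.0), "thumb_tip": (0, 1.0), "mid_tip": (0, 1.0)},
        )
        goal = Goal(kind="wand", positions=np.array([[np.cos(0.2), np.sin(0.2), 0.0]]))
        for theta in (0.0, 0.4, -0.3):
            o = chain_oracle(chain, np.array([theta]), goal, self.spec)

            def cost(a):
                tip = forward_kinematics(chain, [a])["wrist"]
                return np.sum((tip - goal.point) ** 2)

            fd = (cost(theta + 1e-6) - cost(theta - 1e-6)) / 2e-6
            if abs(fd) > 1e-9:
                assert np.sign(o.velocity[0]) == -np.sign(fd)

    def test_step_decreases_cost_from_random_poses(self, rng):
        chain = two_link()
        spec = ChainOracleSpec(mu=1e-6, omega_max=0.05, delta=1e-9, goal_tol=1e-3)
        for _ in range(10):
            angles = rng.uniform(-1.5, 1.5, 2)
            goal_pos = forward_kinematics(chain, rng.uniform(-1.5, 1.5, 2))["wrist"]
            goal = Goal(kind="wand", positions=goal_pos[None, :])

            def cost(a):
                return np.sum((forward_kinematics(chain, a)["wrist"] - goal.point) ** 2)

            o = chain_oracle(chain, angles, goal, spec).velocity
            if np.allclose(o, 0):
                continue
            assert cost(angles + o) < cost(angles)

    def test_step_matches_grid_search_near_goal(self, rng):
        # in the regime where the one-step optimum lies inside the search box,
        # a brute-force search over discretized joint increments must agree
        # with the damped-LS step direction
        chain = two_link()
        spec = ChainOracleSpec(mu=1e-6, omega_max=0.05, delta=1e-9, goal_tol=1e-4)
        grid = np.linspace(-0.05, 0.05, 41)
        for _ in range(10):
            angles = rng.uniform(-1.2, 1.2, 2)
            true_delta = rng.uniform(-0.02, 0.02, 2)
            goal_pos = forward_kinematics(chain, angles + true_delta)["wrist"]
            goal = Goal(kind="wand", positions=goal_pos[None, :])

            def cost(a):
                return np.sum((forward_kinematics(chain, a)["wrist"] - goal.point) ** 2)

            o = chain_oracle(chain, angles, goal, spec).velocity
            if np.linalg.norm(o) < 1e-6:
                continue
            best = min(
                ((d1, d2) for d1 in grid for d2 in grid),
                key=lambda d: cost(angles + np.array(d)),
            )
            cos = np.dot(o, best) / (np.linalg.norm(o) * np.linalg.norm(best) + 1e-12)
            assert cos > 0.9

    def test_joint_speed_infnorm_bound(self, rng):
        chain = two_link()
        for _ in range(50):
            angles = rng.uniform(-np.pi, np.pi, 2)
            goal = Goal(kind="wand", positions=rng.uniform(-2, 2, 3)[None, :])
            o = chain_oracle(chain, angles, goal, self.spec)
            assert np.max(np.abs(o.velocity)) <= self.spec.omega_max + 1e-12

    def test_requires_wand_goal(self):
        with pytest.raises(ValueError, match="wand"):
            chain_oracle(two_link(), np.zeros(2), cursor_goal([1, 0, 0]), self.spec)

    def test_zero_damping_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            ChainOracleSpec(mu=0.0)


class TestIntentionNoise:
    def test_zero_pct_is_identity(self, rng):
        o = OracleAction(np.array([1.0, 2.0, 3.0]))
        assert apply_intention_noise(o, 0.0, rng) is o

    def test_hundred_pct_adds_equal_norm_vector(self, rng):
        o = OracleAction(np.array([0.3, -0.4, 0.0]))
        for _ in range(200):
            u = apply_intention_noise(o, 100.0, rng)
            assert np.linalg.norm(u.velocity - o.velocity) == pytest.approx(0.5)

    def test_mean_is_unbiased(self, rng):
        # the sphere mean is zero, so the noisy intention is centred on o
        o = OracleAction(np.array([1.0, 0.0, 0.0]))
        draws = np.stack([apply_intention_noise(o, 100.0, rng).velocity for _ in range(100_000)])
        assert np.allclose(draws.mean(axis=0), o.velocity, atol=4.0 / np.sqrt(100_000))

    def test_negative_pct_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_intention_noise(OracleAction(np.ones(3)), -1.0, rng)


class TestLinearMismatch:
    def test_identity_and_gain(self):
        o = OracleAction(np.array([1.0, -2.0, 0.5]))
        assert np.allclose(apply_linear_mismatch(o, np.eye(3)).velocity, o.velocity)
        assert np.allclose(apply_linear_mismatch(o, 2 * np.eye(3)).velocity, 2 * o.velocity)

    def test_matches_explicit_summation(self, rng):
        o = OracleAction(rng.standard_normal(4))
        M = rng.standard_normal((4, 4))
        u = apply_linear_mismatch(o, M).velocity
        loop = np.array([sum(M[i, j] * o.velocity[j] for j in range(4)) for i in range(4)])
        assert np.allclose(u, loop)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_linear_mismatch(OracleAction(np.ones(3)), np.eye(2))


class TestArcMismatch:
    spec45 = MismatchSpec(kind="arc", phi_max=45.0, sigmoid_midpoint=3.0, sigmoid_slope=1.0)

    def test_zero_angle_is_identity(self):
        o = OracleAction(np.array([1.0, 0.0, 0.0]))
        spec = MismatchSpec(kind="arc", phi_max=0.0)
        u = apply_arc_mismatch(o, np.zeros(3), cursor_goal([5, 0, 0]), spec)
        assert np.allclose(u.velocity, o.velocity)

    def test_rotation_preserves_norm(self, rng):
        for _ in range(50):
            o = OracleAction(rng.standard_normal(3))
            pose = rng.standard_normal(3)
            goal = cursor_goal(rng.standard_normal(3) * 5)
            u = apply_arc_mismatch(o, pose, goal, self.spec45)
            assert np.linalg.norm(u.velocity) == pytest.approx(np.linalg.norm(o.velocity))

    def test_far_from_goal_angle_saturates(self):
        # independent oracle: the composed plane rotations equal an extrinsic
        # z-x-y Euler rotation with all three angles theta(d); far beyond the
        # sigmoid midpoint theta approaches phi_max (within saturation).
        d = 30.0
        theta = np.deg2rad(45.0) / (1.0 + np.exp(-(d - 3.0) / 1.0))
        R_scipy = Rotation.from_euler("zxy", [theta, theta, theta]).as_matrix()
        o = OracleAction(np.array([0.0, 0.5, 0.0]))
        u = apply_arc_mismatch(o, np.zeros(3), cursor_goal([d, 0, 0]), self.spec45)
        assert np.allclose(u.velocity, R_scipy @ o.velocity, atol=1e-12)
        angles = Rotation.from_matrix(R_scipy).as_euler("zxy")
        assert np.allclose(np.rad2deg(angles), 45.0, atol=3.0)  # sigmoid saturation

    def test_near_goal_rotation_vanishes(self):
        o = OracleAction(np.array([0.1, 0.0, 0.0]))
        u = apply_arc_mismatch(o, np.array([0.05, 0, 0]), cursor_goal([0.1, 0, 0]), self.spec45)
        angle = np.arccos(
            np.clip(np.dot(u.velocity, o.velocity) / np.dot(o.velocity, o.velocity), -1, 1)
        )
        assert np.rad2deg(angle) < 5.0

    def test_phi_outside_range_rejected(self):
        with pytest.raises(ValueError):
            MismatchSpec(kind="arc", phi_max=91.0)

    def test_sequential_plane_rotation_convention(self):
        theta = 0.3
        c, s = np.cos(theta), np.sin(theta)
        rot_xy = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rot_yz = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
        rot_zx = np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])
        assert np.allclose(arc_rotation(theta), rot_zx @ rot_yz @ rot_xy)
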