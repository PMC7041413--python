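"""Synthetic task suite: low-dimensional mappings and control environments.

Mapping tasks are Lipschitz functions f: [0,1]^dA -> [0,1]^dB with a scalar
error feedback L(x, y) >= 0 (zero at an optimum).  The learner only ever sees
L, never f or its gradient.  Control environments follow a minimal gym-style
protocol (reset/step with declared state and action boxes) so agents can be
run against external environments through the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Tuple

import numpy as np

__all__ = [
    "TaskSpec",
    "mapping_tasks",
    "identity_task",
    "sinus_task",
    "polynomial_task",
    "throw_ball_task",
    "throw_ball_feedback",
    "robotic_arm_task",
    "robotic_arm_feedback",
    "arm_endpoint",
    "Environment",
    "MountainCarEnv",
    "CartPoleEnv",
    "mountain_car_env",
    "cartpole_env",
]

GRAVITY = 9.81


@dataclass(frozen=True)
class TaskSpec:
    """A mapping task: target function, scalar feedback, Lipschitz constant.

    ``feedback_bound`` is an upper bound on L, used to initialise running
    error thresholds.
    """

    name: str
    d_A: int
    d_B: int
    f: Callable[[np.ndarray], np.ndarray] | None
    feedback: Callable[[np.ndarray, np.ndarray], float]
    C: float
    feedback_bound: float = 1.0


def _abs_feedback(f: Callable[[np.ndarray], np.ndarray]):
    def L(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.linalg.norm(np.atleast_1d(f(x)) - np.atleast_1d(y)))

    return L


def identity_task() -> TaskSpec:
    """f(x) = x with absolute-distance feedback; C = 1."""
    f = lambda x: np.atleast_1d(np.asarray(x, dtype=float))
    return TaskSpec("identity", 1, 1, f, _abs_feedback(f), C=1.0, feedback_bound=1.0)


def sinus_task() -> TaskSpec:
    """f(x) = sin(x) on [0,1] (range within [0, sin 1]); C = 1."""
    f = lambda x: np.sin(np.atleast_1d(np.asarray(x, dtype=float)))
    return TaskSpec("sinus", 1, 1, f, _abs_feedback(f), C=1.0, feedback_bound=1.0)


def polynomial_raw(x):
    """The second-order polynomial g(x) = x^2 - 3x + 1 (range [-1, 1] on [0,1])."""
    x = np.asarray(x, dtype=float)
    return x * x - 3.0 * x + 1.0


def polynomial_task() -> TaskSpec:
    """g(x) = x^2 - 3x + 1 rescaled into [0,1] via (g+1)/2; C = 1.5.

    The raw polynomial maps [0,1] onto [-1,1], outside the coded interval;
    the affine rescale keeps the target inside (0,1] while preserving shape.
    |d/dx (g+1)/2| = |2x-3|/2 <= 1.5 on [0,1].
    """
    f = lambda x: (polynomial_raw(np.atleast_1d(x)) + 1.0) / 2.0
    return TaskSpec("polynomial", 1, 1, f, _abs_feedback(f), C=1.5, feedback_bound=1.0)


def mapping_tasks() -> Dict[str, TaskSpec]:
    """The three 1-D mapping tasks keyed by name."""
    return {
        t.name: t for t in (identity_task(), sinus_task(), polynomial_task())
    }


# -- throw ball ---------------------------------------------------------------

V_MAX = math.sqrt(GRAVITY)  # maximal launch speed; makes the maximal range 1


def throw_ball_feedback(d: float, theta: float, v: float) -> float:
    """|range - d| for a drag-free throw at angle theta and speed v.

    Flat ground, launch height 0: range = v^2 sin(2 theta) / g.  With
    v <= sqrt(g) the maximal range (at theta = pi/4) is exactly 1, so every
    target d in [0,1] is reachable for every angle in (0, pi/2).
    """
    rng = v * v * math.sin(2.0 * theta) / GRAVITY
    return abs(rng - d)


def throw_ball_task() -> TaskSpec:
    """Target distance in [0,1] -> (angle, speed), feedback |range - d|.

    The network output (y1, y2) in (0,1]^2 decodes to theta = y1 * pi/2 and
    v = y2 * v_max.  The optimum is underdetermined: the zero-feedback set is
    a curve in (theta, v) space.
    """

    def L(x: np.ndarray, y: np.ndarray) -> float:
        d = float(np.atleast_1d(x)[0])
        y = np.atleast_1d(y)
        theta = float(y[0]) * math.pi / 2.0
        v = float(y[1]) * V_MAX
        return throw_ball_feedback(d, theta, v)

    return TaskSpec("throw_ball", 1, 2, None, L, C=2.0, feedback_bound=1.0)


# -- robotic arm --------------------------------------------------------------

L1 = 0.5
L2 = 0.5


def arm_endpoint(alpha: float, beta: float) -> np.ndarray:
    """Endpoint of the two-link arm (links 0.5/0.5, anchored at the origin)."""
    return np.array(
        [
            L1 * math.cos(alpha) + L2 * math.cos(alpha + beta),
            L1 * math.sin(alpha) + L2 * math.sin(alpha + beta),
        ]
    )


def robotic_arm_feedback(target: np.ndarray, alpha: float, beta: float) -> float:
    """Euclidean distance between the arm endpoint and the target.

    Both are expressed in workspace coordinates [0,1]^2: physical coordinates
    (the reachable disc of radius 1 around the anchor) map through
    (e + 1) / 2.
    """
    e01 = (arm_endpoint(alpha, beta) + 1.0) / 2.0
    return float(np.linalg.norm(e01 - np.asarray(target, dtype=float)))


def robotic_arm_task() -> TaskSpec:
    """Target position in [0,1]^2 -> joint angles, euclidean feedback.

    Outputs (y1, y2) in (0,1]^2 decode to angles 2*pi*y - pi in (-pi, pi].
    """

    def L(x: np.ndarray, y: np.ndarray) -> float:
        y = np.atleast_1d(y)
        alpha = 2.0 * math.pi * float(y[0]) - math.pi
        beta = 2.0 * math.pi * float(y[1]) - math.pi
        return robotic_arm_feedback(np.atleast_1d(x), alpha, beta)

    return TaskSpec("robotic_arm", 2, 2, None, L, C=2.0, feedback_bound=math.sqrt(2.0))


def arm_inverse_kinematics(target01: np.ndarray) -> Tuple[float, float]:
    """Closed-form two-link inverse kinematics for a workspace target.

    Returns (alpha, beta) with endpoint at the target (elbow-down solution).
    Raises ValueError for unreachable targets.
    """
    t = 2.0 * np.asarray(target01, dtype=float) - 1.0
    r2 = float(t @ t)
    cos_beta = (r2 - L1 * L1 - L2 * L2) / (2.0 * L1 * L2)
    if not -1.0 - 1e-12 <= cos_beta <= 1.0 + 1e-12:
        raise ValueError(f"target {target01} unreachable")
    cos_beta = min(1.0, max(-1.0, cos_beta))
    beta = math.acos(cos_beta)
    alpha = math.atan2(t[1], t[0]) - math.atan2(
        L2 * math.sin(beta), L1 + L2 * math.cos(beta)
    )
    return alpha, beta


# -- control environments -----------------------------------------------------


class Environment:
    """Minimal episodic continuous-control interface.

    ``reset(rng) -> state``; ``step(action) -> (state, reward, done)``.
    ``state_box`` and ``action_box`` are (low, high) arrays declaring the
    coding ranges.  Dynamics are deterministic given (state, action); the
    only randomness is the start state.
    """

    state_box: Tuple[np.ndarray, np.ndarray]
    action_box: Tuple[np.ndarray, np.ndarray]
    max_steps: int

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def step(self, action: np.ndarray) -> Tuple[np.ndarray, float, bool]:
        raise NotImplementedError


class MountainCarEnv(Environment):
    """Continuous mountain car: gain momentum to escape a valley.

    State (position, velocity); action a in [-1, 1] is the applied
    acceleration.  velocity += 0.0015 a - 0.0025 cos(3 position); the goal at
    position >= 0.45 pays +100, each step costs 0.1 a^2 (fuel).  Start
    position uniform in [-0.6, -0.4], 999-step cap.
    """

    def __init__(self) -> None:
        self.state_box = (np.array([-1.2, -0.07]), np.array([0.6, 0.07]))
        self.action_box = (np.array([-1.0]), np.array([1.0]))
        self.max_steps = 999
        self.goal_position = 0.45
        self._state = np.zeros(2)
        self._t = 0

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        self._state = np.array([rng.uniform(-0.6, -0.4), 0.0])
        self._t = 0
        return self._state.copy()

    def step(self, action) -> Tuple[np.ndarray, float, bool]:
        a = float(np.clip(np.atleast_1d(action)[0], -1.0, 1.0))
        pos, vel = self._state
        vel += 0.0015 * a - 0.0025 * math.cos(3.0 * pos)
        vel = min(max(vel, -0.07), 0.07)
        pos += vel
        if pos < -1.2:
            pos, vel = -1.2, 0.0
        reward = -0.1 * a * a
        done = False
        if pos >= self.goal_position:
            reward += 100.0
            done = True
        self._t += 1
        if self._t >= self.max_steps:
            done = True
        self._state = np.array([pos, vel])
        return self._state.copy(), reward, done


class CartPoleEnv(Environment):
    """Continuous-action cart-pole: balance an inverted pendulum on a cart.

    Classical dynamics (cart mass 1, pole mass 0.1, half-length 0.5,
    g = 9.8), Euler-integrated at dt = 0.02.  The action is the horizontal
    force in [-10, 10].  +1 reward per step until |angle| > 0.2095 rad or
    |cart position| > 2.4; 1000-step cap.  State: (x, x_dot, theta,
    theta_dot).
    """

    def __init__(self) -> None:
        self.state_box = (
            np.array([-2.4, -3.0, -0.21, -3.0]),
            np.array([2.4, 3.0, 0.21, 3.0]),
        )
        self.action_box = (np.array([-10.0]), np.array([10.0]))
        self.max_steps = 1000
        self.dt = 0.02
        self.masscart = 1.0
        self.masspole = 0.1
        self.length = 0.5  # half pole length
        self.g = 9.8
        self._state = np.zeros(4)
        self._t = 0

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        self._state = rng.uniform(-0.05, 0.05, size=4)
        self._t = 0
        return self._state.copy()

    def step(self, action) -> Tuple[np.ndarray, float, bool]:
        force = float(np.clip(np.atleast_1d(action)[0], -10.0, 10.0))
        x, x_dot, th, th_dot = self._state
        total_m = self.masscart + self.masspole
        pm_l = self.masspole * self.length
        sin, cos = math.sin(th), math.cos(th)
        tmp = (force + pm_l * th_dot * th_dot * sin) / total_m
        th_acc = (self.g * sin - cos * tmp) / (
            self.length * (4.0 / 3.0 - self.masspole * cos * cos / total_m)
        )
        x_acc = tmp - pm_l * th_acc * cos / total_m
        x += self.dt * x_dot
        x_dot += self.dt * x_acc
        th += self.dt * th_dot
        th_dot += self.dt * th_acc
        self._state = np.array([x, x_dot, th, th_dot])
        self._t += 1
        done = abs(th) > 0.2095 or abs(x) > 2.4 or self._t >= self.max_steps
        return self._state.copy(), 1.0, done


def mountain_car_env() -> MountainCarEnv:
    return MountainCarEnv()


def cartpole_env() -> CartPoleEnv:
    return CartPoleEnv()
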