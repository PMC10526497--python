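"""The binocular depth-estimation hierarchy.

Four belief levels are stacked per the generative model:

* an absolute belief ``mu_a = (x, y, 1)`` over the target's world position
  (depth on ``x``),
* a vergence-accommodation belief ``mu_theta = (theta_a, theta_v)`` over the
  common and differential eye rotations, with per-eye absolute angles
  ``theta(0) = theta_a - theta_v`` and ``theta(1) = theta_a + theta_v``,
* per-eye relative beliefs ``mu_r(i)`` (the target in each eye's frame),
* per-eye projected beliefs ``mu_c(i) = (1, c)`` on the camera planes.

Top-down, each level predicts the one below (eye transform, then pinhole
projection, then an identity visual map); bottom-up, prediction errors are
pulled back through the analytic adjoints in :mod:`depthsim.transforms`.
Fixation is induced by an attractor on the projected beliefs that drifts
them toward the plane centres ``(1, 0)``; estimation and fixation alternate
in action/perception phases so the shared error pathways do not fight.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import transforms as tf
from .inference import (
    ActionState,
    ErrorUnit,
    GeneralizedBelief,
    free_energy_proxy,
    set_error_instantaneous,
    step_action,
    step_belief,
    step_error_unit,
)

CENTER = np.array([1.0, 0.0])  # homogeneous centre of a camera plane


class Phase(enum.Enum):
    PERCEPTION = "perception"
    ACTION = "action"
    SIMULTANEOUS = "simultaneous"  # non-cycled: both pathways open at once


class BlockMechanism(enum.Enum):
    """How action is blocked during a perception phase."""

    ZERO_ATTRACTOR_GAIN = "zero_attractor_gain"
    ZERO_PROPRIO_PRECISION = "zero_proprio_precision"


@dataclass(frozen=True)
class PhaseSchedule:
    """Strictly alternating phases of equal length."""

    cycle_length: int = 100
    start: Phase = Phase.PERCEPTION

    def __post_init__(self) -> None:
        if self.cycle_length < 1:
            raise ValueError("cycle_length must be >= 1")
        if self.start not in (Phase.PERCEPTION, Phase.ACTION):
            raise ValueError("schedule must start with perception or action")


def schedule_phase(t: int, sched: PhaseSchedule) -> Phase:
    """Phase at integrator step ``t`` (deterministic alternation)."""
    if t < 0:
        raise ValueError("step index must be nonnegative")
    other = Phase.ACTION if sched.start is Phase.PERCEPTION else Phase.PERCEPTION
    return sched.start if (t // sched.cycle_length) % 2 == 0 else other


@dataclass
class AgentConfig:
    """Geometry, precisions and gains of the depth-estimation agent.

    ``eye_offsets`` records the lateral placement convention: eye 0 sits at
    ``+L``, eye 1 at ``-L``.  The attractor gain ``lam`` is stored positive
    and applied with a minus sign, so the believed projection drifts toward
    the plane centre.
    """

    L: float = 0.5
    focal: float = 1.0
    dt: float = 0.05
    # precisions (defaults tuned for Euler stability at dt = 0.05 over the
    # shipped target box; see the shipped config echo for provenance)
    pi_r: float = 1.0
    pi_p: float = 50.0
    pi_pp: float = 5.0  # precision of the velocity order of proprioception
    pi_c: float = 10.0
    pi_v: float = 10.0
    gamma_a: float = 1.0
    gamma_theta: float = 1.0
    gamma_r: float = 1.0
    gamma_c: float = 1.0
    # learning gains
    k_a: float = 10.0
    k_theta: float = 0.05
    k_r: float = 4.0
    k_c: float = 0.5
    k_action: float = 1.0
    lam: float = 3.0
    instantaneous_errors: bool = True
    mechanism: BlockMechanism = BlockMechanism.ZERO_ATTRACTOR_GAIN

    @property
    def camera(self) -> tf.Camera:
        return tf.Camera(self.focal)

    @property
    def eye_offsets(self) -> np.ndarray:
        return np.array([self.L, -self.L])


# per-eye sign of d(theta(i))/d(theta_v): theta(0) = theta_a - theta_v
_THETA_V_SIGN = np.array([-1.0, 1.0])


def eye_angles(mu_theta: np.ndarray) -> np.ndarray:
    """Absolute per-eye angles from a (theta_a, theta_v) pair."""
    theta_a, theta_v = mu_theta[0], mu_theta[1]
    return np.array([theta_a - theta_v, theta_a + theta_v])


class DepthAgent:
    """Message-passing state of the full hierarchy plus the action signal."""

    def __init__(
        self,
        cfg: AgentConfig,
        init_position: np.ndarray,
        init_angles: np.ndarray,
    ) -> None:
        self.cfg = cfg
        self.mu_a = GeneralizedBelief(
            mu=np.array([init_position[0], init_position[1], 1.0]),
            dynamics_precision=cfg.gamma_a,
            mask=np.array([1.0, 1.0, 0.0]),
        )
        self.mu_theta = GeneralizedBelief(
            mu=np.asarray(init_angles, dtype=float),
            dynamics_precision=cfg.gamma_theta,
        )
        self.mu_r: List[GeneralizedBelief] = []
        self.mu_c: List[GeneralizedBelief] = []
        for i in range(2):
            rel = self.predict_relative(i)
            self.mu_r.append(
                GeneralizedBelief(
                    mu=rel, dynamics_precision=cfg.gamma_r, mask=np.array([1.0, 1.0, 0.0])
                )
            )
            proj = tf.project_to_camera(rel, cfg.camera)
            self.mu_c.append(
                GeneralizedBelief(
                    mu=proj, dynamics_precision=cfg.gamma_c, mask=np.array([0.0, 1.0])
                )
            )
        self.eps_r = [ErrorUnit(np.zeros(3), cfg.pi_r) for _ in range(2)]
        self.eps_c = [ErrorUnit(np.zeros(2), cfg.pi_c) for _ in range(2)]
        self.eps_v = [ErrorUnit(np.zeros(2), cfg.pi_v) for _ in range(2)]
        self.eps_p = ErrorUnit(np.zeros(2), cfg.pi_p)
        self.eps_pp = ErrorUnit(np.zeros(2), cfg.pi_pp)
        self.eps_mu_a = ErrorUnit(np.zeros(3), cfg.gamma_a)
        self.eps_mu_theta = ErrorUnit(np.zeros(2), cfg.gamma_theta)
        self.eps_mu_r = [ErrorUnit(np.zeros(3), cfg.gamma_r) for _ in range(2)]
        self.eps_mu_c = [ErrorUnit(np.zeros(2), cfg.gamma_c) for _ in range(2)]
        self.action = ActionState(np.zeros(2), gain=cfg.k_action, enabled=False)
        self._last_free_energy = 0.0

    # ---------------------------------------------------------------- forward
    def predict_relative(self, eye: int) -> np.ndarray:
        """Top-down prediction of the target in eye ``eye``'s frame."""
        angles = eye_angles(self.mu_theta.mu)
        T = tf.make_eye_transform(angles[eye], self.cfg.eye_offsets[eye])
        return tf.apply_transform(T, self.mu_a.mu)

    def predict_projection(self, eye: int) -> np.ndarray:
        """Top-down prediction of eye ``eye``'s image point from mu_r."""
        return tf.project_to_camera(self.mu_r[eye].mu, self.cfg.camera)

    def attractor_fc(self, eye: int, lam: Optional[float] = None) -> np.ndarray:
        """Fixation attractor: velocity pulling mu_c toward the plane centre."""
        lam = self.cfg.lam if lam is None else lam
        return -lam * (self.mu_c[eye].mu - CENTER)

    def estimate(self) -> np.ndarray:
        """Current (x, y) estimate of the target position."""
        return self.mu_a.mu[:2].copy()

    @property
    def free_energy(self) -> float:
        """Precision-weighted squared-error proxy from the last step."""
        return self._last_free_energy

    # ------------------------------------------------------------------- step
    def step(
        self,
        sp: np.ndarray,
        sv: List[np.ndarray],
        phase: Phase,
        sp_prime: Optional[np.ndarray] = None,
    ) -> None:
        """One synchronous Euler step of every belief, error unit and action.

        ``sp`` is the proprioceptive observation (true angles) and
        ``sp_prime`` its velocity order (realized angular velocity, zero if
        omitted); ``sv`` holds one homogeneous image point ``(1, c)`` per
        eye.  The phase gates the pathways: during perception the attractor
        and action are off; during action the absolute belief is frozen.
        """
        cfg = self.cfg
        dt = cfg.dt
        zero_pp = (
            phase is Phase.PERCEPTION
            and cfg.mechanism is BlockMechanism.ZERO_PROPRIO_PRECISION
        )
        if phase is Phase.PERCEPTION and not zero_pp:
            lam = 0.0  # default mechanism: attractor gain zeroed
        else:
            lam = cfg.lam
        self.mu_a.frozen = phase is Phase.ACTION
        self.action.enabled = phase is not Phase.PERCEPTION

        # ---- forward predictions and raw errors (all from the state at t)
        angles = eye_angles(self.mu_theta.mu)
        T = [
            tf.make_eye_transform(angles[i], cfg.eye_offsets[i]) for i in range(2)
        ]
        dT = [
            tf.d_eye_transform_dtheta(angles[i], cfg.eye_offsets[i]) for i in range(2)
        ]
        pred_r = [tf.apply_transform(T[i], self.mu_a.mu) for i in range(2)]
        pred_c = [self.predict_projection(i) for i in range(2)]

        raw_r = [self.mu_r[i].mu - pred_r[i] for i in range(2)]
        raw_c = [self.mu_c[i].mu - pred_c[i] for i in range(2)]
        raw_v = [np.asarray(sv[i], dtype=float) - self.mu_c[i].mu for i in range(2)]
        raw_p = np.asarray(sp, dtype=float) - self.mu_theta.mu
        if sp_prime is None:
            sp_prime = np.zeros(2)
        raw_pp = np.asarray(sp_prime, dtype=float) - self.mu_theta.mu_prime
        raw_mu_a = self.mu_a.mu_prime.copy()  # f_a = 0
        raw_mu_theta = self.mu_theta.mu_prime.copy()  # f_theta = 0
        raw_mu_r = [self.mu_r[i].mu_prime.copy() for i in range(2)]
        raw_mu_c = [
            self.mu_c[i].mu_prime - self.attractor_fc(i, lam) for i in range(2)
        ]

        units = (
            self.eps_r + self.eps_c + self.eps_v + [self.eps_p, self.eps_pp]
            + [self.eps_mu_a, self.eps_mu_theta] + self.eps_mu_r + self.eps_mu_c
        )
        raws = (
            raw_r + raw_c + raw_v + [raw_p, raw_pp]
            + [raw_mu_a, raw_mu_theta] + raw_mu_r + raw_mu_c
        )
        self._last_free_energy = free_energy_proxy(units, raws)

        # instantaneous mode: errors are algebraic functions of the state
        if cfg.instantaneous_errors:
            for eu, raw in zip(units, raws):
                set_error_instantaneous(eu, raw)

        # ---- belief drives from the current error-unit values
        eps_r = [self.eps_r[i].value for i in range(2)]
        eps_c = [self.eps_c[i].value for i in range(2)]
        eps_v = [self.eps_v[i].value for i in range(2)]
        eps_p = np.zeros(2) if zero_pp else self.eps_p.value
        eps_pp = np.zeros(2) if zero_pp else self.eps_pp.value

        # absolute belief: ascending relative errors through both eyes
        up_a = sum(tf.backprop_point(T[i], eps_r[i]) for i in range(2))

        # eye-angle belief: ascending relative errors via the transform
        # parameter, plus the proprioceptive likelihood
        up_theta = np.zeros(2)
        for i in range(2):
            g = tf.backprop_param(dT[i], eps_r[i], self.mu_a.mu)
            up_theta += g * np.array([1.0, _THETA_V_SIGN[i]])
        up_theta += eps_p

        # relative beliefs: descending prior minus, ascending projection error
        up_r, down_r = [], []
        for i in range(2):
            asc = tf.backprop_projection(self.mu_r[i].mu, cfg.camera, eps_c[i][1])
            up_r.append(np.array([asc[0], asc[1], 0.0]))
            down_r.append(-eps_r[i])

        # projected beliefs: descending prior, visual likelihood, attractor
        up_c, down_c = [], []
        for i in range(2):
            up_c.append(eps_v[i])
            down_c.append(-eps_c[i] - lam * self.eps_mu_c[i].value)

        # ---- synchronous updates
        step_belief(self.mu_a, up_a, 0.0, dt, cfg.k_a, -self.eps_mu_a.value)
        # the velocity order of proprioception drives the motor reflex only;
        # feeding it to mu_theta' as well would cancel the friction it
        # provides to the oculomotor loop
        step_belief(
            self.mu_theta,
            up_theta,
            0.0,
            dt,
            cfg.k_theta,
            -self.eps_mu_theta.value,
        )
        for i in range(2):
            step_belief(
                self.mu_r[i], up_r[i], down_r[i], dt, cfg.k_r, -self.eps_mu_r[i].value
            )
            step_belief(
                self.mu_c[i], up_c[i], down_c[i], dt, cfg.k_c, -self.eps_mu_c[i].value
            )

        if self.action.enabled and not zero_pp:
            # both generalized orders of the proprioceptive error drive the
            # motor signal; the velocity order acts as friction
            drive = ErrorUnit(self.eps_p.value + self.eps_pp.value, 1.0)
            step_action(self.action, drive, None, dt)

        if not cfg.instantaneous_errors:
            for eu, raw in zip(units, raws):
                step_error_unit(eu, raw, dt)
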