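"""The generative process: true world state and noisy observations.

The world holds a single target at ``(x, y)`` with strictly positive depth
``x`` and two eyes on the lateral axis at ``(0, +L)`` (eye 0) and
``(0, -L)`` (eye 1).  Proprioception reads the true vergence-accommodation
angles exactly; vision reads each eye's true pinhole projection corrupted by
Gaussian noise whose spread grows exponentially with the distance between
the point of fixation and the target (the nonuniform-fovea model), or is
exactly zero in the uniform condition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from . import transforms as tf
from .agent import eye_angles
from .inference import ActionState


class ObservationError(RuntimeError):
    """Raised when the target falls behind an eye (non-positive depth)."""


class FoveaMode(enum.Enum):
    UNIFORM = "uniform"
    NONUNIFORM = "nonuniform"


@dataclass(frozen=True)
class FoveaNoiseModel:
    """Distance-dependent visual noise.

    ``k`` is the exponential scaling factor; in ``UNIFORM`` mode the noise
    is identically zero.  The dimensionless spread ``exp(d / k)`` is mapped
    to image units by ``sigma0`` (the standard deviation at perfect
    fixation); ``sigma_is_variance`` switches the interpretation of the
    spread from a standard deviation (default) to a variance, for
    sensitivity analyses.
    """

    k: float = 1.5
    mode: FoveaMode = FoveaMode.NONUNIFORM
    sigma0: float = 0.05
    sigma_is_variance: bool = False


@dataclass(frozen=True)
class WorldState:
    """True target, true eye angles and fixed geometry."""

    target: np.ndarray  # (x, y), x > 0
    eye_angles_true: np.ndarray  # (theta_a, theta_v)
    eye_velocity: np.ndarray = None  # realized angular velocity (set by apply_action)
    L: float = 0.5
    cam: tf.Camera = tf.Camera(1.0)
    far_clip: float = 10.0
    angle_limit: float = np.pi / 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        object.__setattr__(
            self, "eye_angles_true", np.asarray(self.eye_angles_true, dtype=float)
        )
        vel = (
            np.zeros(2)
            if self.eye_velocity is None
            else np.asarray(self.eye_velocity, dtype=float)
        )
        object.__setattr__(self, "eye_velocity", vel)
        if self.target[0] <= 0:
            raise ValueError("target depth must be strictly positive")

    @property
    def eye_offsets(self) -> np.ndarray:
        return np.array([self.L, -self.L])


@dataclass(frozen=True)
class Observation:
    """Proprioception is read out in two generalized orders (angles and
    angular velocity), both noiseless; vision is one image point per eye."""

    sp: np.ndarray  # (theta_a, theta_v), noiseless
    sp_prime: np.ndarray  # realized (theta_a', theta_v'), noiseless
    sv: tuple  # per-eye homogeneous image points (1, c)


def fovea_sigma(d: float, noise: FoveaNoiseModel) -> float:
    """Spread of the visual noise at fixation-to-target distance ``d``."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    if noise.mode is FoveaMode.UNIFORM:
        return 0.0
    return float(np.exp(d / noise.k))


def true_projection(world: WorldState, eye: int) -> np.ndarray:
    """Noise-free image point of the target in eye ``eye`` (homogeneous)."""
    angles = eye_angles(world.eye_angles_true)
    T = tf.make_eye_transform(angles[eye], world.eye_offsets[eye])
    rel = tf.apply_transform(T, np.append(world.target, 1.0))
    if rel[0] <= 0:
        raise ObservationError(f"target is behind eye {eye}")
    return tf.project_to_camera(rel, world.cam)


def fixation_point(world: WorldState) -> np.ndarray:
    """Intersection of the two eyes' gaze rays.

    Each eye's gaze ray is the line its depth axis traces in the world:
    ``y = l_i + x * tan(theta(i))``.  When the rays are parallel, or when
    they meet behind the eyes (diverging gaze), a finite surrogate at
    ``far_clip`` world units along the mean gaze direction is returned so a
    fixation distance is always defined.
    """
    angles = eye_angles(world.eye_angles_true)
    t0, t1 = np.tan(angles[0]), np.tan(angles[1])
    denom = t1 - t0
    theta_mean = world.eye_angles_true[0]
    far = world.far_clip * np.array([np.cos(theta_mean), np.sin(theta_mean)])
    if abs(denom) < 1e-12:
        return far
    x = 2.0 * world.L / denom
    if x <= 0:  # gaze rays intersect behind the eyes
        return far
    y = world.L + x * t0
    return np.array([x, y])


def observe(
    world: WorldState, noise: FoveaNoiseModel, rng: np.random.Generator
) -> Observation:
    """Sample one observation from the generative process."""
    d = float(np.linalg.norm(fixation_point(world) - world.target))
    sigma = fovea_sigma(d, noise)
    if noise.sigma_is_variance:
        sigma = float(np.sqrt(sigma))
    sigma *= noise.sigma0
    sv = []
    for eye in range(2):
        proj = true_projection(world, eye)
        c = proj[1] + (sigma * rng.standard_normal() if sigma > 0 else 0.0)
        sv.append(np.array([1.0, c]))
    return Observation(
        sp=world.eye_angles_true.copy(),
        sp_prime=world.eye_velocity.copy(),
        sv=tuple(sv),
    )


def apply_action(world: WorldState, act: ActionState, dt: float) -> WorldState:
    """Advance the true eye angles by ``dt`` times the motor signal.

    The per-eye absolute angles are clipped to ``(-angle_limit, angle_limit)``
    so targets stay in front of the eyes; the clipped pair is mapped back to
    vergence-accommodation form.
    """
    new = world.eye_angles_true + dt * act.effective()
    lim = world.angle_limit - 1e-9
    th = np.clip(eye_angles(new), -lim, lim)
    new = np.array([(th[0] + th[1]) / 2.0, (th[1] - th[0]) / 2.0])
    vel = (new - world.eye_angles_true) / dt  # realized velocity, after clipping
    return replace(world, eye_angles_true=new, eye_velocity=vel)


def fixation_angles(target: np.ndarray, L: float) -> np.ndarray:
    """Vergence-accommodation pair that verges both eyes onto ``target``."""
    x, y = float(target[0]), float(target[1])
    th0 = np.arctan2(y - L, x)
    th1 = np.arctan2(y + L, x)
    return np.array([(th0 + th1) / 2.0, (th1 - th0) / 2.0])
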