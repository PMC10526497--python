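"""Generic continuous-time predictive-coding machinery.

Beliefs are carried in generalized coordinates up to the first derivative
(value and velocity).  Prediction errors are dynamic states of their own:
rather than being computed as instantaneous precision-weighted differences,
each error unit relaxes toward ``precision * raw_error`` with unit time
constant, following ``d(eps)/dt = raw_error - eps / precision``.  An
``instantaneous`` switch replaces the relaxation with its algebraic fixed
point, which is convenient for testing the update equations in isolation.

All integration is explicit Euler with a caller-supplied ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


class DivergenceError(RuntimeError):
    """Raised when a belief update produces non-finite values."""


@dataclass
class ErrorUnit:
    """A dynamic prediction-error state with precision ``pi``.

    For a constant raw error ``e`` the value converges to ``pi * e``; the
    unit therefore delivers the precision-weighted error to the beliefs it
    feeds without the precision appearing in their update rules.
    """

    value: np.ndarray
    precision: float = 1.0

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError(f"precision must be positive, got {self.precision}")
        self.value = np.asarray(self.value, dtype=float).copy()


def step_error_unit(eu: ErrorUnit, raw_error: np.ndarray, dt: float) -> ErrorUnit:
    """One Euler step of the error-unit relaxation (in place; returns ``eu``)."""
    eu.value = eu.value + dt * (np.asarray(raw_error, dtype=float) - eu.value / eu.precision)
    return eu


def set_error_instantaneous(eu: ErrorUnit, raw_error: np.ndarray) -> ErrorUnit:
    """Jump the unit straight to its fixed point ``pi * raw_error``."""
    eu.value = eu.precision * np.asarray(raw_error, dtype=float)
    return eu


@dataclass
class GeneralizedBelief:
    """A latent variable with two temporal orders and an optional dynamics map.

    ``mask`` marks which components are updatable; frozen homogeneous
    coordinates (the trailing 1 of a projective point) carry a 0 there.
    """

    mu: np.ndarray
    mu_prime: Optional[np.ndarray] = None
    dynamics_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    dynamics_precision: float = 1.0
    frozen: bool = False
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).copy()
        if self.mu_prime is None:
            self.mu_prime = np.zeros_like(self.mu)
        else:
            self.mu_prime = np.asarray(self.mu_prime, dtype=float).copy()
        if self.mask is None:
            self.mask = np.ones_like(self.mu)
        else:
            self.mask = np.asarray(self.mask, dtype=float)
        if self.dynamics_precision <= 0:
            raise ValueError("dynamics precision must be positive")

    def predicted_velocity(self) -> np.ndarray:
        if self.dynamics_fn is None:
            return np.zeros_like(self.mu)
        return np.asarray(self.dynamics_fn(self.mu), dtype=float)


def step_belief(
    b: GeneralizedBelief,
    bottom_up: np.ndarray,
    top_down: np.ndarray,
    dt: float,
    gain: float = 1.0,
    order1_drive: Optional[np.ndarray] = None,
) -> GeneralizedBelief:
    """One Euler step of a generalized belief (in place; returns ``b``).

    Zeroth order moves along its own velocity plus the gain-scaled sum of
    ascending (``bottom_up``) and descending (``top_down``) error terms; the
    first order follows ``order1_drive`` (typically minus the dynamics
    error).  Frozen beliefs are left untouched by contract.
    """
    if b.frozen:
        return b
    drive0 = np.asarray(bottom_up, dtype=float) + np.asarray(top_down, dtype=float)
    b.mu = b.mu + dt * b.mask * (b.mu_prime + gain * drive0)
    if order1_drive is not None:
        b.mu_prime = b.mu_prime + dt * b.mask * gain * np.asarray(order1_drive, dtype=float)
    if not np.all(np.isfinite(b.mu)):
        raise DivergenceError("belief update produced non-finite values")
    return b


@dataclass
class ActionState:
    """Motor control signal (angular velocities) with an update gain."""

    a: np.ndarray
    gain: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).copy()

    def effective(self) -> np.ndarray:
        """The signal actually sent to the plant: zero when disabled."""
        return self.a if self.enabled else np.zeros_like(self.a)


def step_action(
    act: ActionState,
    proprio_error: ErrorUnit,
    jac: Optional[np.ndarray] = None,
    dt: float = 0.01,
) -> ActionState:
    """Descend the proprioceptive error: ``a <- a - dt * gain * jac.T @ eps_p``.

    The error unit's value already carries the proprioceptive precision (its
    fixed point is ``pi_p * raw``), so no further weighting is applied.  With
    the identity proprioceptive map ``jac`` defaults to the identity.
    Disabled actions are not updated.
    """
    if not act.enabled:
        return act
    eps = proprio_error.value
    drive = eps if jac is None else np.asarray(jac, dtype=float).T @ eps
    act.a = act.a - dt * act.gain * drive
    return act


@dataclass
class IntegratorConfig:
    """Euler discretization parameters shared by a whole model."""

    dt: float = 0.05
    gains: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def free_energy_proxy(
    error_units: Sequence[ErrorUnit], raw_errors: Sequence[np.ndarray]
) -> float:
    """Monitoring scalar: ``0.5 * sum_k pi_k * ||raw_k||^2``.

    Nonnegative, zero iff every raw error vanishes, and invariant to the
    ordering of the unit/raw pairs.
    """
    if len(error_units) != len(raw_errors):
        raise ValueError("error_units and raw_errors must have equal length")
    total = 0.0
    for eu, raw in zip(error_units, raw_errors):
        raw = np.asarray(raw, dtype=float)
        total += 0.5 * eu.precision * float(raw @ raw)
    return total
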