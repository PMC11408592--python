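"""Adam and its gradient-norm-scaled variant.

Standard Adam keeps exponential moving averages of the gradient (``m``) and
squared gradient (``v``), bias-corrects them to ``m_hat``, ``v_hat`` and
updates ``theta <- theta - alpha * m_hat / (sqrt(v_hat) + eps)``.

The custom variant additionally computes the Euclidean norm ``n = ||g||`` of
each parameter tensor's gradient and folds it into the step.  Two readings of
that update are provided:

* ``norm_scaled`` (default) — the learning rate is divided by ``n + eps``::

      theta <- theta - alpha / (n + eps) * m_hat / (sqrt(v_hat) + eps)

  so large-gradient tensors take proportionally smaller steps.  This is the
  reading consistent with "adapting the learning rate based on the
  gradient's scale".
* ``literal`` — the printed update taken at face value, with ``m_hat`` in
  the denominator and ``sqrt(v_hat)`` in the numerator::

      theta <- theta - alpha / m_hat * sqrt(v_hat) / (n + eps)

  This is numerically fragile as ``m_hat -> 0``, so ``|m_hat|`` is floored
  at ``m_hat_floor`` with its sign preserved.

Both custom variants short-circuit a zero-gradient step (``n = 0``) to
``delta theta = 0`` while still advancing the moments and the step counter;
the norm-based scale is undefined there.  The functions are pure: they
return fresh arrays and a fresh state, leaving their inputs untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VARIANTS = ("standard", "norm_scaled", "literal")

#: training-config optimizer names -> update-rule variants
OPTIMIZER_NAMES = {
    "adam": "standard",
    "custom_adam": "norm_scaled",
    "custom_adam_literal": "literal",
}


@dataclass(frozen=True)
class AdamHyperparams:
    alpha: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    variant: str = "norm_scaled"
    m_hat_floor: float = 1e-12

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.beta1 < 1:
            raise ValueError("beta1 must lie in [0, 1)")
        if not 0 <= self.beta2 < 1:
            raise ValueError("beta2 must lie in [0, 1)")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not self.m_hat_floor > 0:
            raise ValueError("m_hat_floor must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )


@dataclass
class MomentState:
    """Per-parameter optimizer state: first/second moments and step count."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros_like(cls, theta: np.ndarray) -> "MomentState":
        theta = np.asarray(theta)
        return cls(
            m=np.zeros_like(theta, dtype=np.float64),
            v=np.zeros_like(theta, dtype=np.float64),
            t=0,
        )


def gradient_norm(g, name: str = "gradient") -> float:
    """Euclidean (L2/Frobenius) norm over all elements of ``g``."""
    g = np.asarray(g, dtype=np.float64)
    if g.size == 0:
        raise ValueError(f"{name} has no elements")
    if not np.all(np.isfinite(g)):
        raise ValueError(f"{name} contains non-finite elements")
    return float(np.linalg.norm(g.ravel()))


def _check_shapes(theta, g, state):
    if theta.shape != g.shape:
        raise ValueError(f"theta shape {theta.shape} != gradient shape {g.shape}")
    if state.m.shape != theta.shape or state.v.shape != theta.shape:
        raise ValueError("moment state shapes do not match the parameter")


def _advance_moments(g, state, hp):
    m = hp.beta1 * state.m + (1.0 - hp.beta1) * g
    v = hp.beta2 * state.v + (1.0 - hp.beta2) * g * g
    t = state.t + 1
    m_hat = m / (1.0 - hp.beta1 ** t)
    v_hat = v / (1.0 - hp.beta2 ** t)
    return MomentState(m, v, t), m_hat, v_hat


def adam_step(theta, g, state: MomentState, hp: AdamHyperparams):
    """One standard Adam step; returns ``(new_theta, new_state)``."""
    if hp.variant != "standard":
        raise ValueError("adam_step requires variant='standard'")
    theta = np.asarray(theta, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    gradient_norm(g)  # finiteness / emptiness check
    _check_shapes(theta, g, state)
    new_state, m_hat, v_hat = _advance_moments(g, state, hp)
    new_theta = theta - hp.alpha * m_hat / (np.sqrt(v_hat) + hp.epsilon)
    return new_theta, new_state


def custom_adam_step(theta, g, state: MomentState, hp: AdamHyperparams):
    """One gradient-norm-scaled step (``norm_scaled`` or ``literal``)."""
    if hp.variant == "standard":
        raise ValueError("variant='standard': use adam_step instead")
    theta = np.asarray(theta, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    n = gradient_norm(g)
    _check_shapes(theta, g, state)
    new_state, m_hat, v_hat = _advance_moments(g, state, hp)
    if n == 0.0:
        return theta.copy(), new_state
    if hp.variant == "norm_scaled":
        delta = (hp.alpha / (n + hp.epsilon)) * m_hat / (np.sqrt(v_hat) + hp.epsilon)
    else:  # literal
        sign = np.where(m_hat < 0, -1.0, 1.0)
        m_clamped = sign * np.maximum(np.abs(m_hat), hp.m_hat_floor)
        delta = (hp.alpha / m_clamped) * (np.sqrt(v_hat) / (n + hp.epsilon))
    return theta - delta, new_state


def step_all(
    parameters: Sequence[np.ndarray],
    gradients: Sequence[np.ndarray | None],
    states: Sequence[MomentState],
    hp: AdamHyperparams,
):
    """Apply the configured step to every parameter with a present gradient.

    Parameters whose gradient is ``None`` are returned untouched, state
    included.  The gradient norm is computed per parameter tensor, never
    globally.  Returns ``(new_parameters, new_states)`` as lists.
    """
    if not (len(parameters) == len(gradients) == len(states)):
        raise ValueError(
            f"length mismatch: {len(parameters)} parameters, "
            f"{len(gradients)} gradients, {len(states)} states"
        )
    step = adam_step if hp.variant == "standard" else custom_adam_step
    new_params, new_states = [], []
    for theta, g, st in zip(parameters, gradients, states):
        if g is None:
            new_params.append(theta)
            new_states.append(st)
        else:
            p, s = step(theta, g, st, hp)
            new_params.append(p)
            new_states.append(s)
    return new_params, new_states


class Optimizer:
    """Stateful convenience wrapper used by the training loop.

    Holds one :class:`MomentState` per parameter slot and dispatches to the
    configured variant through :func:`step_all`.
    """

    def __init__(self, name_or_hp, learning_rate: float | None = None):
        if isinstance(name_or_hp, AdamHyperparams):
            hp = name_or_hp
        else:
            if name_or_hp not in OPTIMIZER_NAMES:
                raise ValueError(
                    f"unknown optimizer {name_or_hp!r}; "
                    f"expected one of {sorted(OPTIMIZER_NAMES)}"
                )
            hp = AdamHyperparams(variant=OPTIMIZER_NAMES[name_or_hp])
        if learning_rate is not None:
            hp = replace(hp, alpha=learning_rate)
        self.hp = hp
        self._states: list[MomentState] | None = None

    def step(self, parameters, gradients):
        if self._states is None:
            self._states = [None] * len(parameters)
        if len(self._states) != len(parameters):
            raise ValueError("parameter count changed between steps")
        # states are allocated lazily: frozen parameters arrive with absent
        # gradients and never need moment buffers
        step = adam_step if self.hp.variant == "standard" else custom_adam_step
        new_params = []
        for i, (theta, g) in enumerate(zip(parameters, gradients)):
            if g is None:
                new_params.append(theta)
                continue
            if self._states[i] is None:
                self._states[i] = MomentState.zeros_like(theta)
            p, self._states[i] = step(theta, g, self._states[i], self.hp)
            new_params.append(p)
        return new_params
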