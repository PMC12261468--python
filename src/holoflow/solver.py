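"""Variance-Diminishing ODE sampler (plus a plain Euler baseline).

The learned field is an *endpoint* predictor: v(x_t, t) estimates the holo
state x1 directly. On the uniform grid t = n/i, s = (n+1)/i the update is

    x_{n+1} = clamp((1-s)/(1-t) * eta) * x_n + clamp((1 - (1-s)/(1-t)) * eta) * v(x_n, t)

with both scalar coefficients clamped into [1e-6, 1 - 1e-6]. For eta = 1
the unclamped coefficients sum to one at every step and the scheme tracks
the CondOT linear path exactly under a perfect oracle field; the clamp
keeps the final step (where (1-s)/(1-t) hits 0) well-defined and bounds how
strongly early, high-variance field evaluations can propagate to the end
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .structures import ComplexStructure, InvalidInputError

# field signature: (coords (N,3), t) -> same-shape endpoint estimate
FieldFn = Callable[[np.ndarray, float], np.ndarray]


class SolverDivergenceError(RuntimeError):
    """Field returned non-finite coordinates during integration."""


@dataclass(frozen=True)
class SolverConfig:
    n_steps: int = 40
    eta: float = 1.0
    clamp_lo: float = 1e-6
    clamp_hi: float = 1.0 - 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise InvalidInputError("n_steps must be >= 1")
        if not (self.clamp_lo < self.clamp_hi):
            raise InvalidInputError("clamp_lo must be below clamp_hi")
        if self.eta <= 0:
            raise InvalidInputError("eta must be positive")


@dataclass(frozen=True)
class Trajectory:
    """States x_0 .. x_i on the time grid t_n = n/i; states[-1] is the holo estimate."""

    states: tuple[np.ndarray, ...]
    times: tuple[float, ...]

    def __post_init__(self):
        if len(self.states) != len(self.times):
            raise InvalidInputError("states and times must have equal length")

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def vd_ode_coefficients(n: int, config: SolverConfig) -> tuple[float, float]:
    """Clamped (state, prediction) blend weights for step n -> n+1."""
    i = config.n_steps
    if not (0 <= n < i):
        raise InvalidInputError(f"step index {n} outside [0, {i})")
    t = n / i
    s = (n + 1) / i
    ratio = (1.0 - s) / (1.0 - t)
    a = float(np.clip(ratio * config.eta, config.clamp_lo, config.clamp_hi))
    b = float(np.clip((1.0 - ratio) * config.eta, config.clamp_lo, config.clamp_hi))
    return a, b


def vd_ode_step(
    x_n: np.ndarray, endpoint_pred: np.ndarray, n: int, config: SolverConfig
) -> np.ndarray:
    """One VD-ODE update blending the current state with the endpoint estimate."""
    a, b = vd_ode_coefficients(n, config)
    return a * np.asarray(x_n, float) + b * np.asarray(endpoint_pred, float)


def _check_finite(x: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(x)):
        raise SolverDivergenceError(f"field returned non-finite coordinates at step {step}")


def _resolve_start(prior_sample) -> np.ndarray:
    if isinstance(prior_sample, ComplexStructure):
        return prior_sample.all_coords()
    return np.asarray(prior_sample, float)


def integrate(
    prior_sample,
    field: FieldFn,
    config: SolverConfig = SolverConfig(),
    log: Callable[[str], None] | None = None,
) -> Trajectory:
    """Integrate the VD-ODE from the prior draw (t=0) to the holo estimate (t=1).

    ``prior_sample`` may be a ComplexStructure or a bare (N, 3) array;
    deterministic given the start state and field.
    """
    x = _resolve_start(prior_sample)
    i = config.n_steps
    states = [x.copy()]
    times = [0.0]
    for n in range(i):
        t = n / i
        pred = np.asarray(field(x, t), float)
        if pred.shape != x.shape:
            raise InvalidInputError(
                f"field returned shape {pred.shape}, expected {x.shape}"
            )
        _check_finite(pred, n)
        a, b = vd_ode_coefficients(n, config)
        x = a * x + b * pred
        if log is not None:
            disp = float(np.linalg.norm(x - states[-1], axis=1).mean())
            log(f"step {n:3d} t={t:.3f} a={a:.6f} b={b:.6f} mean_disp={disp:.4f}")
        states.append(x.copy())
        times.append((n + 1) / i)
    return Trajectory(states=tuple(states), times=tuple(times))


def euler_integrate(
    prior_sample,
    field: FieldFn,
    config: SolverConfig = SolverConfig(),
) -> Trajectory:
    """Plain Euler baseline on the velocity induced by the endpoint field.

    The endpoint parametrization induces the velocity (v(x_t, t) - x_t)/(1-t)
    along the CondOT path; this integrates x' = u with step 1/i and no
    coefficient clamping.
    """
    x = _resolve_start(prior_sample)
    i = config.n_steps
    states = [x.copy()]
    times = [0.0]
    for n in range(i):
        t = n / i
        pred = np.asarray(field(x, t), float)
        if pred.shape != x.shape:
            raise InvalidInputError(
                f"field returned shape {pred.shape}, expected {x.shape}"
            )
        _check_finite(pred, n)
        velocity = (pred - x) / (1.0 - t)
        x = x + velocity / i
        states.append(x.copy())
        times.append((n + 1) / i)
    return Trajectory(states=tuple(states), times=tuple(times))
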