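"""Numerical integration of the diffeomorphic flow ODE.

The direct map is the unit-time flow of the stationary velocity field,
discretized with K forward-Euler steps; the inverse map integrates
backward in time with the explicit modified-Euler scheme (the default)
or with the implicit backward-Euler scheme solved by fixed-point
iteration, which inverts the forward scheme exactly and serves as the
module's oracle.  Points are never re-clamped to the unit cube during
integration (that would break invertibility); the code lookup clamps
internally instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tape import Var, as_var
from .cloud import WeightedPointCloud
from .network import VelocityFieldModel, lerp_code

__all__ = [
    "FlowTrajectory",
    "IntegrationError",
    "forward_map",
    "inverse_map_explicit",
    "inverse_map_implicit",
    "geodesic_frames",
    "kinetic_energy",
    "integrate_forward_var",
    "integrate_backward_var",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class FlowTrajectory:
    """K+1 states of a point set; the endpoint is the mapped cloud.

    For ``direction == "forward"`` states[0] is the input and states[K]
    the image phi(S); for ``"backward"`` states[K] is the input and
    states[0] the image phi^{-1}(T).  ``velocities[k]`` is the logged
    velocity of the step between states[k] and states[k+1], so that
    states[k+1] - states[k] = +- velocities[k] / K.
    """

    states: np.ndarray  # (K+1, P, 3)
    velocities: np.ndarray  # (K, P, 3)
    direction: str
    K: int

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1] if self.direction == "forward" else self.states[0]


def _field(model: VelocityFieldModel, code, x: Var) -> Var:
    """Velocity with the position-aware code re-interpolated at x."""
    zbar = lerp_code(x, code, model.config.g_z)
    return model.velocity(x, zbar)


def _check_finite(v: np.ndarray, step: int, scheme: str):
    if not np.all(np.isfinite(v)):
        raise IntegrationError(f"non-finite velocity at step {step} ({scheme})")


# ---------------------------------------------------------------------------
# differentiable cores (used by the trainer)


def integrate_forward_var(
    model: VelocityFieldModel, code, x0: Var, K: int
) -> tuple[list[Var], list[Var]]:
    """Forward Euler: x^{(k+1)} = x^{(k)} + v(x^{(k)})/K.  Returns all
    K+1 states and the K logged velocities (tape variables)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    states = [as_var(x0)]
    vels = []
    for k in range(K):
        v = _field(model, code, states[-1])
        _check_finite(v.data, k, "forward Euler")
        vels.append(v)
        states.append(states[-1] + v * (1.0 / K))
    return states, vels


def integrate_backward_var(
    model: VelocityFieldModel, code, xK: Var, K: int
) -> tuple[list[Var], list[Var]]:
    """Modified Euler, backward in time:
    x^{(k-1)} = x^{(k)} - v(x^{(k)} - v(x^{(k)})/K)/K.
    Returns states ordered from the input (index 0 = x^{(K)}) down to the
    endpoint, and the K logged outer velocities v^{t,(K)}, ..., v^{t,(1)}."""
    if K < 1:
        raise ValueError("K must be >= 1")
    states = [as_var(xK)]
    vels = []
    for k in range(K, 0, -1):
        x = states[-1]
        inner = x - _field(model, code, x) * (1.0 / K)
        v = _field(model, code, inner)
        _check_finite(v.data, k, "modified Euler")
        vels.append(v)
        states.append(x - v * (1.0 / K))
    return states, vels


# ---------------------------------------------------------------------------
# public numpy API


def forward_map(
    points: np.ndarray, model: VelocityFieldModel, code: np.ndarray, K: int = 10
) -> FlowTrajectory:
    """Direct map phi(S): all intermediate frames are retained so the
    geodesic path can be visualized."""
    states, vels = integrate_forward_var(model, as_var(code), as_var(points), K)
    return FlowTrajectory(
        states=np.stack([s.data for s in states]),
        velocities=np.stack([v.data for v in vels]),
        direction="forward",
        K=K,
    )


def inverse_map_explicit(
    points: np.ndarray, model: VelocityFieldModel, code: np.ndarray, K: int = 10
) -> FlowTrajectory:
    """Inverse map phi^{-1}(T) by the modified-Euler scheme."""
    states, vels = integrate_backward_var(model, as_var(code), as_var(points), K)
    # states run input -> endpoint; store in pseudo-time order (endpoint first)
    ordered = [s.data for s in reversed(states)]
    vel_ordered = [v.data for v in reversed(vels)]
    return FlowTrajectory(
        states=np.stack(ordered),
        velocities=np.stack(vel_ordered),
        direction="backward",
        K=K,
    )


def inverse_map_implicit(
    points: np.ndarray,
    model: VelocityFieldModel,
    code: np.ndarray,
    K: int = 10,
    tol: float = 1e-10,
    max_inner: int = 200,
) -> FlowTrajectory:
    """Implicit backward Euler x^{(k-1)} = x^{(k)} - v(x^{(k-1)})/K solved by
    fixed-point iteration, warm-started at the modified-Euler estimate.

    This is the exact inverse of the forward scheme (to solver tolerance);
    it converges when the per-step contraction Lip(v)/K < 1.
    """
    code_v = as_var(np.asarray(code))
    x = np.asarray(points, dtype=np.float64)
    states = [x]
    vels = []
    for k in range(K, 0, -1):
        xk = states[-1]
        # warm start: modified-Euler estimate
        v_inner = _field(model, code_v, as_var(xk)).data
        y = xk - _field(model, code_v, as_var(xk - v_inner / K)).data / K
        converged = False
        for _ in range(max_inner):
            v = _field(model, code_v, as_var(y)).data
            _check_finite(v, k, "implicit backward Euler")
            y_new = xk - v / K
            if np.max(np.abs(y_new - y)) < tol:
                y = y_new
                converged = True
                break
            y = y_new
        if not converged:
            resid = np.max(np.abs(xk - y - _field(model, code_v, as_var(y)).data / K))
            raise IntegrationError(
                f"fixed-point iteration did not converge at step {k}; "
                f"max per-point residual {resid:.3e}"
            )
        vels.append(_field(model, code_v, as_var(y)).data)
        states.append(y)
    ordered = list(reversed(states))
    vel_ordered = list(reversed(vels))
    return FlowTrajectory(
        states=np.stack(ordered),
        velocities=np.stack(vel_ordered),
        direction="backward",
        K=K,
    )


def geodesic_frames(
    trajectory: FlowTrajectory,
    source: WeightedPointCloud,
    indices: list[int] | None = None,
) -> list[WeightedPointCloud]:
    """Intermediate integration frames as clouds carrying the source weights."""
    if indices is None:
        indices = list(range(trajectory.K + 1))
    frames = []
    for i in indices:
        if not 0 <= i <= trajectory.K:
            raise IndexError(f"frame index {i} out of range [0, {trajectory.K}]")
        frames.append(source.with_points(trajectory.states[i]))
    return frames


def kinetic_energy(trajectory: FlowTrajectory) -> float:
    """Sum of squared logged velocities over all points and steps."""
    return float((trajectory.velocities**2).sum())
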