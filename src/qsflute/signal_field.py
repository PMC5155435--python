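"""AHL signal-field dynamics in one spatial dimension.

The signal concentration C(x, t) obeys

    dC/dt = D_s d2C/dx2 + alpha*rho_P - (k_e + k_b(rho_R)) * C

on 0 <= x <= h, with an absorbing (Dirichlet C = 0) boundary at the open
face x = 0 and a reflecting (zero-flux) boundary at the air face x = h.
At stationarity the closed-form solution is

    C(x) = C_inf * [1 - cosh((h - x)/lambda) / cosh(h/lambda)],

with plateau C_inf = alpha*rho_P/k_tot and penetration depth
lambda = sqrt(D_s/k_tot).  Populations extending less than ~lambda from the
open boundary are strongly drained and may never reach quorum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError, DomainError, FieldState, Grid1D, ModelParams

__all__ = [
    "characteristic_length",
    "SteadyProfile",
    "steady_state_profile",
    "short_height_limit",
    "stable_dt",
    "simulate_signal",
]


def characteristic_length(D: float, k_tot: float) -> float:
    """Signal penetration depth sqrt(D/k_tot) [mm] from an absorbing boundary."""
    if D <= 0:
        raise DomainError(f"diffusivity must be positive, got {D}")
    if k_tot <= 0:
        raise DomainError(f"total degradation rate must be positive, got {k_tot}")
    return float(np.sqrt(D / k_tot))


@dataclass(frozen=True)
class SteadyProfile:
    """Stationary signal profile on a grid."""

    grid: Grid1D
    C: np.ndarray       # nM at each node
    lam: float          # penetration depth, mm
    C_inf: float        # plateau concentration alpha*rho_P/k_tot, nM


def steady_state_profile(params: ModelParams, grid: Grid1D) -> SteadyProfile:
    """Closed-form stationary signal profile (cosh solution)."""
    k_tot = params.k_tot
    if k_tot <= 0:
        raise DomainError(
            "k_tot = 0: no stationary profile exists under pure diffusion with "
            "constant production; use simulate_signal for the transient field"
        )
    lam = characteristic_length(params.D_s, k_tot)
    C_inf = params.alpha * params.rho_P / k_tot
    x = grid.x
    # cosh ratio evaluated stably: cosh(a)/cosh(b) = exp(a-b)*(1+exp(-2a))/(1+exp(-2b))
    a = (grid.h - x) / lam
    b = grid.h / lam
    ratio = np.exp(a - b) * (1.0 + np.exp(-2.0 * a)) / (1.0 + np.exp(-2.0 * b))
    C = C_inf * (1.0 - ratio)
    return SteadyProfile(grid=grid, C=C, lam=lam, C_inf=C_inf)


def short_height_limit(params: ModelParams, h: float, x: float) -> float:
    """Stationary signal in the short-column limit h << lambda.

    Degradation is negligible below the penetration depth and the profile
    becomes the parabola ``(alpha*rho_P/D_s) * (h*x - x^2/2)``, with top value
    ``alpha*rho_P*h^2/(2*D_s)``.
    """
    if h <= 0:
        raise DomainError("height must be positive")
    if not (0 <= x <= h):
        raise DomainError(f"x={x} outside [0, {h}]")
    return params.alpha * params.rho_P / params.D_s * (h * x - x * x / 2.0)


def stable_dt(grid: Grid1D, D_max: float, safety: float = 0.4) -> float:
    """Default explicit-Euler step: ``safety * dx^2 / D_max`` [h]."""
    if D_max <= 0:
        raise DomainError("diffusivity must be positive")
    return safety * grid.dx ** 2 / D_max


def _check_dt(dt: float, grid: Grid1D, D_max: float) -> None:
    if dt <= 0:
        raise ConfigError("dt must be positive")
    if dt > grid.dx ** 2 / (2.0 * D_max) + 1e-15:
        raise ConfigError(
            f"dt={dt} violates the FTCS stability bound dx^2/(2*D) = "
            f"{grid.dx ** 2 / (2.0 * D_max)}"
        )


def simulate_signal(
    params: ModelParams,
    grid: Grid1D,
    t_end: float,
    dt: float | None = None,
) -> FieldState:
    """Integrate the transient signal field from C = 0 to ``t_end`` [h].

    Explicit forward-time centered-space scheme; Dirichlet 0 at the open
    face, mirror-node (second-order zero-flux) at the air face.  Returns a
    :class:`FieldState` with the signal in ``C`` and the other species zero.
    """
    if t_end <= 0:
        raise ConfigError("t_end must be positive")
    if dt is None:
        dt = stable_dt(grid, params.D_s)
    _check_dt(dt, grid, params.D_s)

    n = grid.n_nodes
    inv_dx2 = 1.0 / grid.dx ** 2
    source = params.alpha * params.rho_P
    k_tot = params.k_tot
    C = np.zeros(n)
    lap = np.empty(n)
    n_steps = int(np.ceil(t_end / dt - 1e-9))
    for step in range(n_steps):
        step_dt = min(dt, t_end - step * dt)
        lap[1:-1] = (C[2:] - 2.0 * C[1:-1] + C[:-2]) * inv_dx2
        lap[-1] = 2.0 * (C[-2] - C[-1]) * inv_dx2
        lap[0] = 0.0
        C += step_dt * (params.D_s * lap + source - k_tot * C)
        C[0] = 0.0
    zeros = np.zeros(n)
    return FieldState(t=t_end, grid=grid, C=C, E=zeros.copy(), ES=zeros.copy(),
                      S=zeros.copy(), P=zeros.copy())
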