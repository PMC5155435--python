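"""Reporter activation and the enzyme-substrate-product cascade.

Signal above the quorum threshold activates a fraction of reporter cells
given by a Hill function; activated cells produce beta-galactosidase (E),
which cleaves the chromogenic substrate X-gal (S) into the blue product (P)
through an explicit enzyme-substrate complex (ES):

    E + S  <->[k1, k_m1]  ES  ->[k2]  E + P

E and ES are cell-associated and do not diffuse; S and P diffuse with
diffusivity D_x under the same boundary conditions as the signal (Dirichlet
0 at the open face, zero flux at the air face).  No quasi-steady-state
reduction is applied: the enzyme is absent at t = 0 and builds up slowly
once quorum is reached, so the dynamics are not standard Michaelis-Menten.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ConfigError,
    DomainError,
    FieldState,
    Grid1D,
    IntegrationError,
    ModelParams,
)
from .signal_field import stable_dt

__all__ = [
    "hill_fraction",
    "enzyme_production_rate",
    "CascadeState",
    "simulate_cascade",
    "simulate_columns",
]


def hill_fraction(C, C_star: float, m: int):
    """Fraction of activated reporter cells, ``C^m / (C_star^m + C^m)``.

    Promoter occupancy is treated as an instantaneous equilibrium of the
    concerted binding of ``m`` signal molecules.
    """
    if C_star <= 0:
        raise DomainError(f"C_star must be positive, got {C_star}")
    if m < 1:
        raise DomainError(f"Hill cooperativity must be >= 1, got {m}")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise DomainError("signal concentration must be >= 0")
    r = (C / C_star) ** m
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def enzyme_production_rate(C, params: ModelParams):
    """Volumetric enzyme production rate ``A_tot * f(C)`` [nM/h]."""
    return params.A_tot * hill_fraction(C, params.C_star, params.m)


@dataclass
class CascadeState(FieldState):
    """Five-species field plus the cumulative enzyme production E_cum [nM]."""

    E_cum: np.ndarray = None

    def __post_init__(self) -> None:
        if self.E_cum is None:
            self.E_cum = np.zeros(self.grid.n_nodes)
        self.E_cum = np.asarray(self.E_cum, dtype=float)
        super().__post_init__()


def _masked_laplacian(u, top, inv_dx2, valid, out):
    """Centered second difference with a mirror node at each column's top."""
    out[:, 1:-1] = (u[:, 2:] - 2.0 * u[:, 1:-1] + u[:, :-2]) * inv_dx2
    out[:, 0] = 0.0
    out[:, -1] = 0.0
    rows = np.arange(u.shape[0])
    out[rows, top] = 2.0 * (u[rows, top - 1] - u[rows, top]) * inv_dx2
    out *= valid


def simulate_columns(
    params: ModelParams,
    cells: list,
    dx: float,
    record_times,
    dt: float | None = None,
    closed_system: bool = False,
    initial_E: float = 0.0,
):
    """Co-integrate the full cascade for many columns at once.

    Parameters
    ----------
    cells : list of (rho_P, h)
        Producer density and column height of each column; all columns share
        the node spacing ``dx`` and the time step.
    record_times : sequence of floats
        Times [h] at which to snapshot all species (sorted internally).
    closed_system : bool
        If True, disable diffusion and the draining boundary (well-mixed
        0-D variant used for oracle checks; S + P + ES is then conserved).
    initial_E : float
        Free enzyme present at t = 0 [nM] (0 in the assay; nonzero for
        classical progress-curve checks).

    Returns
    -------
    list of dict
        One entry per recorded time with keys ``t, C, E, ES, S, P, E_cum``;
        arrays have shape ``(n_columns, n_nodes_max)`` and entries beyond a
        column's own top node are zero.
    """
    if not cells:
        raise ConfigError("no columns to integrate")
    record = sorted(float(t) for t in record_times)
    if not record or record[0] <= 0:
        raise ConfigError("record times must be positive")
    grids = [Grid1D(h=h, dx=dx) for _, h in cells]
    n_nodes = np.array([g.n_nodes for g in grids])
    B, N = len(cells), int(n_nodes.max())
    top = n_nodes - 1
    rows = np.arange(B)
    valid = (np.arange(N)[None, :] < n_nodes[:, None]).astype(float)
    rho = np.array([c[0] for c in cells], dtype=float)[:, None]

    D_max = max(params.D_s, params.D_x)
    ref_grid = grids[int(np.argmax(n_nodes))]
    if dt is None:
        dt = stable_dt(ref_grid, D_max)
    if dt > dx ** 2 / (2.0 * D_max) + 1e-15:
        raise ConfigError(
            f"dt={dt} violates the FTCS stability bound dx^2/(2*max(D_s, D_x)) = "
            f"{dx ** 2 / (2.0 * D_max)}"
        )

    inv_dx2 = 1.0 / dx ** 2
    C = np.zeros((B, N))
    E = np.full((B, N), float(initial_E)) * valid
    ES = np.zeros((B, N))
    S = params.S0 * valid
    P = np.zeros((B, N))
    E_cum = E.copy()
    if not closed_system:
        S[:, 0] = 0.0
    lapC = np.zeros((B, N))
    lapS = np.zeros((B, N))
    lapP = np.zeros((B, N))

    k_tot = params.k_tot
    neg_tol = -1e-9 * max(params.S0, 1.0)
    out = []
    ri = 0
    n_steps = int(np.ceil(record[-1] / dt - 1e-9))
    t = 0.0
    for step in range(n_steps):
        if closed_system:
            lapC.fill(0.0)
            lapS.fill(0.0)
            lapP.fill(0.0)
        else:
            _masked_laplacian(C, top, inv_dx2, valid, lapC)
            _masked_laplacian(S, top, inv_dx2, valid, lapS)
            _masked_laplacian(P, top, inv_dx2, valid, lapP)
        f = hill_fraction(C, params.C_star, params.m)
        prod = params.A_tot * f * valid
        bind = params.k1 * E * S
        unbind = params.k_m1 * ES
        cat = params.k2 * ES
        C += dt * (params.D_s * lapC + params.alpha * rho * valid - k_tot * C)
        E += dt * (prod - bind + unbind + cat)
        ES += dt * (bind - unbind - cat)
        S += dt * (params.D_x * lapS - bind + unbind)
        P += dt * (params.D_x * lapP + cat)
        E_cum += dt * prod
        if not closed_system:
            C[:, 0] = 0.0
            S[:, 0] = 0.0
            P[:, 0] = 0.0
        t = (step + 1) * dt
        if step % 512 == 0 or step == n_steps - 1:
            worst = min(C.min(), E.min(), ES.min(), S.min(), P.min())
            if worst < neg_tol:
                bad = int(np.argmin(np.minimum.reduce(
                    [C.min(1), E.min(1), ES.min(1), S.min(1), P.min(1)])))
                raise IntegrationError(
                    f"negative concentration {worst:.3e} nM at t={t:.2f} h in "
                    f"column (rho_P={cells[bad][0]:g}, h={cells[bad][1]:g} mm)"
                )
        while ri < len(record) and t >= record[ri] - 1e-9:
            out.append({
                "t": record[ri],
                "C": C.copy(), "E": E.copy(), "ES": ES.copy(),
                "S": S.copy(), "P": P.copy(), "E_cum": E_cum.copy(),
            })
            ri += 1
    return out


def simulate_cascade(
    params: ModelParams,
    grid: Grid1D,
    t_end: float,
    dt: float | None = None,
    record_times=None,
    closed_system: bool = False,
    initial_E: float = 0.0,
) -> list:
    """Integrate the coupled cascade in one column; return recorded states.

    ``record_times`` defaults to ``[t_end]``.  See :func:`simulate_columns`
    for the scheme and options.
    """
    if record_times is None:
        record_times = [t_end]
    if max(record_times) > t_end + 1e-9:
        raise ConfigError("record times must not exceed t_end")
    snaps = simulate_columns(
        params, [(params.rho_P, grid.h)], grid.dx, record_times,
        dt=dt, closed_system=closed_system, initial_E=initial_E,
    )
    states = []
    for s in snaps:
        states.append(CascadeState(
            t=s["t"], grid=grid,
            C=s["C"][0], E=s["E"][0], ES=s["ES"][0],
            S=s["S"][0], P=s["P"][0], E_cum=s["E_cum"][0],
        ))
    return states
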