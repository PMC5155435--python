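"""Signal-degradation assay models.

Well-mixed suspension decay (Eppendorf incubations read out through a
fivefold dilution series on the reporter), the effective-degradation-time
algebra for equivalent dilution/time pairs, and the radial plate-diffusion
halo of a signal drop deposited on a cell-embedded agar slab.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DomainError, ModelParams, k_b
from .cascade import hill_fraction

__all__ = [
    "decay_remaining",
    "DilutionAssay",
    "predict_wells",
    "estimate_tau",
    "PlateAssay",
    "plate_halo_radius",
]


def decay_remaining(
    C0: float,
    rho: float,
    t: float,
    params: ModelParams,
    include_chemical: bool = True,
) -> float:
    """Signal remaining after suspension decay, ``C0*exp(-(k_e+k_b(rho))*t)``.

    The suspension is treated as well mixed (no spatial structure); chemical
    decay can be excluded for short saline incubations where it is below
    assay resolution.
    """
    if C0 < 0 or t < 0:
        raise DomainError("C0 and t must be >= 0")
    k = k_b(rho, params) + (params.k_e if include_chemical else 0.0)
    return C0 * math.exp(-k * t)


@dataclass(frozen=True)
class DilutionAssay:
    """Design of the dilution-series reporter readout.

    ``dilutions`` are multiplicative factors applied to the supernatant
    before feeding the reporter, strictly decreasing from 1 (undiluted).
    """

    densities: tuple
    exposure_times: tuple
    initial_C0: float
    dilutions: tuple = (1.0, 1.0 / 5.0, 1.0 / 25.0, 1.0 / 125.0)

    def __post_init__(self) -> None:
        for name in ("densities", "exposure_times", "dilutions"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        if self.initial_C0 < 0:
            raise DomainError("initial concentration must be >= 0")
        d = self.dilutions
        if not d or d[0] != 1.0 or any(b >= a for a, b in zip(d, d[1:])) or d[-1] <= 0:
            raise DomainError("dilutions must decrease strictly from 1 and stay positive")


def predict_wells(
    assay: DilutionAssay,
    C_star: float,
    params: ModelParams,
    graded: bool = False,
) -> np.ndarray:
    """Predicted reporter response per (density, exposure time, dilution).

    A well responds iff the diluted post-decay concentration reaches the
    quorum threshold; with ``graded=True`` the Hill activation fraction is
    returned instead of a boolean.
    """
    out = np.empty((len(assay.densities), len(assay.exposure_times), len(assay.dilutions)))
    for i, rho in enumerate(assay.densities):
        for j, t in enumerate(assay.exposure_times):
            rem = decay_remaining(assay.initial_C0, rho, t, params)
            for k, d in enumerate(assay.dilutions):
                conc = d * rem
                out[i, j, k] = (
                    hill_fraction(conc, C_star, params.m) if graded else conc >= C_star
                )
    return out if graded else out.astype(bool)


def estimate_tau(pair_a, pair_b) -> float:
    """Effective degradation time from two equivalent (dilution, time) pairs.

    If dilution ``d_a`` exposed for ``t_a`` gives the same reporter response
    as ``d_b`` exposed for ``t_b``, a single-exponential decay implies
    ``d_a*exp(-t_a/tau) = d_b*exp(-t_b/tau)``, i.e.
    ``tau = (t_a - t_b) / ln(d_a/d_b)`` [h].  The undiluted/1-day vs
    1/25-diluted/1-hour equivalence gives 23/ln(25), about 7.15 h.
    """
    d_a, t_a = pair_a
    d_b, t_b = pair_b
    if d_a <= 0 or d_b <= 0 or t_a < 0 or t_b < 0:
        raise DomainError("dilutions must be positive and times >= 0")
    if t_a == t_b:
        raise DomainError("equal exposure times leave tau undefined")
    if d_a == d_b:
        raise DomainError("equal dilutions at different times are inconsistent")
    tau = (t_a - t_b) / math.log(d_a / d_b)
    if tau <= 0:
        raise DomainError(
            f"pairs imply a non-positive degradation time ({tau:.3g} h); "
            "the observations are inconsistent with exponential decay"
        )
    return tau


@dataclass(frozen=True)
class PlateAssay:
    """Point deposit of signal diffusing in a thin cell-embedded agar slab.

    The plate is modelled as a 2-D slab of uniform thickness (plate volume /
    plate area; 20 ml in a standard 8.5 cm dish gives about 3.5 mm).
    """

    Q_ng: float = 100.0
    rho: float = 0.0
    t_diffuse: float = 6.0
    slab_thickness: float = 20e3 / (math.pi * 42.5 ** 2)
    mw: float = 227.3

    def __post_init__(self) -> None:
        if min(self.Q_ng, self.t_diffuse, self.slab_thickness, self.mw) <= 0:
            raise DomainError("plate assay quantities must be positive")
        if self.rho < 0:
            raise DomainError("cell density must be >= 0")


def plate_halo_radius(assay: PlateAssay, C_star: float, params: ModelParams) -> float:
    """Radius [mm] out to which the deposited signal still reaches quorum.

    The drop is an instantaneous point source in the slab:

        C(r, t) = Q / (4*pi*D*t*d) * exp(-r^2/(4*D*t)) * exp(-k*t)

    with D the signal diffusivity, d the slab thickness and
    k = k_e + k_b(rho).  Returns 0 when even the center is below threshold.
    """
    if C_star <= 0:
        raise DomainError("C_star must be positive")
    D, t, d = params.D_s, assay.t_diffuse, assay.slab_thickness
    q_nmol = assay.Q_ng / assay.mw                      # ng / (g/mol) = nmol
    k = params.k_e + k_b(assay.rho, params)
    # nmol/mm^3 -> nM: 1 nmol/mm^3 = 1e-6 mol/l = 1e6 nM
    center = q_nmol / (4.0 * math.pi * D * t * d) * 1e6 * math.exp(-k * t)
    if center < C_star:
        return 0.0
    return math.sqrt(4.0 * D * t * math.log(center / C_star))
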