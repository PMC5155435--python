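"""Canonical units, parameter containers and experiment geometry.

Canonical units throughout the package: length mm, time h, concentration nM,
cell density cells/ml, diffusivity mm^2/h.  These make every quantity of the
modelled system O(1)-O(100): the characteristic signal penetration depth is
3 mm, tube heights span 2-20 mm, observations happen at 48-120 h.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "MW_OHL",
    "MW_XGAL",
    "XGAL_UG_PER_ML",
    "DomainError",
    "ConfigError",
    "IntegrationError",
    "ModelParams",
    "Grid1D",
    "FieldState",
    "PanFluteDesign",
    "default_params",
    "load_calibration",
    "k_b",
    "density_from_total",
    "ng_per_ml_to_nM",
    "nM_to_ng_per_ml",
    "einstein_stokes_ratio",
]

#: molecular weight of N-octanoyl-L-homoserine lactone (OHL), g/mol
MW_OHL = 227.3
#: molecular weight of X-gal (5-bromo-4-chloro-3-indolyl-beta-D-galactopyranoside), g/mol
MW_XGAL = 408.63
#: X-gal working concentration in the gel, ug/ml
XGAL_UG_PER_ML = 60.0


class DomainError(ValueError):
    """An argument is outside its physically meaningful domain."""


class ConfigError(ValueError):
    """A configuration (grid, time step, search space, ...) is invalid."""


class IntegrationError(RuntimeError):
    """A numerical integration produced an unusable state."""


def ng_per_ml_to_nM(conc_ng_per_ml: float, mw_g_per_mol: float) -> float:
    """Convert a mass concentration (ng/ml) to molarity (nM)."""
    if mw_g_per_mol <= 0:
        raise DomainError("molecular weight must be positive")
    return conc_ng_per_ml * 1e3 / mw_g_per_mol


def nM_to_ng_per_ml(conc_nM: float, mw_g_per_mol: float) -> float:
    """Convert a molarity (nM) to mass concentration (ng/ml)."""
    if mw_g_per_mol <= 0:
        raise DomainError("molecular weight must be positive")
    return conc_nM * mw_g_per_mol / 1e3


def einstein_stokes_ratio(mw_light: float = MW_OHL, mw_heavy: float = MW_XGAL) -> float:
    """Diffusivity ratio D_heavy/D_light of two spherical molecules.

    By the Einstein-Stokes relation D ~ 1/r and r ~ M^(1/3), so the ratio is
    (M_light/M_heavy)^(1/3).  For OHL vs X-gal this evaluates to 0.822; the
    shipped default D_x/D_s follows the conventional rounded value 0.83.
    """
    if mw_light <= 0 or mw_heavy <= 0:
        raise DomainError("molecular weights must be positive")
    return (mw_light / mw_heavy) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the quorum-sensing reaction-diffusion model.

    Attributes
    ----------
    alpha : float
        AHL production rate per producer cell [nM*ml/(cell*h)].
    D_s : float
        AHL diffusivity in the gel [mm^2/h].
    k_e : float
        Abiotic (chemical) AHL degradation rate [1/h].
    k_b_ref : float
        Biotic AHL degradation rate at the reference density [1/h].
    rho_ref : float
        Reference cell density for ``k_b_ref`` [cells/ml].
    rho_P, rho_R : float
        Producer and reporter densities [cells/ml].
    C_star : float
        Quorum activation threshold [nM].
    m : int
        Hill cooperativity (dimensionless, >= 1).
    A_tot : float
        Maximum volumetric enzyme production rate, i.e. maximum promoter
        activity times reporter density [nM/h].
    k1, k_m1, k2 : float
        Mass-action rates of E + S <-> ES -> E + P
        [1/(nM*h), 1/h, 1/h respectively].
    D_x : float
        Substrate and cleaved-product diffusivity [mm^2/h].
    S0 : float
        Initial X-gal concentration [nM].
    """

    alpha: float
    D_s: float
    k_e: float
    k_b_ref: float
    rho_ref: float
    rho_P: float
    rho_R: float
    C_star: float
    m: int
    A_tot: float
    k1: float
    k_m1: float
    k2: float
    D_x: float
    S0: float
    allow_free_D_x: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "D_s", "k_e", "k_b_ref", "rho_ref", "rho_P",
                     "rho_R", "C_star", "A_tot", "k1", "k_m1", "k2", "D_x", "S0"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.m < 1:
            raise DomainError(f"Hill cooperativity m must be >= 1, got {self.m}")
        if not self.allow_free_D_x and not (
            0.8 * self.D_s <= self.D_x <= self.D_s
        ):
            raise DomainError(
                "D_x must lie in [0.8*D_s, D_s] (Einstein-Stokes band); "
                "pass allow_free_D_x=True to override"
            )

    @property
    def k_tot(self) -> float:
        """Total AHL degradation rate k_e + k_b(rho_R) [1/h]."""
        return self.k_e + k_b(self.rho_R, self)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["m"] = int(d["m"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D discretization of one gel cylinder.

    The open (signal-draining) face is node 0 at x = 0; the face in contact
    with air is the last node at x = h and is treated as reflecting.
    """

    h: float
    dx: float = 0.1
    bc_bottom: str = "absorbing"
    bc_top: str = "reflecting"

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ConfigError(f"height must be positive, got {self.h}")
        if not (0 < self.dx <= self.h / 10 + 1e-12):
            raise ConfigError(
                f"node spacing dx={self.dx} must satisfy 0 < dx <= h/10 = {self.h / 10}"
            )
        if abs(self.h / self.dx - round(self.h / self.dx)) > 1e-9:
            raise ConfigError(f"height {self.h} is not an integer multiple of dx={self.dx}")
        if self.bc_bottom != "absorbing" or self.bc_top != "reflecting":
            raise ConfigError("only absorbing-bottom / reflecting-top grids are supported")

    @property
    def n_nodes(self) -> int:
        return int(round(self.h / self.dx)) + 1

    @property
    def x(self) -> np.ndarray:
        """Node positions from the open face (0) to the air face (h) [mm]."""
        return np.linspace(0.0, self.h, self.n_nodes)


@dataclass
class FieldState:
    """Concentrations of the five species on a grid at one time [nM]."""

    t: float
    grid: Grid1D
    C: np.ndarray
    E: np.ndarray
    ES: np.ndarray
    S: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_nodes
        for name in ("C", "E", "ES", "S", "P"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ConfigError(f"{name} has shape {arr.shape}, expected ({n},)")


@dataclass(frozen=True)
class PanFluteDesign:
    """The height x density x observation-time design of the tube array."""

    heights: tuple = tuple(float(h) for h in range(2, 21, 2))
    densities: tuple = (1e3, 1e4, 1e5, 1e6)
    obs_times: tuple = (48.0, 72.0, 96.0)

    def __post_init__(self) -> None:
        for name in ("heights", "densities", "obs_times"):
            vals = tuple(float(v) for v in getattr(self, name))
            object.__setattr__(self, name, vals)
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ConfigError(f"{name} must be strictly increasing")
            if not vals or vals[0] <= 0:
                raise ConfigError(f"{name} must be non-empty and positive")

    @property
    def shape(self) -> tuple:
        return (len(self.densities), len(self.heights), len(self.obs_times))


def load_calibration() -> dict:
    """Load the shipped calibrated parameter file (fitted rates + thresholds)."""
    text = resources.files("qsflute").joinpath("data/calibrated_params.json").read_text()
    return json.loads(text)


def default_params() -> ModelParams:
    """The package's calibrated default parameter set.

    Printed-constraint anchors: biotic degradation (10 h)^-1 at 1e8 cells/ml,
    chemical degradation (7 d)^-1, signal penetration depth
    sqrt(D_s/k_tot) = 3.0 mm (fixes D_s), D_x = 0.83*D_s, m = 1, X-gal at
    60 ug/ml.  The remaining six rates come from the shipped calibration,
    which reproduces the observed activation boundaries of the tube assay
    (see :mod:`qsflute.pipeline`).
    """
    cal = load_calibration()["fitted"]
    k_e = 1.0 / 168.0           # 7-day chemical decay
    k_b_ref = 0.1               # (10 h)^-1 at the reporter density
    lam = 3.0                   # mm, target penetration depth
    D_s = lam ** 2 * (k_e + k_b_ref)
    return ModelParams(
        alpha=cal["alpha"],
        D_s=D_s,
        k_e=k_e,
        k_b_ref=k_b_ref,
        rho_ref=1e8,
        rho_P=1e6,
        rho_R=1e8,
        C_star=cal["C_star"],
        m=int(cal["m"]),
        A_tot=cal["A_tot"],
        k1=cal["k1"],
        k_m1=cal["k_m1"],
        k2=cal["k2"],
        D_x=0.83 * D_s,
        S0=ng_per_ml_to_nM(XGAL_UG_PER_ML * 1e3, MW_XGAL),
    )


def k_b(rho: float, params: ModelParams) -> float:
    """Biotic AHL degradation rate at cell density ``rho`` [1/h].

    Linear in density through the origin:
    ``k_b(rho) = k_b_ref * rho / rho_ref``.
    """
    if rho < 0:
        raise DomainError(f"cell density must be >= 0, got {rho}")
    return params.k_b_ref * rho / params.rho_ref


def density_from_total(total_cells: float, volume_ul: float) -> float:
    """Cell density [cells/ml] from a total cell count in a volume [ul]."""
    if total_cells < 0:
        raise DomainError("total cell count must be >= 0")
    if volume_ul <= 0:
        raise DomainError("volume must be positive")
    return total_cells / (volume_ul / 1000.0)
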