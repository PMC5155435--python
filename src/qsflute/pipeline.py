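"""The pan-flute design pipeline: simulate, score, calibrate.

The assay readout is the blue cleaved product at the exposed top of each
tube, discretized by three concentration thresholds into four visual
levels (0 = white ... 3 = full blue).  Calibration adjusts the free model
parameters and the thresholds so that the simulated level table matches an
observed one under a categorical (Hamming) objective.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConfigError,
    IntegrationError,
    ModelParams,
    PanFluteDesign,
    load_calibration,
)
from .cascade import simulate_columns

__all__ = [
    "ColorThresholds",
    "ScoreTable",
    "PTopMap",
    "CalibrationResult",
    "default_thresholds",
    "run_panflute",
    "score_table",
    "table_mismatch",
    "optimal_thresholds",
    "calibrate",
    "min_activating_height",
]

#: order in which free parameters are searched (stage 1 then stage 2)
STAGE1_PARAMS = ("alpha", "C_star")
STAGE2_PARAMS = ("A_tot", "k1", "k_m1", "k2")


@dataclass(frozen=True)
class ColorThresholds:
    """Cleaved-product thresholds separating the four color levels [nM]."""

    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        if not (0 < self.theta1 < self.theta2 < self.theta3):
            raise ConfigError(
                f"thresholds must be positive and strictly increasing, got "
                f"({self.theta1}, {self.theta2}, {self.theta3})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3])


def default_thresholds() -> ColorThresholds:
    """The shipped calibrated thresholds."""
    return ColorThresholds(*load_calibration()["thresholds_nM"])


@dataclass(frozen=True)
class PTopMap:
    """Cleaved product at the top node for every design cell [nM].

    ``values[i, j, k]`` corresponds to ``densities[i] x heights[j] x
    obs_times[k]`` of the design.
    """

    design: PanFluteDesign
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != self.design.shape:
            raise ConfigError(
                f"values shape {vals.shape} does not match design {self.design.shape}"
            )


@dataclass(frozen=True)
class ScoreTable:
    """4-level color-intensity table over the design grid."""

    design: PanFluteDesign
    levels: np.ndarray

    def __post_init__(self) -> None:
        lev = np.asarray(self.levels)
        if lev.shape != self.design.shape:
            raise ConfigError(
                f"levels shape {lev.shape} does not match design {self.design.shape}"
            )
        if not np.issubdtype(lev.dtype, np.integer):
            if not np.all(lev == np.round(lev)):
                raise ConfigError("levels must be integers")
            lev = lev.astype(np.int64)
        if lev.min() < 0 or lev.max() > 3:
            raise ConfigError("levels must be in {0, 1, 2, 3}")
        object.__setattr__(self, "levels", lev.astype(np.int8))


@dataclass
class CalibrationResult:
    """Outcome of the staged grid calibration."""

    params: ModelParams
    thresholds: ColorThresholds
    mismatch: int
    trace: list = field(default_factory=list)
    degenerate: bool = False


def run_panflute(
    params: ModelParams,
    design: PanFluteDesign,
    dx: float = 0.1,
    dt: float | None = None,
) -> PTopMap:
    """Simulate every (density, height) column and record P at the top node.

    All columns are integrated in one vectorized batch to the last
    observation time; snapshots are taken at each observation time.
    """
    cells = [(rho, h) for rho in design.densities for h in design.heights]
    try:
        snaps = simulate_columns(params, cells, dx, design.obs_times, dt=dt)
    except IntegrationError:
        raise
    n_rho, n_h, n_t = design.shape
    top_idx = np.array([int(round(h / dx)) for h in design.heights] * n_rho)
    values = np.empty((n_rho, n_h, n_t))
    for k, snap in enumerate(snaps):
        ptop = snap["P"][np.arange(len(cells)), top_idx]
        values[:, :, k] = ptop.reshape(n_rho, n_h)
    return PTopMap(design=design, values=values)


def score_table(ptop: PTopMap, thresholds: ColorThresholds) -> ScoreTable:
    """Discretize P_top into levels: number of thresholds strictly exceeded."""
    th = thresholds.as_array()
    levels = (ptop.values[..., None] > th).sum(axis=-1)
    return ScoreTable(design=ptop.design, levels=levels)


def table_mismatch(a: ScoreTable, b: ScoreTable) -> int:
    """Number of design cells whose levels differ (Hamming distance)."""
    if a.design != b.design:
        raise ConfigError("score tables have different designs")
    return int(np.count_nonzero(a.levels != b.levels))


def min_activating_height(table: ScoreTable, density: float, obs_time: float) -> float:
    """Smallest height with level >= 1 at a given density and time [mm].

    Returns ``inf`` when no height activates.
    """
    i = table.design.densities.index(float(density))
    k = table.design.obs_times.index(float(obs_time))
    col = table.levels[i, :, k]
    on = np.nonzero(col >= 1)[0]
    return float(table.design.heights[on[0]]) if on.size else float("inf")


def _candidate_cuts(values: np.ndarray) -> np.ndarray:
    """Candidate threshold positions: midpoints of sorted unique values,
    plus sentinels below and above, all strictly positive."""
    v = np.unique(values)
    cuts = []
    if v[0] > 0:
        cuts.append(v[0] / 2.0)
    for lo, hi in zip(v[:-1], v[1:]):
        cuts.append(hi / 2.0 if lo <= 0 else 0.5 * (lo + hi))
    top = v[-1] if v[-1] > 0 else 1.0
    cuts.extend([2.0 * top, 3.0 * top, 4.0 * top])
    return np.array(sorted(set(cuts)))


def optimal_thresholds(ptop: PTopMap, observed: ScoreTable):
    """Exact minimizer of the Hamming mismatch over threshold triples.

    Scans all strictly increasing triples of candidate cutpoints (midpoints
    between consecutive unique P_top values); returns the first minimizer in
    lexicographic cutpoint order.
    """
    if ptop.design != observed.design:
        raise ConfigError("P_top map and observed table have different designs")
    values = ptop.values.ravel()
    obs = observed.levels.ravel().astype(np.int8)
    cuts = _candidate_cuts(values)
    m = len(cuts)
    R = (values[None, :] > cuts[:, None]).astype(np.int8)   # (m, n_cells)
    best = (None, values.size + 1)
    for i in range(m - 2):
        # levels for all (j, k) with i < j <= k; enforce j < k by masking
        lev = R[i][None, None, :] + R[i + 1:, None, :] + R[None, i + 1:, :]
        mis = np.count_nonzero(lev != obs[None, None, :], axis=2)
        jj, kk = np.triu_indices(m - i - 1, k=1)
        flat = mis[jj, kk]
        a = int(np.argmin(flat))
        if flat[a] < best[1]:
            best = ((i, i + 1 + jj[a], i + 1 + kk[a]), int(flat[a]))
    (i, j, k), mismatch = best
    return ColorThresholds(cuts[i], cuts[j], cuts[k]), mismatch


def _binary_mismatch(values: np.ndarray, observed_on: np.ndarray) -> int:
    """Best achievable activated/non-activated disagreement over cutpoints."""
    cuts = _candidate_cuts(values)
    pred = values[None, :] > cuts[:, None]
    return int(np.count_nonzero(pred != observed_on[None, :], axis=1).min())


def calibrate(
    observed: ScoreTable,
    fixed: ModelParams,
    search_space: dict,
    dx: float = 0.2,
    dt: float | None = None,
    cache: dict | None = None,
) -> CalibrationResult:
    """Staged exhaustive grid search against an observed score table.

    Stage 1 fits ``alpha`` and ``C_star`` (enzymatic rates held at their
    values in ``fixed``) to the activated/non-activated boundary pattern;
    stage 2 fits ``A_tot, k1, k_m1, k2`` together with the three color
    thresholds under the full 4-level Hamming objective.  Candidate lists
    are sorted ascending and scanned in lexicographic order; the first
    minimizer wins ties, which makes the result independent of the order in
    which the caller lists candidates.

    ``cache`` may be a dict shared between repeated calibrations of the same
    design (e.g. noise replicates); simulated P_top maps are memoized in it
    keyed by the candidate parameters and solver settings.
    """
    known = set(STAGE1_PARAMS) | set(STAGE2_PARAMS)
    unknown = set(search_space) - known
    if unknown:
        raise ConfigError(f"unknown free parameters: {sorted(unknown)}")
    if not search_space or any(len(list(v)) == 0 for v in search_space.values()):
        raise ConfigError("search space must give a non-empty grid per parameter")
    grids = {k: sorted(float(x) for x in v) for k, v in search_space.items()}
    design = observed.design
    trace = []

    def ptop_for(p: ModelParams) -> PTopMap:
        if cache is None:
            return run_panflute(p, design, dx=dx, dt=dt)
        key = (tuple(sorted(p.to_dict().items())), design, dx, dt)
        if key not in cache:
            cache[key] = run_panflute(p, design, dx=dx, dt=dt)
        return cache[key]

    # stage 1: activation boundary pattern
    obs_on = (observed.levels.ravel() >= 1)
    s1_names = [n for n in STAGE1_PARAMS if n in grids]
    best1 = None
    for combo in itertools.product(*(grids[n] for n in s1_names)):
        p = fixed.replace(**dict(zip(s1_names, combo)))
        mis = _binary_mismatch(ptop_for(p).values.ravel(), obs_on)
        trace.append({"stage": 1, "candidate": dict(zip(s1_names, combo)),
                      "binary_mismatch": mis})
        if best1 is None or mis < best1[1]:
            best1 = (dict(zip(s1_names, combo)), mis)
    stage1 = best1[0] if best1 else {}

    # stage 2: nuance levels and thresholds
    s2_names = [n for n in STAGE2_PARAMS if n in grids]
    base = fixed.replace(**stage1)
    best2 = None
    for combo in itertools.product(*(grids[n] for n in s2_names)):
        p = base.replace(**dict(zip(s2_names, combo)))
        th, mis = optimal_thresholds(ptop_for(p), observed)
        trace.append({"stage": 2, "candidate": dict(zip(s2_names, combo)),
                      "mismatch": mis})
        if best2 is None or mis < best2[2]:
            best2 = (dict(zip(s2_names, combo)), th, mis)
    if best2 is None:
        th, mis = optimal_thresholds(ptop_for(base), observed)
        best2 = ({}, th, mis)

    final = base.replace(**best2[0])
    degenerate = bool(observed.levels.max() == 0)
    if degenerate and "alpha" in grids:
        # an all-white table carries no activation signal; report the grid
        # minimum explicitly rather than an arbitrary tie
        final = final.replace(alpha=grids["alpha"][0])
    return CalibrationResult(params=final, thresholds=best2[1],
                             mismatch=best2[2], trace=trace,
                             degenerate=degenerate)
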