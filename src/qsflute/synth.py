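"""Synthetic observed datasets with the statistical structure of the assays.

Score tables are generated by running the forward pipeline under known
ground-truth parameters and thresholding, then optionally corrupting each
cell with seeded +/-1-level misclassification noise — the real observable
is a discretized visual score, so noise enters at the scoring step, not as
additive concentration noise.  Dilution-series grids come from the
exponential suspension-decay model.  All randomness flows through one
explicitly seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DomainError, ModelParams, PanFluteDesign, ng_per_ml_to_nM, MW_OHL
from .pipeline import ColorThresholds, PTopMap, ScoreTable, run_panflute, score_table
from .degradation import DilutionAssay, predict_wells

__all__ = [
    "SyntheticSpec",
    "make_score_table",
    "apply_level_noise",
    "make_dilution_assay",
    "default_dilution_C0",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and noise model for a synthetic score table."""

    params: ModelParams
    thresholds: ColorThresholds
    design: PanFluteDesign = field(default_factory=PanFluteDesign)
    flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_prob <= 0.5):
            raise DomainError(f"flip_prob must be in [0, 0.5], got {self.flip_prob}")


def apply_level_noise(table: ScoreTable, flip_prob: float, rng: np.random.Generator) -> ScoreTable:
    """Flip each cell by one level with probability ``flip_prob``.

    Direction is uniform except at the ends of the scale (0 flips up, 3
    flips down), so every drawn flip visibly changes the cell.
    """
    lev = table.levels.astype(np.int8).copy()
    flip = rng.random(lev.shape) < flip_prob
    down = rng.random(lev.shape) < 0.5
    delta = np.where(down, -1, 1).astype(np.int8)
    delta[lev == 0] = 1
    delta[lev == 3] = -1
    lev[flip] += delta[flip]
    return ScoreTable(design=table.design, levels=lev)


def make_score_table(spec: SyntheticSpec, dx: float = 0.2) -> ScoreTable:
    """Forward-simulate a score table under ground truth, then add noise."""
    ptop = run_panflute(spec.params, spec.design, dx=dx)
    table = score_table(ptop, spec.thresholds)
    if spec.flip_prob > 0:
        table = apply_level_noise(table, spec.flip_prob, np.random.default_rng(spec.seed))
    return table


def default_dilution_C0() -> float:
    """Initial signal concentration of the suspension assay [nM].

    550 ng of OHL brought to 1.67 ml of suspension: 329 ng/ml, i.e. about
    1.45e3 nM at MW 227.3 g/mol.
    """
    return ng_per_ml_to_nM(550.0 / 1.67, MW_OHL)


def make_dilution_assay(
    params: ModelParams,
    densities=(8.8e5, 8.8e6, 8.8e7, 8.8e8, 4.4e9),
    times=(1.0 / 60.0, 1.0, 24.0),
    C0: float | None = None,
    seed: int = 0,
    noise_prob: float = 0.0,
):
    """Synthetic dilution-series responses under the decay ground truth.

    Returns the :class:`DilutionAssay` design and its (optionally noisy)
    boolean response grid.
    """
    if not (0.0 <= noise_prob <= 0.5):
        raise DomainError(f"noise_prob must be in [0, 0.5], got {noise_prob}")
    assay = DilutionAssay(
        densities=densities,
        exposure_times=times,
        initial_C0=default_dilution_C0() if C0 is None else C0,
    )
    response = predict_wells(assay, params.C_star, params)
    if noise_prob > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(response.shape) < noise_prob
        response = response ^ flip
    return assay, response
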