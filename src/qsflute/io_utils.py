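"""TSV/JSON readers and writers for tables, parameter sets and designs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigError, ModelParams, PanFluteDesign
from .pipeline import ColorThresholds, PTopMap, ScoreTable

__all__ = [
    "read_score_table",
    "write_score_table",
    "write_ptop",
    "read_params",
    "write_params",
    "read_design",
    "write_design",
    "write_profile",
]

SCORE_COLUMNS = ["density_cells_per_ml", "height_mm", "time_h", "level"]


def write_score_table(table: ScoreTable, path) -> None:
    d = table.design
    rows = [
        (rho, h, t, int(table.levels[i, j, k]))
        for i, rho in enumerate(d.densities)
        for j, h in enumerate(d.heights)
        for k, t in enumerate(d.obs_times)
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_score_table(path) -> ScoreTable:
    """Read a level table written by :func:`write_score_table` (lossless)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ConfigError(f"{path}: empty score-table file") from None
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ConfigError(f"{path}: score table has no rows")
    bad = df[~df["level"].isin([0, 1, 2, 3])]
    if len(bad):
        raise ConfigError(
            f"{path}: invalid level values at rows {(bad.index + 2).tolist()} "
            "(levels must be integers 0-3)"
        )
    dup = df.duplicated(subset=SCORE_COLUMNS[:3])
    if dup.any():
        raise ConfigError(
            f"{path}: duplicate design cells at rows {(df.index[dup] + 2).tolist()}"
        )
    design = PanFluteDesign(
        heights=tuple(sorted(df["height_mm"].unique())),
        densities=tuple(sorted(df["density_cells_per_ml"].unique())),
        obs_times=tuple(sorted(df["time_h"].unique())),
    )
    levels = np.full(design.shape, -1, dtype=np.int8)
    for _, row in df.iterrows():
        i = design.densities.index(float(row["density_cells_per_ml"]))
        j = design.heights.index(float(row["height_mm"]))
        k = design.obs_times.index(float(row["time_h"]))
        levels[i, j, k] = int(row["level"])
    if (levels < 0).any():
        raise ConfigError(f"{path}: table does not cover the full design grid")
    return ScoreTable(design=design, levels=levels)


def write_ptop(ptop: PTopMap, path) -> None:
    d = ptop.design
    rows = [
        (rho, h, t, ptop.values[i, j, k])
        for i, rho in enumerate(d.densities)
        for j, h in enumerate(d.heights)
        for k, t in enumerate(d.obs_times)
    ]
    pd.DataFrame(
        rows, columns=SCORE_COLUMNS[:3] + ["value_nM"]
    ).to_csv(path, sep="\t", index=False)


def read_params(path) -> ModelParams:
    with open(path) as fh:
        return ModelParams.from_dict(json.load(fh))


def write_params(params: ModelParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_design(path) -> PanFluteDesign:
    with open(path) as fh:
        d = json.load(fh)
    try:
        return PanFluteDesign(
            heights=tuple(d["heights_mm"]),
            densities=tuple(d["densities_cells_per_ml"]),
            obs_times=tuple(d["obs_times_h"]),
        )
    except KeyError as e:
        raise ConfigError(f"{path}: missing design key {e}") from None


def write_design(design: PanFluteDesign, path) -> None:
    Path(path).write_text(json.dumps({
        "heights_mm": list(design.heights),
        "densities_cells_per_ml": list(design.densities),
        "obs_times_h": list(design.obs_times),
    }, indent=2) + "\n")


def write_profile(state, path) -> None:
    """Write a cascade/field state as a TSV profile of all five species."""
    df = pd.DataFrame({
        "x_mm": state.grid.x,
        "C_nM": state.C,
        "E_nM": state.E,
        "ES_nM": state.ES,
        "S_nM": state.S,
        "P_nM": state.P,
    })
    df.to_csv(path, sep="\t", index=False)
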