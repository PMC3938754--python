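"""Configuration loading and tabular/JSON writers shared by the CLI."""

from __future__ import annotations

import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .cell import CellModel
from .selection import LandscapeGrid
from .evolution import StabilityDistribution

log = logging.getLogger(__name__)

_CELL_KEYS = ("temperature", "rt_override", "cell_mass", "specific_rate",
              "nonproteome_fraction", "repro_fraction", "der_override",
              "n_eff", "n_census")


def load_cell_model(path) -> CellModel:
    """Build a CellModel from a flat JSON document.

    Missing keys fall back to the built-in yeast defaults; unknown keys are
    rejected (no silent typo acceptance); invariant violations raise with
    the offending field named.  Effective values are logged.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError("cell model document must be a JSON object")
    unknown = sorted(set(doc) - set(_CELL_KEYS))
    if unknown:
        raise ValueError(f"unknown cell model key(s) {unknown}; "
                         f"allowed: {sorted(_CELL_KEYS)}")
    cell = CellModel(**doc)
    log.info("cell model: %s", {k: getattr(cell, k) for k in _CELL_KEYS})
    if cell.rt_override is not None:
        log.info("rt_override=%.4g kJ/mol active: Boltzmann factors use the "
                 "override instead of R*T", cell.rt_override)
    return cell


def write_grid_tsv(grid: LandscapeGrid, path) -> None:
    """Grid TSV: first row/column carry the axis values, body is the grid."""
    df = pd.DataFrame(grid.values,
                      index=pd.Index(grid.y_values, name=grid.y_name),
                      columns=grid.x_values)
    df.columns.name = grid.x_name
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_trajectory_tsv(trajectory: Sequence[StabilityDistribution],
                         path) -> None:
    """Trajectory TSV: column 1 the dG grid (kcal/mol), one column per phase."""
    grid = trajectory[0].grid
    data = {"dg_kcal": grid}
    for t, dist in enumerate(trajectory):
        data[f"phase{t}"] = dist.pmf
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def write_json(obj: dict, path) -> None:
    def _default(x):
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON serializable: {type(x)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
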