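"""Kimura fixation probabilities and fixation surfaces.

A new mutant arising as a single copy in a haploid population fixes with
probability

    P_fix(s) = (1 - exp(-2 s N_eff / N)) / (1 - exp(-2 N_eff s))

which tends to 1/N for neutral mutations, ~2 s N_eff/N for beneficial ones
and vanishes exponentially for deleterious ones below the drift threshold
-1/N_eff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cell import CellModel, ProteinSpec
from .selection import LandscapeGrid, landscape, s_stability

log = logging.getLogger(__name__)

# below this |2 N_eff s| the expm1 ratio is replaced by its series
_SERIES_CUTOFF = 1.0e-8
# beyond this -2 N_eff s the denominator is a pure exponential
_EXP_CUTOFF = 500.0


@dataclass(frozen=True)
class FixationParams:
    """Effective and census population sizes for the diffusion formula."""

    n_eff: float = 1.0e7
    n_census: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_eff < 1:
            raise ValueError("n_eff must be >= 1")
        if self.n_census is None:
            object.__setattr__(self, "n_census", self.n_eff)
        if self.n_census < self.n_eff:
            raise ValueError("n_census must be >= n_eff")


def fixation_probability(s: float, params: FixationParams,
                         _warn: bool = True) -> float:
    """Haploid Kimura fixation probability of a single new mutant.

    Continuous at s=0 (limit 1/N, via series expansion near zero), clipped
    to [0, 1]; ``s <= -1`` returns 0 with a warning (a lethal mutant cannot
    fix).
    """
    ne, n = params.n_eff, params.n_census
    if s <= -1.0:
        if _warn:
            log.warning("s=%.3g <= -1: lethal mutant, fixation probability 0",
                        s)
        return 0.0
    a = 2.0 * s * ne / n  # numerator exponent
    b = 2.0 * ne * s  # denominator exponent
    if abs(b) < _SERIES_CUTOFF:
        # (1-e^-a)/(1-e^-b) = (a - a^2/2 + ...)/(b - b^2/2 + ...)
        #                   -> (a/b) * (1 - a/2) / (1 - b/2)
        p = (1.0 / n) * (1.0 - a / 2.0) / (1.0 - b / 2.0)
    elif -b > _EXP_CUTOFF:
        # strongly deleterious: denominator ~ -exp(-b); log-space product
        log_p = math.log(abs(-math.expm1(-a))) + b if a != 0 else -math.inf
        p = math.exp(log_p) if log_p > -745 else 0.0
    else:
        p = (-math.expm1(-a)) / (-math.expm1(-b))
    return min(max(p, 0.0), 1.0)


def fixation_probabilities(s: np.ndarray, params: FixationParams) -> np.ndarray:
    """Vectorized ``fixation_probability`` over an array of s values."""
    flat = np.asarray(s, dtype=float).ravel()
    n_lethal = int(np.count_nonzero(flat <= -1.0))
    if n_lethal:
        log.warning("%d of %d selection coefficients are <= -1 (lethal); "
                    "their fixation probabilities are 0", n_lethal, flat.size)
    out = np.array([fixation_probability(v, params, _warn=False)
                    for v in flat])
    return out.reshape(np.shape(s))


def fixation_surface(template: ProteinSpec, cell: CellModel,
                     params: FixationParams,
                     x_spec: Tuple[str, Sequence[float]],
                     y_spec: Tuple[str, Sequence[float]]) -> LandscapeGrid:
    """Elementwise fixation probability over a selection landscape."""
    grid = landscape(template, cell, x_spec, y_spec)
    values = fixation_probabilities(grid.values, params)
    meta = dict(grid.metadata, quantity="p_fix", params=params)
    return LandscapeGrid(x_name=grid.x_name, x_values=grid.x_values,
                         y_name=grid.y_name, y_values=grid.y_values,
                         values=values, metadata=meta)


#: Fig-2-style surface presets: abundance-changing mutations of a
#: 10,000-copy wild type, vs length (left) or turnover (right).
SURFACE_PRESETS = {
    "fig2-left": (("abundance_mut", np.linspace(0.0, 2.0e4, 81)),
                  ("n_aa", np.linspace(100, 2000, 39))),
    "fig2-right": (("abundance_mut", np.linspace(0.0, 2.0e4, 81)),
                   ("k_d", np.geomspace(1.0e-5, 1.0e-1, 41))),
}


def fixation_surface_preset(name: str, cell: CellModel,
                            params: FixationParams,
                            template: Optional[ProteinSpec] = None
                            ) -> LandscapeGrid:
    if name not in SURFACE_PRESETS:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(SURFACE_PRESETS)}")
    template = template or ProteinSpec(abundance=1.0e4)
    x_spec, y_spec = SURFACE_PRESETS[name]
    return fixation_surface(template, cell, params, x_spec, y_spec)


def fixation_vs_stability(template: ProteinSpec, cell: CellModel,
                          params: FixationParams,
                          dg_mut_grid: Sequence[float],
                          vary: str = "abundance",
                          values: Sequence[float] = (1.0e3, 1.0e4, 1.0e5)
                          ) -> pd.DataFrame:
    """Fixation probability of stability-changing mutations.

    One row per mutant ``dg_fold`` (kJ/mol), one column per value of the
    varied wild-type parameter (``abundance`` or ``k_d``).  The wild type
    keeps the template's stability.
    """
    if vary not in ("abundance", "k_d"):
        raise ValueError("vary must be 'abundance' or 'k_d'")
    dg_mut_grid = np.asarray(dg_mut_grid, dtype=float)
    out = {}
    for v in values:
        wt = template.replace(**{vary: v})
        col = [fixation_probability(s_stability(wt, dg, cell).s, params)
               for dg in dg_mut_grid]
        out[f"{vary}={v:g}"] = col
    df = pd.DataFrame(out, index=pd.Index(dg_mut_grid, name="dg_mut_kj"))
    return df
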