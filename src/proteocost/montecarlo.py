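"""Stochastic origin-fixation simulator.

Independent cross-check of the deterministic kernel iteration: mutations
arise one at a time with ddG drawn from the mixture model, and each is
either fixed (with its Kimura probability, via rejection sampling against a
per-state envelope) or purged.  Time is measured in fixed mutations, so the
per-phase sample clouds should match the deterministic phase distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import CellModel, ProteinSpec
from .evolution import DdgModel, EvolveConfig, fixation_matrix
from .fixation import FixationParams

_MIN_ACCEPT_RATE = 1.0e-6


@dataclass(frozen=True)
class McConfig:
    """Replication and seeding controls for the simulator."""

    n_replicates: int = 1000
    n_fixed_mutations: int = 14
    seed: int = 0
    envelope_factor: float = 1.1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.envelope_factor < 1.0:
            raise ValueError("envelope_factor must be >= 1")


class _GridSampler:
    """Rejection sampler for one fixed mutation on the dG grid.

    Proposals are ddG draws from the mixture; the proposed stability is
    snapped to the nearest grid point (off-grid proposals are rejected,
    mirroring the kernel's truncation) and accepted with probability
    P_fix / M_i, where M_i is the envelope_factor-inflated maximum fixation
    probability over targets reachable from the current grid state.
    Accepted targets are therefore distributed exactly as the normalized
    kernel row.
    """

    def __init__(self, grid: np.ndarray, template: ProteinSpec,
                 cell: CellModel, params: FixationParams, ddg: DdgModel,
                 envelope_factor: float = 1.1):
        self.grid = np.asarray(grid, dtype=float)
        self.step = float(self.grid[1] - self.grid[0])
        self.ddg = ddg
        self.pfix = fixation_matrix(self.grid, template, cell, params)
        self.row_max = self.pfix.max(axis=1)
        if np.any(self.row_max <= 0.0):
            raise ValueError("fixation probability vanishes for some grid "
                             "state; no mutation can ever fix from there")
        self.envelope = envelope_factor * self.row_max

    def step_many(self, idx: np.ndarray, rng: np.random.Generator
                  ) -> np.ndarray:
        """Advance every replicate (given by grid index) by one fixed
        mutation; returns the new index array."""
        idx = np.asarray(idx, dtype=np.intp).copy()
        pending = np.arange(idx.size)
        n_proposals = 0
        n_accepted = 0
        while pending.size:
            cur = idx[pending]
            ddg = self.ddg.sample_rng(pending.size, rng)
            target = np.rint((self.grid[cur] + ddg - self.grid[0])
                             / self.step).astype(np.intp)
            u = rng.random(pending.size)
            in_grid = (target >= 0) & (target < self.grid.size)
            accept = np.zeros(pending.size, dtype=bool)
            ok = np.flatnonzero(in_grid)
            if ok.size:
                p = self.pfix[cur[ok], target[ok]]
                accept[ok] = u[ok] < p / self.envelope[cur[ok]]
            idx[pending[accept]] = target[accept]
            n_proposals += pending.size
            n_accepted += int(accept.sum())
            pending = pending[~accept]
            if (n_proposals > 1000 and
                    n_accepted / n_proposals < _MIN_ACCEPT_RATE):
                raise RuntimeError(
                    "rejection acceptance rate below 1e-6; check that the "
                    "selection regime leaves any fixable mutations")
        return idx


def next_fixed_mutation(dg: float, template: ProteinSpec, cell: CellModel,
                        params: FixationParams, ddg: DdgModel,
                        rng: np.random.Generator,
                        config: EvolveConfig | None = None,
                        envelope_factor: float = 1.1) -> float:
    """Stability after the next fixed mutation, starting from ``dg`` kcal/mol."""
    config = config or EvolveConfig()
    sampler = _GridSampler(config.make_grid(), template, cell, params, ddg,
                           envelope_factor)
    i0 = int(np.argmin(np.abs(sampler.grid - dg)))
    i1 = sampler.step_many(np.array([i0]), rng)[0]
    return float(sampler.grid[i1])


def simulate_population(dg0: float, template: ProteinSpec, cell: CellModel,
                        params: FixationParams, ddg: DdgModel,
                        mc: McConfig,
                        config: EvolveConfig | None = None) -> np.ndarray:
    """Independent origin-fixation trajectories.

    Returns an array of shape ``(n_fixed_mutations + 1, n_replicates)`` of
    dG samples (kcal/mol); row 0 is the common start.  Per-replicate
    randomness derives deterministically from (seed, replicate index) via a
    spawned generator sequence, so results are bitwise reproducible.
    """
    config = config or EvolveConfig()
    sampler = _GridSampler(config.make_grid(), template, cell, params, ddg,
                           mc.envelope_factor)
    rng = np.random.default_rng(np.random.SeedSequence(mc.seed))
    i0 = int(np.argmin(np.abs(sampler.grid - dg0)))
    idx = np.full(mc.n_replicates, i0, dtype=np.intp)
    out = np.empty((mc.n_fixed_mutations + 1, mc.n_replicates))
    out[0] = sampler.grid[idx]
    for t in range(1, mc.n_fixed_mutations + 1):
        idx = sampler.step_many(idx, rng)
        out[t] = sampler.grid[idx]
    return out
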