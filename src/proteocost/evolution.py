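"""Mutation-selection dynamics of protein folding stability.

Arising mutations perturb a protein's folding free energy by ddG drawn from
a bi-Gaussian mixture (two lobes roughly corresponding to surface and core
residues, both destabilizing on average).  Each arising mutation fixes with
the Kimura probability of its proteostatic selection coefficient, so the
per-fixation transition density between stabilities dG_i -> dG_j is

    K(i, j)  propto  p_ddg(dG_j - dG_i) * P_fix(s(dG_i -> dG_j))

discretized on a uniform dG grid (kcal/mol) and row-normalized, i.e.
conditioned on one fixation per phase.  Iterating a starting distribution
through this kernel converges to the mutation-selection equilibrium
distribution of stabilities; its mode and skew are the observables compared
against empirical stability distributions.

The statsmodels-style front end is :class:`StabilityEvolution` (the model:
protein, cell, population and mutation-spectrum parameters plus the grid)
whose :meth:`~StabilityEvolution.fit` returns a
:class:`StabilityEvolutionResults` carrying the equilibrium distribution,
its mode/mean/skew, convergence diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .cell import CellModel, ProteinSpec, thermal_energy
from .fixation import FixationParams, fixation_probabilities
from .selection import cost_coefficient

KJ_PER_KCAL = 4.184


@dataclass(frozen=True)
class DdgModel:
    """Bi-Gaussian distribution of mutational stability effects (kcal/mol).

    Positive ddG destabilizes.  Defaults are the canonical two-lobe fit
    (means 0.56 and 1.96 kcal/mol, s.d. 0.90 and 1.93); the mixture weight
    of the low-ddG lobe defaults to 0.7, giving a mean effect of about
    1 kcal/mol (~ 4 kJ/mol) per mutation.
    """

    p1: float = 0.7
    mu1: float = 0.56
    mu2: float = 1.96
    sigma1: float = 0.90
    sigma2: float = 1.93

    def __post_init__(self) -> None:
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError("p1 must lie in [0, 1]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be > 0")

    @property
    def mean(self) -> float:
        return self.p1 * self.mu1 + (1.0 - self.p1) * self.mu2

    def density(self, x) -> np.ndarray:
        """Mixture density at x (kcal/mol)."""
        x = np.asarray(x, dtype=float)
        return (self.p1 * stats.norm.pdf(x, self.mu1, self.sigma1)
                + (1.0 - self.p1) * stats.norm.pdf(x, self.mu2, self.sigma2))

    def sample(self, n: int, seed: int) -> np.ndarray:
        """n reproducible draws; the seed is mandatory."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        return self.sample_rng(n, rng)

    def sample_rng(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp1 = rng.random(n) < self.p1
        x = np.where(comp1,
                     rng.normal(self.mu1, self.sigma1, size=n),
                     rng.normal(self.mu2, self.sigma2, size=n))
        return x


def ddg_density(x, model: DdgModel) -> np.ndarray:
    return model.density(x)


def ddg_sample(model: DdgModel, n: int, seed: int) -> np.ndarray:
    return model.sample(n, seed)


@dataclass(frozen=True)
class StabilityDistribution:
    """Probability mass over a uniform dG grid (kcal/mol, ascending)."""

    grid: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "pmf", pmf)
        if grid.shape != pmf.shape or grid.ndim != 1:
            raise ValueError("grid and pmf must be matching 1-D arrays")
        steps = np.diff(grid)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("grid spacing must be uniform")
        if np.any(pmf < -1e-15):
            raise ValueError("probability masses must be >= 0")
        if abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError("probability masses must sum to 1")

    @classmethod
    def point_mass(cls, grid: np.ndarray, dg0: float) -> "StabilityDistribution":
        """Delta start at the grid point nearest dg0."""
        grid = np.asarray(grid, dtype=float)
        pmf = np.zeros_like(grid)
        pmf[int(np.argmin(np.abs(grid - dg0)))] = 1.0
        return cls(grid=grid, pmf=pmf)

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.pmf))])

    @property
    def mean(self) -> float:
        return float(np.dot(self.grid, self.pmf))

    @property
    def std(self) -> float:
        return float(math.sqrt(max(np.dot(self.grid ** 2, self.pmf)
                                   - self.mean ** 2, 0.0)))

    @property
    def skewness(self) -> float:
        sd = self.std
        if sd == 0:
            return 0.0
        return float(np.dot((self.grid - self.mean) ** 3, self.pmf) / sd ** 3)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def tv_distance(self, other: "StabilityDistribution") -> float:
        _check_same_grid(self, other)
        return 0.5 * float(np.abs(self.pmf - other.pmf).sum())


def _check_same_grid(d1: StabilityDistribution, d2: StabilityDistribution):
    if d1.grid.shape != d2.grid.shape or not np.allclose(d1.grid, d2.grid):
        raise ValueError("distributions are on different grids")


def ks_distance(d1: StabilityDistribution, d2: StabilityDistribution) -> float:
    """Two-sample KS statistic between the discretized distributions."""
    _check_same_grid(d1, d2)
    return float(np.max(np.abs(d1.cdf() - d2.cdf())))


@dataclass(frozen=True)
class EvolveConfig:
    """Grid and convergence controls for the kernel iteration."""

    grid_min: float = -15.0  # kcal/mol
    grid_max: float = -0.5
    grid_step: float = 0.05
    max_iterations: int = 5000
    convergence_tol: float = 1.0e-6  # total-variation distance per phase
    ks_alpha: float = 0.05  # level for the KS convergence diagnostic

    def __post_init__(self) -> None:
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")

    def make_grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


def stability_selection_matrix(grid_kcal: np.ndarray, template: ProteinSpec,
                               cell: CellModel) -> np.ndarray:
    """s(i -> j) for every ordered pair of grid stabilities.

    Approximate-U convention: ``s = -c_i A (exp(G_j/RT) - exp(G_i/RT))``
    with the grid in kcal/mol converted to kJ/mol.
    """
    rt = thermal_energy(cell)
    c_i = cost_coefficient(template, cell)
    boltz = np.exp(np.asarray(grid_kcal) * KJ_PER_KCAL / rt)
    return -c_i * template.abundance * (boltz[None, :] - boltz[:, None])


def fixation_matrix(grid_kcal: np.ndarray, template: ProteinSpec,
                    cell: CellModel, params: FixationParams) -> np.ndarray:
    """P_fix(i -> j) for every ordered pair of grid stabilities."""
    s = stability_selection_matrix(grid_kcal, template, cell)
    return fixation_probabilities(s, params)


def transition_kernel(grid_kcal: np.ndarray, template: ProteinSpec,
                      cell: CellModel, params: FixationParams,
                      ddg: DdgModel) -> np.ndarray:
    """Row-stochastic per-fixation transition matrix on the dG grid.

    Entry (i, j) is proportional to the ddG proposal density at
    ``grid[j] - grid[i]`` times the fixation probability of the implied
    selection coefficient; rows are normalized (one fixation per phase).
    Proposal mass falling outside the grid is truncated beforehand.
    """
    grid_kcal = np.asarray(grid_kcal, dtype=float)
    ddg_mat = ddg.density(grid_kcal[None, :] - grid_kcal[:, None])
    pfix = fixation_matrix(grid_kcal, template, cell, params)
    kernel = ddg_mat * pfix
    row_sums = kernel.sum(axis=1)
    dead = np.flatnonzero(row_sums <= 0.0)
    if dead.size:
        raise ValueError(
            "no fixable mutation from grid state(s) "
            f"{grid_kcal[dead[:5]].tolist()} kcal/mol; check parameters")
    return kernel / row_sums[:, None]


def evolve_distribution(p0: StabilityDistribution, kernel: np.ndarray,
                        config: EvolveConfig
                        ) -> Tuple[List[StabilityDistribution], bool]:
    """Iterate ``P_{t+1} = K^T P_t`` until the total-variation change per
    phase drops below tolerance.

    Returns (trajectory including the start, converged flag).
    """
    if kernel.shape != (len(p0.grid), len(p0.grid)):
        raise ValueError("kernel shape does not match the grid")
    traj = [p0]
    p = p0.pmf
    converged = False
    for _ in range(config.max_iterations):
        p_next = kernel.T @ p
        p_next = p_next / p_next.sum()
        traj.append(StabilityDistribution(grid=p0.grid, pmf=p_next))
        tv = 0.5 * float(np.abs(p_next - p).sum())
        p = p_next
        if tv < config.convergence_tol:
            converged = True
            break
    return traj, converged


def ks_convergence_phase(traj: Sequence[StabilityDistribution],
                         alpha: float = 0.05,
                         nominal_n: int = 10000) -> Optional[int]:
    """Diagnostic: first phase whose KS statistic against the previous phase
    falls below the two-sample critical value at level alpha for samples of
    ``nominal_n`` (the number of fixed mutations after which consecutive
    phases would be statistically indistinguishable)."""
    d_crit = math.sqrt(-math.log(alpha / 2.0) / 2.0) * math.sqrt(2.0 / nominal_n)
    for t in range(1, len(traj)):
        if ks_distance(traj[t], traj[t - 1]) < d_crit:
            return t
    return None


class StabilityEvolution:
    """Mutation-selection model of one protein's folding stability.

    Parameters
    ----------
    template : ProteinSpec
        The protein whose abundance, length, turnover and handling costs set
        the selection strength (its ``dg_fold`` is not used; stability is
        the evolving variable).
    cell : CellModel
        Organism-level energetics (temperature, metabolic rate, reproductive
        fraction) and population sizes.
    params : FixationParams, optional
        Population sizes for the fixation probability; defaults to the
        cell's ``n_eff``/``n_census``.
    ddg : DdgModel
        Mutation-effect spectrum.
    config : EvolveConfig
        Grid and convergence controls.

    Examples
    --------
    >>> model = StabilityEvolution(ProteinSpec(abundance=2**12))
    >>> res = model.fit(start=-3.0)
    >>> round(res.equilibrium.mode, 2)  # doctest: +SKIP
    -6.5
    """

    def __init__(self, template: ProteinSpec,
                 cell: Optional[CellModel] = None,
                 params: Optional[FixationParams] = None,
                 ddg: Optional[DdgModel] = None,
                 config: Optional[EvolveConfig] = None):
        self.template = template
        self.cell = cell or CellModel()
        self.params = params or FixationParams(n_eff=self.cell.n_eff,
                                               n_census=self.cell.n_census)
        self.ddg = ddg or DdgModel()
        self.config = config or EvolveConfig()
        self.grid = self.config.make_grid()
        self._kernel: Optional[np.ndarray] = None

    @classmethod
    def from_params(cls, abundance: float = 2 ** 12, n_eff: float = 1.0e7,
                    p1: float = 0.7, **protein_kwargs) -> "StabilityEvolution":
        """Convenience constructor from the headline knobs."""
        template = ProteinSpec(abundance=abundance, **protein_kwargs)
        return cls(template, params=FixationParams(n_eff=n_eff),
                   ddg=DdgModel(p1=p1))

    @property
    def kernel(self) -> np.ndarray:
        if self._kernel is None:
            self._kernel = transition_kernel(self.grid, self.template,
                                             self.cell, self.params, self.ddg)
        return self._kernel

    def fit(self, start: float = -3.0) -> "StabilityEvolutionResults":
        """Iterate the kernel from a point mass at ``start`` (kcal/mol) to
        mutation-selection equilibrium."""
        p0 = StabilityDistribution.point_mass(self.grid, start)
        traj, converged = evolve_distribution(p0, self.kernel, self.config)
        return StabilityEvolutionResults(self, traj, converged, start)

    def simulate(self, start: float = -3.0, n_replicates: int = 1000,
                 n_fixed_mutations: int = 14, seed: int = 0) -> np.ndarray:
        """Monte-Carlo origin-fixation sample paths (see
        :mod:`proteocost.montecarlo`); returns the per-phase sample array."""
        from .montecarlo import McConfig, simulate_population
        mc = McConfig(n_replicates=n_replicates,
                      n_fixed_mutations=n_fixed_mutations, seed=seed)
        return simulate_population(start, self.template, self.cell,
                                   self.params, self.ddg, mc,
                                   config=self.config)


class StabilityEvolutionResults:
    """Results of a :class:`StabilityEvolution` fit.

    Attributes
    ----------
    trajectory : list of StabilityDistribution
        All phases from the starting point mass onward.
    equilibrium : StabilityDistribution
        The final (limiting) distribution.
    converged : bool
        Whether the total-variation tolerance was reached.
    """

    def __init__(self, model: StabilityEvolution,
                 trajectory: List[StabilityDistribution],
                 converged: bool, start: float):
        self.model = model
        self.trajectory = trajectory
        self.converged = converged
        self.start = start

    @property
    def equilibrium(self) -> StabilityDistribution:
        return self.trajectory[-1]

    @property
    def n_iterations(self) -> int:
        return len(self.trajectory) - 1

    @property
    def mode(self) -> float:
        return self.equilibrium.mode

    @property
    def mean(self) -> float:
        return self.equilibrium.mean

    @property
    def ks_phase(self) -> Optional[int]:
        """Phases until consecutive distributions become statistically
        indistinguishable (KS diagnostic; see ``ks_convergence_phase``)."""
        return ks_convergence_phase(self.trajectory,
                                    alpha=self.model.config.ks_alpha)

    def summary(self) -> str:
        m = self.model
        eq = self.equilibrium
        lines = [
            "Mutation-selection equilibrium of protein stability",
            "=" * 55,
            f"protein: {m.template.name}  A={m.template.abundance:g}  "
            f"n_aa={m.template.n_aa}  k_d={m.template.k_d:g}/s",
            f"cell: T={m.cell.temperature:g} K  RT={thermal_energy(m.cell):.4g} kJ/mol  "
            f"rate={m.cell.specific_rate:g} J/s/g",
            f"population: N_eff={m.params.n_eff:g}  N={m.params.n_census:g}",
            f"ddG mixture: p1={m.ddg.p1:g}  mean={m.ddg.mean:.3g} kcal/mol",
            f"grid: [{m.config.grid_min:g}, {m.config.grid_max:g}] "
            f"step {m.config.grid_step:g} kcal/mol",
            "-" * 55,
            f"start dG0:        {self.start:10.3f} kcal/mol",
            f"phases iterated:  {self.n_iterations:10d}"
            f"   converged: {self.converged}",
            f"KS-indistinguishable after: {self.ks_phase} phases",
            f"equilibrium mode: {eq.mode:10.3f} kcal/mol",
            f"equilibrium mean: {eq.mean:10.3f} kcal/mol",
            f"equilibrium s.d.: {eq.std:10.3f} kcal/mol",
            f"skewness:         {eq.skewness:10.3f}  "
            "(negative = tail toward higher stability)",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<StabilityEvolutionResults mode={self.mode:.3f} "
                f"mean={self.mean:.3f} phases={self.n_iterations} "
                f"converged={self.converged}>")


def equilibrium(template: ProteinSpec, cell: CellModel,
                params: FixationParams, ddg: DdgModel,
                config: EvolveConfig, start: float = -3.0
                ) -> Tuple[StabilityDistribution, int, bool]:
    """Functional wrapper: (limiting distribution, iterations, converged)."""
    model = StabilityEvolution(template, cell, params, ddg, config)
    res = model.fit(start=start)
    return res.equilibrium, res.n_iterations, res.converged


#: Figure-level sweep presets: (scenario, values, template/cell overrides)
SWEEP_PRESETS = {
    "fig4b": ("abundance", [1.0e4, 1.0e5, 1.0e6, 1.0e7], {"specific_rate": 2.8e-2}),
    "fig4c": ("temperature", [310.15, 320.15, 330.15, 340.15],
              {"specific_rate": 2.8e-2}),
    "fig4d": ("metabolic_rate", [0.9, 9.0, 90.0, 900.0], {}),
}


def sweep(scenario: str, values: Sequence[float], template: ProteinSpec,
          cell: CellModel, params: FixationParams, ddg: DdgModel,
          config: EvolveConfig, start: float = -3.0
          ) -> List[StabilityDistribution]:
    """Equilibrium distributions along one swept parameter.

    ``abundance`` edits the template's copy number; ``temperature`` the
    cell temperature (entering only through RT); ``metabolic_rate`` the
    cell's specific respiration rate (rescaling reproductive power and
    hence the cost coefficient).
    """
    out = []
    for v in values:
        if not math.isfinite(v):
            raise ValueError("sweep values must be finite")
        t, c = template, cell
        if scenario == "abundance":
            t = template.replace(abundance=float(v))
        elif scenario == "temperature":
            c = cell.replace(temperature=float(v), rt_override=None)
        elif scenario == "metabolic_rate":
            c = cell.replace(specific_rate=float(v), der_override=None)
        else:
            raise ValueError(f"unknown sweep scenario {scenario!r}")
        dist, _, _ = equilibrium(t, c, params, ddg, config, start=start)
        out.append(dist)
    return out


def sweep_preset(name: str, template: Optional[ProteinSpec] = None,
                 cell: Optional[CellModel] = None,
                 params: Optional[FixationParams] = None,
                 ddg: Optional[DdgModel] = None,
                 config: Optional[EvolveConfig] = None
                 ) -> Tuple[str, List[float], List[StabilityDistribution]]:
    """Run one captioned sweep preset; returns (scenario, values, dists)."""
    if name not in SWEEP_PRESETS:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(SWEEP_PRESETS)}")
    scenario, values, cell_overrides = SWEEP_PRESETS[name]
    template = template or ProteinSpec(abundance=2 ** 12)
    cell = cell or CellModel()
    if cell_overrides:
        cell = cell.replace(**cell_overrides)
    params = params or FixationParams(n_eff=1.0e7)
    ddg = ddg or DdgModel()
    config = config or EvolveConfig()
    return scenario, values, sweep(scenario, values, template, cell, params,
                                   ddg, config)
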