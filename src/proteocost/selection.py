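"""Fitness as chemical energy available for reproduction, and the selection
coefficients of proteostatic mutations.

Fitness is taken proportional to the power left for reproduction after
proteome maintenance.  Because total metabolic rate and non-proteome costs
are shared between wild type and mutant, the selection coefficient of a
mutation reduces to the change in proteome maintenance power divided by the
reproductive power:

    s = -(dE_maint' - dE_maint) / (dE_r/dt)        ("fixed_budget" mode)

The dimensionless per-unfolded-copy cost of protein i,

    c_i = N_aa * k_d * (2*C_s + C_d) / (N_A * dE_r/dt)     [costs in J/mol]

turns this into the classic misfolding-avoidance form ``s = -c_i * dU``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .cell import (CellModel, ProteinSpec, proteome_maintenance,
                   thermal_energy, unfolded_count)

log = logging.getLogger(__name__)

MODES = ("fixed_budget", "self_consistent")


@dataclass(frozen=True)
class SelectionResult:
    """Selection coefficient of a mutant proteome against a wild type."""

    s: float
    c_i: Optional[float]  # per-unfolded-copy cost of the mutated protein
    delta_u: Optional[float]  # change in steady-state unfolded copies
    delta_cost: float  # change in maintenance power, J/s
    mode: str


@dataclass(frozen=True)
class LandscapeGrid:
    """A 2-D grid of selection coefficients (or fixation probabilities)."""

    x_name: str
    x_values: np.ndarray
    y_name: str
    y_values: np.ndarray
    values: np.ndarray  # shape (len(y_values), len(x_values))
    metadata: dict

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.y_values), len(self.x_values)):
            raise ValueError("grid shape does not match axis lengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite entries")


def reproductive_power(cell: CellModel) -> float:
    """Power devoted to reproduction dE_r/dt, J/s.

    ``repro_fraction * cell_mass * specific_rate * (1 - nonproteome_fraction)``
    unless fixed directly by ``der_override``.
    """
    if cell.der_override is not None:
        der = cell.der_override
    else:
        der = (cell.repro_fraction * cell.cell_mass * cell.specific_rate
               * (1.0 - cell.nonproteome_fraction))
    if der <= 0:
        raise ValueError("reproductive power must be > 0 "
                         "(fitness denominator)")
    return der


def maintenance_budget(cell: CellModel) -> float:
    """Proteome power not devoted to reproduction, (1-F)*dE/dt_proteome, J/s."""
    return ((1.0 - cell.repro_fraction) * cell.cell_mass * cell.specific_rate
            * (1.0 - cell.nonproteome_fraction))


def fitness(proteome: Sequence[ProteinSpec], cell: CellModel,
            mode: str = "fixed_budget",
            reference: Optional[Sequence[ProteinSpec]] = None) -> float:
    """Fitness of a proteome as reproductive power, J/s.

    self_consistent mode: total proteome power minus the proteome's kinetic
    maintenance power.  fixed_budget mode: the fixed reproductive power minus the
    maintenance excess over a reference (wild-type) proteome, empty by
    default.  Negative values are allowed but flagged (the cell would enter
    a dormant, non-reproducing phase).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    maint = proteome_maintenance(proteome, cell)
    if mode == "self_consistent":
        total = (cell.cell_mass * cell.specific_rate
                 * (1.0 - cell.nonproteome_fraction))
        phi = total - maint
    else:
        ref = 0.0 if reference is None else proteome_maintenance(reference, cell)
        phi = reproductive_power(cell) - (maint - ref)
    if phi < 0:
        log.warning("negative fitness (%.3g J/s): proteome maintenance "
                    "exceeds available power (dormant phase)", phi)
    return phi


def cost_coefficient(protein: ProteinSpec, cell: CellModel) -> float:
    """Dimensionless fitness cost per steady-state unfolded copy, c_i."""
    der = reproductive_power(cell)
    per_copy_j_mol = protein.n_aa * protein.k_d * (2.0 * protein.c_s
                                                   + protein.c_d) * 1000.0
    return per_copy_j_mol / (cell.constants.avogadro * der)


def selection_coefficient(wt: Sequence[ProteinSpec],
                          mut: Sequence[ProteinSpec],
                          cell: CellModel,
                          mode: str = "fixed_budget") -> SelectionResult:
    """Selection coefficient of a mutant proteome vs the wild type.

    Any number of proteins may differ between the two proteomes (epistatic
    compensation is expressed as abundance edits of related proteins).
    fixed_budget mode: ``s = -d(maintenance)/dE_r``; self_consistent mode:
    ``s = (phi' - phi)/phi`` with the self-consistent fitness bookkeeping.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    m_wt = proteome_maintenance(wt, cell)
    m_mut = proteome_maintenance(mut, cell)
    delta_cost = m_mut - m_wt
    if mode == "fixed_budget":
        s = -delta_cost / reproductive_power(cell)
    else:
        phi_wt = fitness(wt, cell, mode="self_consistent")
        if phi_wt <= 0:
            raise ValueError("wild-type fitness must be > 0 "
                             "(selection denominator)")
        phi_mut = fitness(mut, cell, mode="self_consistent")
        s = (phi_mut - phi_wt) / phi_wt
    delta_u = None
    c_i = None
    changed = _single_change(wt, mut)
    if changed is not None:
        p_wt, p_mut = changed
        delta_u = (unfolded_count(p_mut, cell) - unfolded_count(p_wt, cell))
        c_i = cost_coefficient(p_wt, cell)
    return SelectionResult(s=s, c_i=c_i, delta_u=delta_u,
                           delta_cost=delta_cost, mode=mode)


def _single_change(wt: Sequence[ProteinSpec], mut: Sequence[ProteinSpec]
                   ) -> Optional[Tuple[ProteinSpec, ProteinSpec]]:
    """The (wt, mut) pair if exactly one protein differs, else None."""
    if len(wt) != len(mut):
        return None
    diffs = [(a, b) for a, b in zip(wt, mut) if a != b]
    if len(diffs) == 1:
        return diffs[0]
    return None


def s_stability(protein: ProteinSpec, dg_mut: float, cell: CellModel
                ) -> SelectionResult:
    """Selection coefficient when only the folding free energy changes.

    Uses the stable-protein approximation ``U = A * exp(dG/RT)``, so
    ``s = -c_i * A * (exp(dG'/RT) - exp(dG/RT))``.  ``dg_mut`` in kJ/mol.
    """
    rt = thermal_energy(cell)
    c_i = cost_coefficient(protein, cell)
    a = protein.abundance
    delta_u = a * (math.exp(dg_mut / rt) - math.exp(protein.dg_fold / rt))
    s = -c_i * delta_u
    der = reproductive_power(cell)
    return SelectionResult(s=s, c_i=c_i, delta_u=delta_u,
                           delta_cost=-s * der, mode="fixed_budget")


def s_abundance(protein: ProteinSpec, abundance_mut: float, cell: CellModel
                ) -> SelectionResult:
    """Selection coefficient when only the copy number changes.

    Exact steady-state unfolded counts, so this matches the general
    two-proteome ``selection_coefficient`` identically.
    """
    mut = protein.replace(abundance=abundance_mut)
    c_i = cost_coefficient(protein, cell)
    delta_u = unfolded_count(mut, cell) - unfolded_count(protein, cell)
    s = -c_i * delta_u
    der = reproductive_power(cell)
    return SelectionResult(s=s, c_i=c_i, delta_u=delta_u,
                           delta_cost=-s * der, mode="fixed_budget")


def s_misfolding_legacy(delta_u: float, c: float,
                        u_wt: float = 0.0) -> Tuple[float, float]:
    """Legacy misfolding-cost selection coefficient, both forms.

    Returns ``(log_form, linear_form)`` where the log form is
    ``ln(1 + c*U_wt) - ln(1 + c*U_mut)`` (the original per-copy
    multiplicative cost) and the linear form is ``-c * dU``, its
    first-order expansion.  The expansion error is ~ s^2/2, so the two
    agree to four decimal digits whenever |s| < 0.01.
    """
    if c < 0:
        raise ValueError("cost parameter c must be >= 0")
    u_mut = u_wt + delta_u
    log_form = math.log1p(c * u_wt) - math.log1p(c * u_mut)
    linear_form = -c * delta_u
    return log_form, linear_form


def round_to_power_of_ten(s: float) -> float:
    """Signed order-of-magnitude convention: ``sign(s) * 10**round(log10|s|)``."""
    if s == 0:
        return 0.0
    return math.copysign(10.0 ** round(math.log10(abs(s))), s)


_LANDSCAPE_AXES = ("abundance_mut", "abundance_wt", "k_d", "n_aa", "c_s")

#: Fig-1-style presets: (x axis, y axis, template overrides)
LANDSCAPE_PRESETS = {
    "fig1a": (("abundance_mut", np.linspace(0.0, 1.0e5, 51)),
              ("abundance_wt", np.linspace(0.0, 1.0e5, 51)), {}),
    "fig1b": (("abundance_mut", np.linspace(0.0, 1.0e5, 51)),
              ("k_d", np.geomspace(1.0e-5, 1.0e-1, 41)), {}),
    "fig1c": (("abundance_mut", np.linspace(0.0, 1.0e5, 51)),
              ("n_aa", np.linspace(100, 2000, 39)), {"k_d": 0.01}),
    "fig1d": (("abundance_mut", np.linspace(0.0, 1.0e5, 51)),
              ("c_s", np.linspace(300, 3000, 41)), {"k_d": 0.01}),
}


def _apply_axis(template: ProteinSpec, name: str, value: float,
                abundance_mut: float) -> Tuple[ProteinSpec, float]:
    """Substitute one axis value into (template, mutant abundance)."""
    if name == "abundance_mut":
        return template, float(value)
    if name == "abundance_wt":
        return template.replace(abundance=float(value)), abundance_mut
    if name == "n_aa":
        return template.replace(n_aa=int(round(value))), abundance_mut
    if name in ("k_d", "c_s"):
        return template.replace(**{name: float(value)}), abundance_mut
    raise ValueError(f"unknown landscape axis {name!r}; "
                     f"choose from {_LANDSCAPE_AXES}")


def landscape(template: ProteinSpec, cell: CellModel,
              x_spec: Tuple[str, Sequence[float]],
              y_spec: Tuple[str, Sequence[float]]) -> LandscapeGrid:
    """Grid of selection coefficients for expression-changing mutations.

    Each grid point substitutes the two axis values into the template
    wild-type protein and computes the selection coefficient of a mutant
    whose abundance is ``abundance_mut`` (defaulting to the wild type's if
    not an axis).
    """
    x_name, x_values = x_spec
    y_name, y_values = y_spec
    for name in (x_name, y_name):
        if name not in _LANDSCAPE_AXES:
            raise ValueError(f"unknown landscape axis {name!r}; "
                             f"choose from {_LANDSCAPE_AXES}")
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)
    values = np.empty((len(y_values), len(x_values)))
    for iy, yv in enumerate(y_values):
        for ix, xv in enumerate(x_values):
            wt, a_mut = _apply_axis(template, x_name, xv,
                                    template.abundance)
            wt, a_mut = _apply_axis(wt, y_name, yv, a_mut)
            values[iy, ix] = s_abundance(wt, a_mut, cell).s
    return LandscapeGrid(x_name=x_name, x_values=x_values,
                         y_name=y_name, y_values=y_values,
                         values=values,
                         metadata={"template": template, "cell": cell,
                                   "quantity": "s"})


def landscape_preset(name: str, cell: CellModel,
                     template: Optional[ProteinSpec] = None) -> LandscapeGrid:
    """One of the built-in selection-landscape presets (fig1a..fig1d)."""
    if name not in LANDSCAPE_PRESETS:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(LANDSCAPE_PRESETS)}")
    x_spec, y_spec, overrides = LANDSCAPE_PRESETS[name]
    template = template or ProteinSpec()
    if overrides:
        template = template.replace(**overrides)
    return landscape(template, cell, x_spec, y_spec)
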