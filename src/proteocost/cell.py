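"""Single-protein proteostasis: turnover kinetics, folding equilibrium, and
maintenance energetics.

A protein is modelled by the two-state scheme

    mRNA --k_s--> F <--k_1/k_2--> U --k_d--> degraded

at steady state, where the folded/unfolded ratio is set by the Boltzmann
factor ``U/F = exp(dG/RT)`` with ``dG`` the folding free energy (negative
for stable folds).  Each degraded copy must be resynthesised, so the
steady-state maintenance power of a protein is the flux of copies through
the degradation pathway times the per-copy handling cost
``N_aa * (2*C_s + C_d)`` (synthesis of the chain plus its precursors, and
degradation), converted from kJ/mol to J per molecule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

log = logging.getLogger(__name__)

KCAL_PER_KJ = 1.0 / 4.184
#: average amino-acid mass used for protein molecular weights, g/mol
AVERAGE_AA_MASS = 130.0
#: ribosomal chain-elongation rate, amino acids per second
RIBOSOME_RATE = 15.0


@dataclass(frozen=True)
class EnergyConstants:
    """Physical constants used throughout, in molar energy units."""

    gas_constant: float = 0.008314  # kJ mol^-1 K^-1
    avogadro: float = 6.022e23  # mol^-1
    kcal_per_kj: float = KCAL_PER_KJ

    def __post_init__(self) -> None:
        for name in ("gas_constant", "avogadro", "kcal_per_kj"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


CONSTANTS = EnergyConstants()


@dataclass(frozen=True)
class ProteinSpec:
    """Turnover, cost and stability parameters of one protein.

    Parameters
    ----------
    name : str
        Identifier.
    n_aa : int
        Chain length in residues (>= 1).
    abundance : float
        Steady-state copy number per cell, folded + unfolded.
    dg_fold : float
        Folding free energy in kJ/mol; negative for stable proteins.
    k_d : float
        Degradation rate constant, s^-1 (acts on unfolded copies).
    c_s : float
        Synthesis cost per residue, kJ/mol (precursors + chain synthesis).
    c_d : float
        Degradation cost per residue, kJ/mol.
    mrna : float, optional
        mRNA copy number; defaults to ``1e-4 * abundance``.
    k_fold : float
        Folding rate constant, s^-1; only used as an advisory synthesis cap.
    """

    name: str = "protein"
    n_aa: int = 467
    abundance: float = 1.0e4
    dg_fold: float = -37.0
    k_d: float = 2.69e-4
    c_s: float = 1500.0
    c_d: float = 30.0
    mrna: Optional[float] = None
    k_fold: float = 1.0e-5

    def __post_init__(self) -> None:
        if self.n_aa < 1:
            raise ValueError("n_aa must be >= 1")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if self.k_d <= 0:
            raise ValueError("k_d must be > 0")
        if self.c_s < 0 or self.c_d < 0:
            raise ValueError("per-residue costs must be >= 0")
        if not math.isfinite(self.dg_fold):
            raise ValueError("dg_fold must be finite")
        if self.mrna is None:
            object.__setattr__(self, "mrna", 1.0e-4 * self.abundance)
        if self.abundance > 0 and self.mrna <= 0:
            raise ValueError("mrna must be > 0 when abundance > 0")

    @property
    def molecular_weight(self) -> float:
        """Protein mass in g/mol at the average residue mass (130 g/mol)."""
        return AVERAGE_AA_MASS * self.n_aa

    def replace(self, **changes) -> "ProteinSpec":
        """Return a copy with the given fields changed.

        ``mrna`` is re-derived from the new abundance unless given
        explicitly, so abundance edits keep the default 1e-4 coupling.
        """
        fields = {
            "name": self.name,
            "n_aa": self.n_aa,
            "abundance": self.abundance,
            "dg_fold": self.dg_fold,
            "k_d": self.k_d,
            "c_s": self.c_s,
            "c_d": self.c_d,
            "mrna": None if "abundance" in changes and "mrna" not in changes else self.mrna,
            "k_fold": self.k_fold,
        }
        fields.update(changes)
        return ProteinSpec(**fields)


@dataclass(frozen=True)
class CellModel:
    """Organism-level energy bookkeeping.

    The total metabolic rate of the cell is ``cell_mass * specific_rate``;
    a fraction ``nonproteome_fraction`` of it covers non-proteome costs
    (RNA metabolism, ion pumps, ...), and of the proteome share a fraction
    ``repro_fraction`` is spent on reproduction.  Defaults describe a yeast
    cell at 37 C.
    """

    temperature: float = 310.15  # K
    rt_override: Optional[float] = None  # kJ/mol; replaces R*T when set
    cell_mass: float = 3.4e-11  # g
    specific_rate: float = 0.9  # J s^-1 g^-1
    nonproteome_fraction: float = 1.0 / 3.0
    repro_fraction: float = 0.10
    der_override: Optional[float] = None  # J s^-1; fixes dE_r/dt directly
    n_eff: float = 1.0e7
    n_census: Optional[float] = None
    constants: EnergyConstants = field(default=CONSTANTS)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0 < self.repro_fraction < 1:
            raise ValueError("repro_fraction must lie in (0, 1)")
        if not 0 <= self.nonproteome_fraction < 1:
            raise ValueError("nonproteome_fraction must lie in [0, 1)")
        if self.n_eff < 1:
            raise ValueError("n_eff must be >= 1")
        if self.n_census is None:
            object.__setattr__(self, "n_census", self.n_eff)
        if self.n_census < self.n_eff:
            raise ValueError("n_census must be >= n_eff")
        if self.rt_override is not None and self.rt_override <= 0:
            raise ValueError("rt_override must be > 0")

    def replace(self, **changes) -> "CellModel":
        fields = {f: getattr(self, f) for f in (
            "temperature", "rt_override", "cell_mass", "specific_rate",
            "nonproteome_fraction", "repro_fraction", "der_override",
            "n_eff", "n_census", "constants")}
        fields.update(changes)
        return CellModel(**fields)


class SynthesisRate(NamedTuple):
    """Steady-state synthesis rate constant with the Table-level advisory cap."""

    value: float  # s^-1, flux form 2*k_d*U/mRNA
    ribosome_cap: float  # s^-1, min(ribosome rate / n_aa, k_fold)


@dataclass(frozen=True)
class SteadyState:
    """Per-protein steady-state stocks, rates and maintenance power."""

    u: float  # unfolded (nonfunctional) copies
    f: float  # folded copies
    p_folded: float
    k_s: SynthesisRate
    cost_power: float  # J/s


def thermal_energy(cell: CellModel) -> float:
    """Molar thermal energy RT in kJ/mol (or the cell's override)."""
    if cell.rt_override is not None:
        return cell.rt_override
    return cell.constants.gas_constant * cell.temperature


def unfolded_count(protein: ProteinSpec, cell: CellModel,
                   approximate: bool = False) -> float:
    """Steady-state number of unfolded copies.

    Exact two-state form ``A * exp(dG/RT) / (1 + exp(dG/RT))`` by default;
    with ``approximate=True`` the small-``exp(dG/RT)`` form ``A * exp(dG/RT)``
    (valid for proteins much more stable than -RT).  Both saturate rather
    than overflow for strongly positive ``dg_fold``.
    """
    rt = thermal_energy(cell)
    x = protein.dg_fold / rt
    if approximate:
        if x > 0:
            log.warning("approximate unfolded count requested for unstable "
                        "protein %s (dG=%.3g); clamping at abundance",
                        protein.name, protein.dg_fold)
            return min(protein.abundance, protein.abundance * math.exp(min(x, 700.0)))
        return protein.abundance * math.exp(x)
    # exact logistic form, written to avoid overflow on either side
    if x >= 0:
        frac = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        frac = e / (1.0 + e)
    return protein.abundance * frac


def prob_folded(protein: ProteinSpec, cell: CellModel) -> float:
    """Probability that one copy is folded: ``1 / (1 + exp(dG/RT))``."""
    rt = thermal_energy(cell)
    x = protein.dg_fold / rt
    if x <= 0:
        return 1.0 / (1.0 + math.exp(x))
    e = math.exp(-x)
    return e / (1.0 + e)


def synthesis_rate(protein: ProteinSpec, cell: CellModel,
                   approximate: bool = False) -> SynthesisRate:
    """Steady-state synthesis rate constant ``k_s = 2 k_d U / mRNA``.

    The flux form balances the degradation flux (every degraded copy is
    replaced, and synthesis passes through the unfolded state, hence the
    factor two).  The advisory cap ``min(R/n_aa, k_fold)`` is the slowest
    of ribosomal elongation and folding and is reported alongside.
    """
    u = unfolded_count(protein, cell, approximate=approximate)
    if u > 0 and (protein.mrna is None or protein.mrna <= 0):
        raise ValueError(
            f"protein {protein.name!r}: nonzero abundance with zero mRNA")
    value = 0.0 if u == 0 else 2.0 * protein.k_d * u / protein.mrna
    cap = min(RIBOSOME_RATE / protein.n_aa, protein.k_fold)
    return SynthesisRate(value=value, ribosome_cap=cap)


def maintenance_power(protein: ProteinSpec, cell: CellModel,
                      approximate: bool = False) -> float:
    """Steady-state maintenance power of one protein, J/s.

    Degradation flux ``k_d * U`` copies/s, each costing
    ``n_aa * (2*c_s + c_d)`` kJ/mol to replace and clear; converted to J
    per molecule via Avogadro's number.
    """
    u = unfolded_count(protein, cell, approximate=approximate)
    per_copy_kj_mol = protein.n_aa * (2.0 * protein.c_s + protein.c_d)
    return protein.k_d * u * per_copy_kj_mol * 1000.0 / cell.constants.avogadro


def proteome_maintenance(proteome: Sequence[ProteinSpec], cell: CellModel,
                         approximate: bool = False) -> float:
    """Summed maintenance power of a proteome, J/s (0 for an empty one)."""
    return sum(maintenance_power(p, cell, approximate=approximate)
               for p in proteome)


def steady_state(protein: ProteinSpec, cell: CellModel,
                 approximate: bool = False) -> SteadyState:
    """All per-protein steady-state quantities in one pass."""
    u = unfolded_count(protein, cell, approximate=approximate)
    pf = prob_folded(protein, cell)
    f = protein.abundance - u if not approximate else protein.abundance * pf
    return SteadyState(
        u=u,
        f=f,
        p_folded=pf,
        k_s=synthesis_rate(protein, cell, approximate=approximate),
        cost_power=maintenance_power(protein, cell, approximate=approximate),
    )
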