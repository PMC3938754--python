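"""Synthetic proteome tables with field-typical statistical structure.

Abundances span five orders of magnitude (log-uniform), chain lengths are
gamma-distributed around a 467-residue mean, half-lives are lognormal with
a 43-minute median (so k_d has median ln2/(43*60) ~ 2.7e-4 /s), and folding
free energies are Gaussian around -37 kJ/mol truncated to stay below
-0.5 kJ/mol.  Handling costs default to 1500 (synthesis) and 30
(degradation) kJ/mol per residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .cell import ProteinSpec

log = logging.getLogger(__name__)

COLUMNS = ["name", "n_aa", "abundance", "dg_fold_kj", "k_d_s",
           "c_s_kj", "c_d_kj", "mrna", "k_fold"]


@dataclass(frozen=True)
class ProteomeGenConfig:
    """Distributional parameters of the generator; the seed is mandatory."""

    n_proteins: int = 1000
    seed: int = 0
    abundance_log10_range: tuple = (0.0, 5.0)
    length_mean: float = 467.0
    length_shape: float = 4.0  # gamma shape (right-skewed, positive)
    half_life_median_min: float = 43.0
    half_life_log_sd: float = 1.0  # sd of ln(half-life)
    dg_mean_kj: float = -37.0
    dg_sd_kj: float = 8.0
    dg_max_kj: float = -0.5  # truncation: all proteins at least this stable
    c_s_kj: float = 1500.0
    c_d_kj: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.abundance_log10_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("abundance_log10_range must be a finite (lo, hi)")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.length_mean <= 0 or self.length_shape <= 0:
            raise ValueError("length parameters must be > 0")
        if self.half_life_median_min <= 0 or self.half_life_log_sd <= 0:
            raise ValueError("half-life parameters must be > 0")
        if self.dg_sd_kj <= 0 or not np.isfinite(self.dg_mean_kj):
            raise ValueError("dg parameters invalid")


def generate(config: ProteomeGenConfig) -> List[ProteinSpec]:
    """Draw a reproducible synthetic proteome."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    lo, hi = config.abundance_log10_range
    abundance = 10.0 ** rng.uniform(lo, hi, size=n)
    lengths = rng.gamma(config.length_shape,
                        config.length_mean / config.length_shape, size=n)
    n_aa = np.maximum(np.rint(lengths).astype(int), 30)
    half_life_s = 60.0 * config.half_life_median_min * np.exp(
        rng.normal(0.0, config.half_life_log_sd, size=n))
    k_d = np.log(2.0) / half_life_s
    dg = rng.normal(config.dg_mean_kj, config.dg_sd_kj, size=n)
    # reflect mass above the truncation bound back below it
    over = dg > config.dg_max_kj
    dg[over] = 2.0 * config.dg_max_kj - dg[over]
    return [
        ProteinSpec(name=f"prot{i:05d}", n_aa=int(n_aa[i]),
                    abundance=float(abundance[i]), dg_fold=float(dg[i]),
                    k_d=float(k_d[i]), c_s=config.c_s_kj, c_d=config.c_d_kj)
        for i in range(n)
    ]


def to_frame(proteome: Sequence[ProteinSpec]) -> pd.DataFrame:
    rows = [{"name": p.name, "n_aa": p.n_aa, "abundance": p.abundance,
             "dg_fold_kj": p.dg_fold, "k_d_s": p.k_d, "c_s_kj": p.c_s,
             "c_d_kj": p.c_d, "mrna": p.mrna, "k_fold": p.k_fold}
            for p in proteome]
    return pd.DataFrame(rows, columns=COLUMNS)


def write_proteome(proteome: Sequence[ProteinSpec], path) -> None:
    """Write the tab-separated proteome table (header always present)."""
    # %.17g keeps the round trip exact to the bit
    to_frame(proteome).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")


def read_proteome(path) -> List[ProteinSpec]:
    """Read a proteome TSV back into ProteinSpec objects.

    Unknown columns are preserved-but-warned; positive ``dg_fold_kj``
    entries are interpreted as stabilities quoted with the opposite sign
    convention and negated with a loud warning.  Malformed rows raise with
    their line number.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"proteome table missing required columns {missing}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        log.warning("ignoring unknown proteome columns %s", extra)
    out = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line_no = pos + 2  # 1-based, after the header line
        try:
            dg = float(row["dg_fold_kj"])
            if dg > 0:
                log.warning(
                    "line %d (%s): positive dg_fold_kj %.3g interpreted as a "
                    "stability magnitude; negating", line_no, row["name"], dg)
                dg = -dg
            kwargs = {}
            if "mrna" in df.columns and pd.notna(row.get("mrna")):
                kwargs["mrna"] = float(row["mrna"])
            if "k_fold" in df.columns and pd.notna(row.get("k_fold")):
                kwargs["k_fold"] = float(row["k_fold"])
            out.append(ProteinSpec(
                name=str(row["name"]), n_aa=int(row["n_aa"]),
                abundance=float(row["abundance"]), dg_fold=dg,
                k_d=float(row["k_d_s"]), c_s=float(row["c_s_kj"]),
                c_d=float(row["c_d_kj"]), **kwargs))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed proteome row at line {line_no}: {exc}"
                             ) from exc
    return out
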