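# Methods

## The model

A protein `i` is described by a two-state turnover scheme at steady state:
synthesis feeds the folded pool `F_i`, folding/unfolding exchange
`F_i ⇌ U_i` equilibrates with ratio `U_i/F_i = exp(ΔG_i/RT)` (ΔG < 0 for
stable folds), and degradation removes unfolded copies at rate `k_d·U_i`.
Every degraded copy must be replaced, so maintaining protein `i` costs

    P_i = N_aa,i · k_d,i · U_i · (2·C_s,i + C_d,i) / N_A      [J/s]

with `C_s` and `C_d` the per-residue synthesis and degradation costs in
J/mol (the factor 2 on `C_s` counts precursor plus chain-synthesis cost of
the replacement flux through the unfolded state) and `N_A` Avogadro's
number. The synthesis rate constant implied by flux balance is
`k_s = 2·k_d·U/mRNA`; an advisory cap `min(R/N_aa, k_fold)` (ribosomal
elongation at R = 15 aa/s vs the folding rate) is reported alongside but
does not enter the energetics.

Fitness is taken proportional to the power left for reproduction. Because
total metabolic rate and non-proteome costs are common to wild type and
mutant, the selection coefficient of any proteome edit reduces to

    s = −ΔP / (dE_r/dt),     dE_r/dt = F · m_cell · q · (1 − f_C)

with `q` the specific metabolic rate (J/s/g), `f_C` the non-proteome
fraction and `F` the reproductive fraction. Defaults describe a yeast
cell: m = 3.4e-11 g, q = 0.9 J/s/g, f_C = 1/3, F = 0.10, giving
dE_r/dt = 2.04e-12 J/s and a per-unfolded-copy cost
`c_i = N_aa·k_d·(2C_s+C_d)/(N_A·dE_r/dt) ≈ 3.1e-7` for an average protein
(467 aa, k_d = 2.69e-4 s⁻¹, C_s = 1500, C_d = 30 kJ/mol). Two bookkeeping
modes exist: the default "fixed_budget" mode divides Δcost by the fixed
dE_r/dt; "self_consistent" mode evaluates `(Φ′−Φ)/Φ` with
`Φ = proteome power − kinetic maintenance`. They differ only at second
order in s for realistic parameters.

Fixation follows the haploid Kimura diffusion form with effective size
`N_eff` and census size `N` (defaulting to `N_eff`, so the neutral limit
is 1/N_eff). Whether a haploid or diploid variant is intended by the
source literature is not recoverable; near the drift boundary the
figure-level behavior is insensitive to that factor of two, and the form
is swappable by passing a different callable where needed.

Stability evolution is origin–fixation dynamics over the scalar ΔG
(kcal/mol): mutational effects ΔΔG are drawn from a bi-Gaussian mixture,
each arising mutation fixes with `P_fix(s(ΔG→ΔG+ΔΔG))`, and time is
counted in fixed mutations. Discretized on a uniform grid this is a
row-normalized Markov kernel `K(i,j) ∝ p_ΔΔG(G_j−G_i)·P_fix(s_ij)`
(normalization conditions on one fixation per phase); iterating
`P_{t+1} = Kᵀ P_t` converges to the mutation–selection equilibrium.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| temperature | 310.15 | K | 37 °C reference |
| rt_override | off (2.5 opt.) | kJ/mol | the worked yeast numbers (0.037 / 4.5 / 19 unfolded copies) only reproduce with RT = 2.5, i.e. T ≈ 300.7 K; physical RT is the default, the override is the documented parity mode |
| cell_mass, specific_rate | 3.4e-11, 0.9 | g, J/s/g | yeast cell respiration |
| nonproteome_fraction, repro_fraction | 1/3, 0.10 | – | proteome share 0.6 J/s/g; 10 % of it reproduces |
| k_d | 2.69e-4 | s⁻¹ | 43-min median half-life |
| C_s, C_d | 1500, 30 | kJ/mol per aa | conservative synthesis cost incl. precursors; ~1 ATP per residue degraded |
| mRNA | 1e-4·A | copies | typical mRNA:protein ratio; cancels out of the energetics, affects only the reported k_s |
| ΔΔG mixture | μ=0.56, 1.96; σ=0.90, 1.93 | kcal/mol | two-lobe fit of mutational stability effects |
| p1 | 0.7 | – | the mixture weight is not fixed by the source data; 0.7 puts the mean effect near 1 kcal/mol (~5 kJ/mol, the typical destabilization). The equilibrium mode moves < 0.1 kcal/mol over p1 ∈ {0.5, 0.7, 0.9} (tested) |
| ΔG grid | [−15, −0.5] step 0.05 | kcal/mol | covers the empirical stability range; near ΔG = 0 fixation probabilities vanish so the upper cut is inert |
| N_eff | 1e7 | – | yeast-scale effective population |
| convergence_tol | 1e-6 | TV distance | per-phase total-variation change; the default problem converges in ~36 phases, well past the ~9 phases after which consecutive distributions are statistically indistinguishable (KS diagnostic at α = 0.05) |

Sign conventions: ΔG < 0 is stable; ΔΔG = ΔG_new − ΔG_old with positive =
destabilizing. Table inputs quoting stabilities as positive magnitudes are
negated by the readers with a warning. All molar energies are kJ/mol
internally; the ΔG evolution grid is kcal/mol (×4.184 at the interface),
matching how stability distributions are usually plotted.

## Numerical choices

- `P_fix`: `expm1`-based evaluation; a first-order series replaces the
  0/0 ratio for |2·N_eff·s| < 1e-8; strongly deleterious exponents are
  taken in log space and underflow cleanly to 0; s ≤ −1 returns 0 with a
  warning.
- Kernel boundaries: proposal mass falling off the grid is truncated
  before row normalization. A row with no fixable target raises rather
  than silently renormalizing noise.
- The stability shortcut `s = −c_i·A·(e^{ΔG′/RT} − e^{ΔG/RT})` uses the
  stable-protein approximation `U ≈ A·e^{ΔG/RT}` (relative error
  `e^{ΔG/RT}`, ≤ 1e-4 over the whole grid); abundance-change selection
  uses exact logistic U and matches the general two-proteome computation
  to machine precision.
- Monte-Carlo origin–fixation sampler: proposals are snapped to the
  nearest grid point and accepted with probability `P_fix/M_i`, with the
  envelope `M_i = 1.1 × max_j P_fix(i→j)` per source state (P_fix is
  monotone in s, so the grid maximum is a near-tight bound). Accepted
  moves are then distributed exactly as the kernel row. A vanishing
  acceptance rate (< 1e-6) raises instead of looping. One seeded
  generator drives the vectorized rejection loop, so runs are bitwise
  reproducible per (seed, config).
- Proteome TSVs are written with `%.17g` and parsed with round-trip float
  precision so read(write(x)) is exact.

## The synthetic proteome generator

`generate()` emulates the marginal statistics the model cares about:
log-uniform abundances over five orders of magnitude (guaranteeing range
coverage in small samples, unlike a lognormal), gamma-distributed lengths
(mean 467, shape 4), lognormal half-lives (median 43 min, log-sd 1),
Gaussian stabilities (mean −37, sd 8 kJ/mol) reflected below −0.5 kJ/mol,
and constant handling costs. It does **not** reproduce the joint
correlations of real proteomes (abundance–length anticorrelation,
abundance–stability coupling, cost variation across sequences), so tests
passing on synthetic proteomes validate the energy bookkeeping and
scaling laws, not any claim about a particular organism's proteome.

## Problem sizes used in tests

The default grid (291 states) makes kernel construction and iteration
essentially instant; the stochastic cross-checks use 1e4 replicates for
the per-phase KS comparisons and 2e4 Wright–Fisher replicates at N = 100,
Ns = 2 for the fixation-probability cross-check — sizes chosen so Monte-
Carlo error is far below the effect sizes being tested.

## Known limitations

- Strictly sequential origin–fixation: no polymorphism, clonal
  interference, or explicit sequences; evolution is over the scalar ΔG.
- No chaperone/refolding pathway, no time-dependent (non-steady-state)
  kinetics, no savings/storage term in the energy budget.
- Temperature enters only through RT (ΔG itself is treated as
  temperature-independent; no heat-capacity term), which isolates the
  turnover-cost mechanism but understates real thermal denaturation.
- Compensatory expression of hypomorphic mutations is an input (an
  abundance edit, possibly multi-gene), not inferred.
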