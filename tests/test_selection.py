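"""Fitness bookkeeping, cost coefficient, and selection coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteocost import (CellModel, ProteinSpec, cost_coefficient, fitness,
                        landscape, landscape_preset, maintenance_budget,
                        reproductive_power, round_to_power_of_ten,
                        s_abundance, s_misfolding_legacy, s_stability,
                        selection_coefficient)


class TestEnergyBudget:
    def test_reproductive_power_default_cell(self, cell):
        assert reproductive_power(cell) == pytest.approx(2.04e-12, rel=1e-6)

    def test_maintenance_budget_default_cell(self, cell):
        assert maintenance_budget(cell) == pytest.approx(1.84e-11, rel=3e-3)

    def test_der_override(self):
        cell = CellModel(der_override=1.0e-12)
        assert reproductive_power(cell) == 1.0e-12

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError, match="reproductive power"):
            reproductive_power(CellModel(der_override=0.0))


class TestCostCoefficient:
    def test_default_protein_value(self, cell, protein):
        # hand arithmetic: 467*2.69e-4*3030*1000/(6.022e23*2.04e-12)
        assert cost_coefficient(protein, cell) == pytest.approx(3.10e-7,
                                                                rel=2e-3)

    def test_linear_in_turnover(self, cell, protein):
        doubled = protein.replace(k_d=2 * protein.k_d)
        assert cost_coefficient(doubled, cell) == pytest.approx(
            2.0 * cost_coefficient(protein, cell), rel=1e-12)

    def test_zero_costs(self, cell):
        free = ProteinSpec(c_s=0.0, c_d=0.0)
        assert cost_coefficient(free, cell) == 0.0

    def test_inverse_in_reproductive_power(self, protein):
        lo = CellModel(specific_rate=0.9)
        hi = CellModel(specific_rate=9.0)
        assert cost_coefficient(protein, lo) == pytest.approx(
            10.0 * cost_coefficient(protein, hi), rel=1e-12)


class TestFitness:
    def test_empty_proteome_self_consistent(self, cell):
        total = cell.cell_mass * cell.specific_rate * (2.0 / 3.0)
        assert fitness([], cell, mode="self_consistent") == pytest.approx(
            total)

    def test_identical_proteomes_equal_fitness(self, cell, protein):
        assert fitness([protein], cell) == fitness([protein], cell)

    def test_extra_protein_decreases_fitness(self, cell, protein):
        assert fitness([protein, protein], cell) < fitness([protein], cell)


class TestSelectionCoefficient:
    def test_no_change_is_neutral(self, cell, protein):
        for mode in ("fixed_budget", "self_consistent"):
            assert selection_coefficient([protein], [protein], cell,
                                         mode=mode).s == 0.0

    @pytest.mark.parametrize("a_wt, a_mut, magnitude", [
        (1e4, 1e5, -1e-8),   # 10-fold compensatory overexpression
        (1e5, 1e6, -1e-7),   # same, for a highly expressed protein
    ])
    def test_compensatory_expression_magnitudes(self, parity_cell, a_wt,
                                                a_mut, magnitude):
        wt = ProteinSpec(abundance=a_wt)
        res = selection_coefficient([wt], [wt.replace(abundance=a_mut)],
                                    parity_cell)
        assert res.s < 0
        assert round_to_power_of_ten(res.s) == magnitude

    def test_swap_identity_self_consistent(self, cell):
        wt = [ProteinSpec(abundance=1e4)]
        mut = [ProteinSpec(abundance=1e6)]
        s = selection_coefficient(wt, mut, cell, mode="self_consistent").s
        s_back = selection_coefficient(mut, wt, cell,
                                       mode="self_consistent").s
        assert s_back == pytest.approx(-s / (1.0 + s), rel=1e-9)

    def test_epistatic_multi_protein_edit(self, cell):
        a = ProteinSpec(name="a", abundance=1e4)
        b = ProteinSpec(name="b", abundance=2e4)
        mut = [a.replace(abundance=2e4), b.replace(abundance=4e4)]
        res = selection_coefficient([a, b], mut, cell)
        # both abundance doublings contribute additively to the cost
        single = (selection_coefficient([a], [mut[0]], cell).s
                  + selection_coefficient([b], [mut[1]], cell).s)
        assert res.s == pytest.approx(single, rel=1e-12)

    def test_abundance_shortcut_matches_general(self, cell):
        # single-protein shortcut vs two full proteomes, fixed-budget mode
        wt = ProteinSpec(abundance=1e4, dg_fold=-20.0)
        background = [ProteinSpec(name=f"bg{i}", abundance=10 ** i)
                      for i in range(1, 4)]
        general = selection_coefficient(background + [wt],
                                        background + [wt.replace(abundance=3e4)],
                                        cell)
        shortcut = s_abundance(wt, 3e4, cell)
        assert shortcut.s == pytest.approx(general.s, rel=1e-9)


class TestStabilitySelection:
    def test_no_stability_change_is_neutral(self, cell, protein):
        assert s_stability(protein, protein.dg_fold, cell).s == 0.0

    def test_worked_destabilization(self, parity_cell):
        p = ProteinSpec(abundance=1e5)
        res = s_stability(p, -25.0, parity_cell)
        assert res.delta_u == pytest.approx(4.5, rel=0.01)
        assert abs(res.s) == pytest.approx(1.39e-6, rel=0.01)
        assert abs(res.s) >= 1e-6

    def test_stabilizing_is_beneficial(self, cell, protein):
        assert s_stability(protein, protein.dg_fold - 5.0, cell).s > 0

    def test_matches_general_selection_coefficient(self, cell):
        wt = ProteinSpec(abundance=1e5, dg_fold=-37.0)
        shortcut = s_stability(wt, -25.0, cell)
        general = selection_coefficient([wt], [wt.replace(dg_fold=-25.0)],
                                        cell)
        # the shortcut uses the stable-protein approximation for U
        assert shortcut.s == pytest.approx(general.s, rel=1e-4)


class TestLegacyMisfoldingForm:
    def test_no_change(self):
        log_form, linear_form = s_misfolding_legacy(0.0, 3.1e-7)
        assert log_form == 0.0 and linear_form == 0.0

    def test_forms_agree_to_four_digits(self):
        # agreement to within 1e-4 (four decimal digits): the expansion
        # error is s^2/2, so ~5e-7 at s = 1e-3
        log_form, linear_form = s_misfolding_legacy(delta_u=1e-3 / 3.1e-7,
                                                    c=3.1e-7)
        assert abs(log_form - linear_form) < 1e-4
        assert abs(log_form - linear_form) == pytest.approx(
            linear_form ** 2 / 2.0, rel=1e-2)

    def test_product_oracle(self):
        _, linear_form = s_misfolding_legacy(delta_u=4.5, c=3.10e-7)
        assert linear_form == pytest.approx(-1.395e-6, rel=1e-3)

    @given(c=st.floats(1e-9, 1e-5), delta_u=st.floats(0.1, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_agreement_whenever_selection_weak(self, c, delta_u):
        # whenever |s| < 0.01 the two forms agree to four decimal digits
        # (the first-order expansion error is bounded by s^2/2)
        log_form, linear_form = s_misfolding_legacy(delta_u, c)
        if abs(linear_form) < 0.01:
            assert abs(log_form - linear_form) < 1e-4
            assert abs(log_form - linear_form) <= 0.6 * linear_form ** 2

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            s_misfolding_legacy(1.0, -1.0)


class TestFactorization:
    """|s| of an abundance change factorizes as A*N_aa*k_d*(2C_s+C_d)*exp(dG/RT)."""

    @pytest.mark.parametrize("field, factor", [
        ("n_aa", 2), ("k_d", 3.0), ("abundance", 5.0),
    ])
    def test_linear_scaling(self, cell, field, factor):
        base = ProteinSpec(abundance=1e4)
        scaled = base.replace(**{field: type(getattr(base, field))(
            factor * getattr(base, field))})
        s0 = s_abundance(base, 10.0 * base.abundance, cell).s
        s1 = s_abundance(scaled, 10.0 * scaled.abundance, cell).s
        assert s1 == pytest.approx(factor * s0, rel=1e-9)

    def test_boltzmann_scaling(self, cell):
        base = ProteinSpec(abundance=1e4, dg_fold=-40.0)
        shifted = base.replace(dg_fold=-35.0)
        rt = 0.008314 * cell.temperature
        ratio = (s_abundance(shifted, 1e5, cell).s
                 / s_abundance(base, 1e5, cell).s)
        assert ratio == pytest.approx(math.exp(5.0 / rt), rel=1e-3)

    def test_inverse_in_metabolic_rate(self):
        p = ProteinSpec(abundance=1e4)
        s_lo = s_abundance(p, 1e5, CellModel(specific_rate=0.9)).s
        s_hi = s_abundance(p, 1e5, CellModel(specific_rate=9.0)).s
        assert s_lo == pytest.approx(10.0 * s_hi, rel=1e-12)


class TestLandscape:
    def test_single_point_neutral(self, cell, protein):
        grid = landscape(protein, cell,
                         ("abundance_mut", [protein.abundance]),
                         ("abundance_wt", [protein.abundance]))
        assert grid.values.shape == (1, 1)
        assert grid.values[0, 0] == 0.0

    def test_linear_in_mutant_abundance(self, cell, protein):
        grid = landscape(protein, cell,
                         ("abundance_mut", np.linspace(0, 1e5, 11)),
                         ("abundance_wt", [1e4]))
        row = grid.values[0]
        diffs = np.diff(row)
        assert np.allclose(diffs, diffs[0], rtol=1e-9)
        assert diffs[0] < 0  # more mutant copies, lower fitness

    def test_stronger_selection_at_higher_turnover(self, cell, protein):
        grid = landscape(protein, cell,
                         ("abundance_mut", [1e5]),
                         ("k_d", [1e-4, 1e-3, 1e-2]))
        col = grid.values[:, 0]
        assert np.all(np.diff(col) < 0)

    def test_unknown_axis_rejected(self, cell, protein):
        with pytest.raises(ValueError, match="axis"):
            landscape(protein, cell, ("dg_fold", [1.0]),
                      ("abundance_wt", [1e4]))

    def test_fig1_presets_shapes(self, cell):
        grid = landscape_preset("fig1a", cell)
        assert grid.values.shape == (51, 51)
        assert np.all(np.isfinite(grid.values))
        with pytest.raises(ValueError, match="preset"):
            landscape_preset("nope", cell)
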