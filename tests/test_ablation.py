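"""Vein ablation, flow-change comparison, and cross-vein substitution."""

import numpy as np
import pytest

import wingflux as wf
from wingflux import drosophila
from wingflux.ablation import PlacementError, insert_cross_vein


@pytest.fixture(scope="module")
def comparison(sol_without, sol_with):
    return wf.compare_flows(sol_without, sol_with)


class TestRemoveVein:
    def test_pcv_removal_keeps_network_solvable(self, forewing, fluid, bc):
        net = wf.remove_vein(forewing, "PCV")
        assert len(net) == 22
        assert "A" in net.nodes and "P" in net.nodes
        wf.solve_nodal(net, fluid, bc)  # must not raise

    def test_rail_vein_removal_keeps_connectivity(self, forewing, fluid, bc):
        net = wf.remove_vein(forewing, "V_E_1")
        sol = wf.solve_nodal(net, fluid, bc)
        # all inflow must now take the base rail
        assert sol.flow_rates["V_B_1"] == pytest.approx(
            bc.inflow_rate_um3_s, rel=1e-9)

    def test_unknown_vein(self, forewing):
        with pytest.raises(KeyError):
            wf.remove_vein(forewing, "V_X_9")


class TestCompareFlows:
    def test_sixth_pair_flow_decreases(self, comparison):
        # the PCV bypasses the sixth edge-base pair
        t = comparison.table
        drop_e6 = 1.0 - t.loc["V_E_6", "magnitude_ratio"]
        drop_b6 = 1.0 - t.loc["V_B_6", "magnitude_ratio"]
        assert drop_e6 == pytest.approx(0.69, abs=0.05)
        assert drop_b6 == pytest.approx(0.28, abs=0.05)

    def test_direction_flips_in_split_rung_segments(self, comparison):
        flipped = set(comparison.direction_changed())
        assert {"V_C_5_B", "V_C_6_E"} <= flipped
        assert "V_E_6" not in flipped and "V_B_6" not in flipped

    def test_pressure_loss_decrease_rate(self, comparison):
        assert 100 * comparison.pressure_loss_decrease_rate == pytest.approx(
            20.0, abs=3.0)

    def test_identical_solutions_report_no_change(self, sol_with):
        rep = wf.compare_flows(sol_with, sol_with)
        assert rep.pressure_loss_decrease_rate == 0.0
        assert not rep.table["direction_changed"].any()
        assert np.allclose(rep.table["dq_over_qo"].dropna(), 0.0)

    def test_pcv_only_row_is_one_sided(self, comparison):
        row = comparison.table.loc["PCV"]
        assert np.isnan(row["q_o"]) and not np.isnan(row["q"])

    def test_bypassed_flow_equals_pcv_flow(self, comparison, sol_with):
        t = comparison.table
        decrease = (abs(t.loc["V_E_6", "q"] - t.loc["V_E_6", "q_o"])
                    + abs(t.loc["V_B_6", "q"] - t.loc["V_B_6", "q_o"]))
        assert decrease == pytest.approx(abs(sol_with.flow_rates["PCV"]), rel=1e-6)

    def test_mismatched_inflows_rejected(self, forewing, fluid):
        a = wf.solve_nodal(forewing, fluid, wf.BoundaryConditions(520.0))
        b = wf.solve_nodal(forewing, fluid, wf.BoundaryConditions(521.0))
        with pytest.raises(ValueError):
            wf.compare_flows(a, b)


class TestPcvInflow:
    def test_fraction_of_boundary_inflow(self, sol_with):
        assert wf.pcv_inflow(sol_with) == pytest.approx(0.32, abs=0.03)

    def test_equals_pcv_flow_by_conservation(self, sol_with):
        frac = wf.pcv_inflow(sol_with)
        assert frac == pytest.approx(
            abs(sol_with.flow_rates["PCV"]) / sol_with.inflow_rate_um3_s,
            rel=1e-9)

    def test_undefined_without_pcv(self, sol_without):
        with pytest.raises(ValueError):
            wf.pcv_inflow(sol_without)


class TestSubstituteCrossVein:
    def test_matched_resistance(self, fluid):
        cell = drosophila.load_simplified_cell("M4")
        spec = wf.make_substitute_cross_vein(cell, 0.4, 0.6)
        r_new = wf.hydraulic_resistance(spec.length_um, spec.diameter_um, fluid)
        r_pcv = wf.hydraulic_resistance(
            drosophila.PCV_LENGTH_UM, drosophila.PCV_DIAMETER_UM, fluid)
        assert r_new == pytest.approx(r_pcv, rel=1e-6)

    def test_quarter_power_length_scaling(self):
        assert wf.matched_diameter(360.0) == pytest.approx(
            wf.matched_diameter(180.0) * 2 ** 0.25, rel=1e-12)

    @pytest.mark.parametrize("fa,fp", [(0.0, 0.5), (1.0, 0.5), (0.5, -0.1), (0.5, 1.2)])
    def test_fractions_outside_unit_interval_rejected(self, fa, fp):
        cell = drosophila.load_simplified_cell("M4")
        with pytest.raises(ValueError):
            wf.make_substitute_cross_vein(cell, fa, fp)

    def test_insertion_preserves_rung_series_resistance(self, forewing, fluid):
        cell = drosophila.load_simplified_cell("M3")
        spec = wf.make_substitute_cross_vein(cell, 0.3, 0.7)
        net = insert_cross_vein(wf.remove_vein(forewing, "PCV"), spec)
        resist = net.resistances(fluid)
        original = forewing.resistances(fluid)
        for rung in ("V_C_2", "V_C_3"):
            assert resist[rung + "_e"] + resist[rung + "_b"] == pytest.approx(
                original[rung], rel=1e-12)

    def test_crossing_placement_rejected(self):
        # a dart-shaped (non-convex) cell where opposite-side chords exit
        cell = wf.build_simplified_cell(
            [(0, 0), (0, 300), (300, 300), (60, 80)], 330.0,
            {"anterior_segments": [(1.0, 3.0)], "posterior_segments": [(1.0, 3.0)],
             "edge_diameter_um": 2.0, "base_diameter_um": 2.0},
            cell_id="dart", require_convex=False)
        with pytest.raises(PlacementError):
            wf.make_substitute_cross_vein(cell, 0.05, 0.95)


@pytest.fixture(scope="module")
def table(forewing, fluid, bc):
    return wf.substitution_experiment(
        forewing, drosophila.candidate_cells(), fluid, bc, scan_step=0.01)


class TestSubstitutionExperiment:
    def test_pcv_row_reproduces_ablation_decrease(self, table, sol_without, sol_with):
        rep = wf.compare_flows(sol_without, sol_with)
        row = table[table["cell"] == "M6 (PCV)"].iloc[0]
        assert row["decrease_rate_percent"] == pytest.approx(
            100 * rep.pressure_loss_decrease_rate, rel=1e-12)
        assert row["decrease_rate_percent"] == pytest.approx(20.0, abs=3.0)

    def test_substitutes_never_beat_three_percent(self, table):
        others = table[table["cell"] != "M6 (PCV)"]
        assert len(others) == 4
        assert (others["decrease_rate_percent"] <= 3.0).all()

    def test_rates_are_nonnegative(self, table):
        # Rayleigh monotonicity: adding any vein cannot raise the loss
        assert (table["decrease_rate_percent"] >= -1e-9).all()

    def test_rates_invariant_to_inflow(self, forewing, fluid):
        cells = [drosophila.load_simplified_cell("M4")]
        a = wf.substitution_experiment(forewing, cells, fluid,
                                       wf.BoundaryConditions(5.2e2))
        b = wf.substitution_experiment(forewing, cells, fluid,
                                       wf.BoundaryConditions(1.0))
        assert a["decrease_rate_percent"].values == pytest.approx(
            b["decrease_rate_percent"].values, rel=1e-9)


@pytest.fixture(scope="module")
def profile(forewing, fluid):
    return wf.pair_resistance_profile(forewing, fluid)


class TestPairResistanceProfile:
    def test_reference_pair_normalises_to_one(self, profile):
        assert profile.loc[6, "normalized"] == pytest.approx(1.0, rel=1e-12)

    def test_pcv_cuts_pair_six_to_sixteen_percent(self, profile):
        assert profile.loc[6, "normalized_with_cross"] == pytest.approx(
            0.16, abs=0.01)

    def test_sixth_pair_dominates_by_over_five(self, profile):
        others = profile.loc[[1, 2, 3, 4, 5, 7], "normalized"]
        assert profile.loc[6, "normalized"] / others.max() > 5.0
        assert others.max() < 0.2
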