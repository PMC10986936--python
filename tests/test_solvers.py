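"""Flow solvers: exact examples, cross-validation, and conservation laws."""

import pytest
from hypothesis import given, settings, strategies as st

import wingflux as wf
from wingflux.network import VeinNetwork, VeinSegment
from wingflux.solvers import ConvergenceError


def _net(edges, inlet="IN", outlet="OUT"):
    veins = [VeinSegment(vid, "connecting", a, b, l, d)
             for vid, a, b, l, d in edges]
    return VeinNetwork(veins, inlet, outlet)


@pytest.fixture(scope="module")
def bridge():
    """Five resistors, three closed loops (a Wheatstone-style bridge)."""
    return _net([
        ("r1", "IN", "a", 100.0, 3.0),
        ("r2", "IN", "b", 150.0, 2.5),
        ("r3", "a", "b", 80.0, 4.0),
        ("r4", "a", "OUT", 120.0, 3.5),
        ("r5", "b", "OUT", 90.0, 2.0),
    ])


ALL_SOLVERS = [wf.solve_loops, wf.solve_nodal, wf.solve_hardy_cross]


class TestExactExamples:
    @pytest.mark.parametrize("solver", ALL_SOLVERS)
    def test_single_vein_ohm_analogue(self, solver, fluid, bc):
        net = _net([("v", "IN", "OUT", 300.0, 5.6)])
        sol = solver(net, fluid, bc)
        r = net.veins["v"].resistance(fluid)
        assert sol.flow_rates["v"] == pytest.approx(bc.inflow_rate_um3_s, rel=1e-12)
        assert sol.total_pressure_loss == pytest.approx(
            r * bc.inflow_rate_si, rel=1e-12)

    @pytest.mark.parametrize("solver", ALL_SOLVERS)
    def test_two_equal_parallel_veins_split_evenly(self, solver, fluid, bc):
        net = _net([("p1", "IN", "OUT", 400.0, 3.0),
                    ("p2", "IN", "OUT", 400.0, 3.0)])
        sol = solver(net, fluid, bc)
        half = bc.inflow_rate_um3_s / 2
        assert sol.flow_rates["p1"] == pytest.approx(half, rel=1e-9)
        assert sol.flow_rates["p2"] == pytest.approx(half, rel=1e-9)

    def test_series_chain_adds_losses(self, fluid, bc):
        k = 5
        edges = [(f"s{i}", f"n{i}" if i else "IN",
                  f"n{i + 1}" if i < k - 1 else "OUT", 250.0, 2.2)
                 for i in range(k)]
        net = _net(edges)
        sol = wf.solve_nodal(net, fluid, bc)
        r = net.veins["s0"].resistance(fluid)
        assert sol.total_pressure_loss == pytest.approx(
            k * r * bc.inflow_rate_si, rel=1e-12)

    def test_bridge_loops_vs_nodal_oracle(self, bridge, fluid, bc):
        a = wf.solve_loops(bridge, fluid, bc)
        b = wf.solve_nodal(bridge, fluid, bc)
        for vid in bridge.veins:
            assert a.flow_rates[vid] == pytest.approx(b.flow_rates[vid], rel=1e-9)

    def test_symmetric_bridge_carries_no_bridge_flow(self, fluid, bc):
        net = _net([("r1", "IN", "a", 100.0, 3.0), ("r2", "IN", "b", 100.0, 3.0),
                    ("r3", "a", "b", 80.0, 4.0), ("r4", "a", "OUT", 100.0, 3.0),
                    ("r5", "b", "OUT", 100.0, 3.0)])
        sol = wf.solve_loops(net, fluid, bc)
        assert abs(sol.flow_rates["r3"]) < 1e-9 * bc.inflow_rate_um3_s


class TestCrossSolverAgreement:
    def test_loops_vs_nodal_on_forewing(self, forewing, fluid, bc, sol_with):
        nodal = wf.solve_nodal(forewing, fluid, bc)
        for vid in forewing.veins:
            assert sol_with.flow_rates[vid] == pytest.approx(
                nodal.flow_rates[vid], rel=1e-9)

    def test_hardy_cross_within_printed_bound(self, forewing, fluid, bc, sol_with):
        hc = wf.solve_hardy_cross(forewing, fluid, bc)
        for vid in forewing.veins:
            assert hc.flow_rates[vid] == pytest.approx(
                sol_with.flow_rates[vid], rel=7e-3)
            assert hc.pressure_drops[vid] == pytest.approx(
                sol_with.pressure_drops[vid], rel=7e-3)

    def test_hardy_cross_tight_tolerance(self, forewing, fluid, bc):
        hc = wf.solve_hardy_cross(forewing, fluid, bc, tolerance=1e-12)
        nodal = wf.solve_nodal(forewing, fluid, bc)
        for vid in forewing.veins:
            assert hc.flow_rates[vid] == pytest.approx(
                nodal.flow_rates[vid], rel=1e-6)

    def test_hardy_cross_single_loop_converges_in_one_sweep(self, fluid, bc):
        net = _net([("p1", "IN", "OUT", 400.0, 3.0),
                    ("p2", "IN", "OUT", 700.0, 2.0)])
        sol = wf.solve_hardy_cross(net, fluid, bc)
        # the linear Δp–q law makes the single loop correction exact; the
        # second sweep only confirms convergence
        assert sol.iterations <= 2

    def test_hardy_cross_nonconvergence_reports_residual(self, forewing, fluid, bc):
        with pytest.raises(ConvergenceError) as err:
            wf.solve_hardy_cross(forewing, fluid, bc, tolerance=1e-14, max_iter=2)
        assert err.value.residual > 0


class TestConservationLaws:
    @pytest.mark.parametrize("solver", ALL_SOLVERS)
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_mass_conservation_at_every_node(self, solver, seed, fluid, bc):
        net = wf.random_ladder(wf.GeneratorConfig(seed=seed, n_rungs=5))
        sol = solver(net, fluid, bc)
        balance = {n: 0.0 for n in net.nodes}
        for vid, v in net.veins.items():
            balance[v.tail] -= sol.flow_rates[vid]
            balance[v.head] += sol.flow_rates[vid]
        balance[net.inlet] += bc.inflow_rate_um3_s
        balance[net.outlet] -= bc.inflow_rate_um3_s
        for n, residual in balance.items():
            assert abs(residual) <= 1e-9 * bc.inflow_rate_um3_s

    @pytest.mark.parametrize("solver", ALL_SOLVERS)
    def test_energy_conservation_around_loops(self, solver, forewing, fluid, bc):
        from wingflux.solvers import _bfs_tree, _chord_loops
        sol = solver(forewing, fluid, bc)
        parent, tree_ids = _bfs_tree(forewing)
        for loop in _chord_loops(forewing, parent, tree_ids):
            total = sum(s * sol.pressure_drops[vid] for vid, s in loop.items())
            assert abs(total) <= 1e-9 * sol.total_pressure_loss

    @pytest.mark.parametrize("solver", ALL_SOLVERS)
    def test_ohm_law_per_vein(self, solver, forewing, fluid, bc):
        sol = solver(forewing, fluid, bc)
        resist = forewing.resistances(fluid)
        for vid in forewing.veins:
            q_si = sol.flow_rates[vid] * 1e-18
            assert sol.pressure_drops[vid] == pytest.approx(
                resist[vid] * q_si, rel=1e-9, abs=1e-15)

    def test_linearity_in_inflow(self, forewing, fluid):
        a = wf.solve_loops(forewing, fluid, wf.BoundaryConditions(5.2e2))
        b = wf.solve_loops(forewing, fluid, wf.BoundaryConditions(5.2e5))
        for vid in forewing.veins:
            assert b.flow_rates[vid] == pytest.approx(
                1e3 * a.flow_rates[vid], rel=1e-9)
            assert b.q_over_qin(vid) == pytest.approx(a.q_over_qin(vid), rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rail_swap_symmetry_on_symmetric_ladders(self, seed, fluid, bc):
        net = wf.random_ladder(wf.GeneratorConfig(seed=seed, n_rungs=4,
                                                  symmetric=True))
        sol = wf.solve_nodal(net, fluid, bc)
        for i in range(1, 6):
            assert sol.flow_rates[f"E{i}"] == pytest.approx(
                sol.flow_rates[f"B{i}"], rel=1e-9)
        for i in range(1, 5):
            assert abs(sol.flow_rates[f"C{i}"]) < 1e-9 * bc.inflow_rate_um3_s


class TestResistanceUtilities:
    def test_parallel_combination(self):
        assert wf.combined_parallel_resistance([4.0, 4.0]) == pytest.approx(2.0)
        assert wf.combined_parallel_resistance([1.0]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            wf.combined_parallel_resistance([])
        with pytest.raises(ValueError):
            wf.combined_parallel_resistance([1.0, -2.0])

    def test_equivalent_resistance_single_vein(self, fluid):
        net = _net([("v", "IN", "OUT", 300.0, 5.6)])
        assert wf.equivalent_resistance(net, fluid) == pytest.approx(
            net.veins["v"].resistance(fluid), rel=1e-12)

    def test_equivalent_resistance_series_parallel_oracle(self, fluid):
        for seed in range(200):
            net, r_exact = wf.random_series_parallel(
                wf.GeneratorConfig(seed=seed, n_rungs=8), fluid)
            assert wf.equivalent_resistance(net, fluid) == pytest.approx(
                r_exact, rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rayleigh_monotonicity(self, seed, fluid):
        # increasing one resistance (halving a diameter) can only raise the
        # equivalent resistance; adding a vein can only lower it
        net = wf.random_ladder(wf.GeneratorConfig(seed=seed, n_rungs=3))
        base = wf.equivalent_resistance(net, fluid)
        vid = list(net.veins)[seed % len(net.veins)]
        worse = net.replace_vein(vid, diameter_um=net.veins[vid].diameter_um / 2)
        assert wf.equivalent_resistance(worse, fluid) >= base * (1 - 1e-12)
        extra = VeinNetwork(
            list(net.veins.values())
            + [VeinSegment("extra", "cross", "t1", "b2", 200.0, 3.0)],
            net.inlet, net.outlet)
        assert wf.equivalent_resistance(extra, fluid) <= base * (1 + 1e-12)

    def test_pumping_power(self, sol_with, bc):
        p = wf.pumping_power(sol_with, bc)
        assert p == pytest.approx(sol_with.total_pressure_loss
                                  * bc.inflow_rate_um3_s * 1e-18, rel=1e-12)
        # direct product at the published operating point
        assert wf.pumping_power(sol_with) == pytest.approx(1.7e-13, rel=0.05)


class TestFlowSolutionSerialization:
    def test_frame_and_summary(self, sol_with, bc):
        df = sol_with.to_frame()
        assert set(df.columns) == {"vein_id", "q_um3_per_s", "q_over_Qin", "dp_Pa"}
        assert len(df) == 23
        s = sol_with.summary()
        assert s["solver"] == "loops"
        assert s["power_W"] == pytest.approx(wf.pumping_power(sol_with), rel=1e-12)
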