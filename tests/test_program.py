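import numpy as np
import pytest

import lkdfba as lk
from lkdfba.fitting import fit_lr, fit_nlr
from lkdfba.network import TimeGrid
from lkdfba.program import assemble_program, solve_program

from _oracles import generic_solve, lp_oracle


def lr_constraint(flux, controller, a, b):
    g = lk.InteractionGroup(1, (flux,), (controller,), ("mass_action",))
    return lk.KineticsConstraint(g, "LR", {"a": a, "b": b})


class TestAssembly:
    def test_row_counts_single_influx(self, influx_network):
        grid = TimeGrid(0.0, 3.0, 4)  # K = 3 steps, dt = 1
        cons = [lr_constraint("v_in", "x", 0.0, 5.0)]
        prog = assemble_program(influx_network, grid, cons, [0.0])
        # 3 mass-balance + 3 Euler + 1 initial-condition equality rows
        assert prog.A_eq.shape[0] == 7
        # one kinetics row per step when every step is constrained
        assert prog.A_kin.shape[0] == 3
        prog1 = assemble_program(influx_network, grid, cons, [0.0], kinetics_from_step=1)
        assert prog1.A_kin.shape[0] == 2

    def test_paired_kinetics_row_count_scales_with_groups(self, branched_network, reference_data):
        cons = lk.fit_constraints(branched_network, reference_data, "LR")
        grid = TimeGrid(0.0, 10.0, 50)
        prog = assemble_program(branched_network, grid, cons, [0.5] * 5, kinetics_from_step=1)
        assert prog.A_kin.shape[0] == len(cons) * (grid.n_steps - 1)

    def test_lambda_zero_gives_linear_objective(self, influx_network):
        prog = assemble_program(
            influx_network, TimeGrid(0, 2, 3), [], [0.0], lam=0.0,
            objective_weights={"v_in": 1.0},
        )
        assert prog.lam == 0.0
        omega = np.arange(prog.n_variables, dtype=float)
        assert prog.objective_value(omega) == pytest.approx(prog.q @ omega)

    def test_unknown_objective_species_raises(self, influx_network):
        with pytest.raises(ValueError, match="ghost"):
            assemble_program(influx_network, TimeGrid(0, 2, 3), [], [0.0],
                             objective_weights={"ghost": 1.0})


class TestSolveExamples:
    def test_capped_influx_accumulates_linearly(self, influx_network):
        """v <= 5 at every step, dt=1, K=3, maximize total influx -> x(t3)=15."""
        grid = TimeGrid(0.0, 3.0, 4)
        cons = [lr_constraint("v_in", "x", 0.0, 5.0)]
        prog = assemble_program(
            influx_network, grid, cons, [0.0],
            conc_bounds={"x": (0.0, 100.0)}, flux_bounds={"v_in": (0.0, 10.0)},
            objective_weights={"v_in": 1.0}, lam=1e-6,
        )
        sol = solve_program(prog, tol=1e-9)
        assert sol.is_optimal
        np.testing.assert_allclose(sol.v["v_in"], 5.0, atol=1e-6)
        assert sol.x["x"].iloc[-1] == pytest.approx(15.0, abs=1e-6)
        status, lp_obj = lp_oracle(
            influx_network, grid, cons, [0.0], {"v_in": 1.0},
            conc_bounds={"x": (0.0, 100.0)}, flux_bounds={"v_in": (0.0, 10.0)},
        )
        assert status == "optimal"
        # the lam*||omega||^2 ridge (~5e-4 here) shifts the QP optimum off the LP value
        assert sol.objective == pytest.approx(lp_obj, abs=2e-3)

    def test_concentration_cap_limits_total_influx(self, influx_network):
        grid = TimeGrid(0.0, 3.0, 4)
        cons = [lr_constraint("v_in", "x", 0.0, 5.0)]
        kw = dict(conc_bounds={"x": (0.0, 10.0)}, flux_bounds={"v_in": (0.0, 10.0)})
        prog = assemble_program(influx_network, grid, cons, [0.0],
                                objective_weights={"v_in": 1.0}, lam=1e-6, **kw)
        sol = solve_program(prog, tol=1e-9)
        assert sol.is_optimal
        assert sol.x["x"].max() <= 10.0 + 1e-7
        _, lp_obj = lp_oracle(influx_network, grid, cons, [0.0], {"v_in": 1.0}, **kw)
        assert sol.objective == pytest.approx(lp_obj, abs=2e-3)

    def test_fully_closed_valve_freezes_state(self, influx_network):
        grid = TimeGrid(0.0, 3.0, 4)
        cons = lk.scale_constraints([lr_constraint("v_in", "x", 0.3, 0.0)], ["v_in"], 1e-12)
        prog = assemble_program(influx_network, grid, cons, [0.0],
                                objective_weights={"v_in": 1.0})
        sol = solve_program(prog)
        assert sol.is_optimal
        np.testing.assert_allclose(sol.x["x"], 0.0, atol=1e-6)
        assert sol.objective == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_box_bounds(self, influx_network):
        prog = assemble_program(influx_network, TimeGrid(0, 2, 3), [], [0.0],
                                conc_bounds={"x": (5.0, 1.0)})
        sol = solve_program(prog)
        assert sol.status == "infeasible"
        assert not sol.is_optimal

    def test_negative_rhs_kinetics_is_infeasible(self, influx_network):
        """A constraint forcing v <= -1 conflicts with v >= 0."""
        cons = [lr_constraint("v_in", "x", 0.0, -1.0)]
        prog = assemble_program(influx_network, TimeGrid(0, 2, 3), cons, [0.0])
        sol = solve_program(prog)
        assert sol.status == "infeasible"


class TestOracleEquivalence:
    """The packaged solver must agree with an independently assembled
    generic-solver formulation on small instances."""

    def _two_met_instance(self, seed):
        rng = np.random.default_rng(seed)
        net = lk.MetabolicNetwork(
            ["x1", "x2"], ["v1", "v2"],
            np.array([[1.0, -1.0], [0.0, 1.0]]),
        )
        cons = [
            lr_constraint("v1", "x1", -float(rng.uniform(0, 0.5)), float(rng.uniform(2, 4))),
            lr_constraint("v2", "x1", float(rng.uniform(0.5, 2)), float(rng.uniform(0, 1))),
        ]
        x0 = rng.uniform(0.2, 1.5, size=2)
        return net, cons, x0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_qp_matches_slsqp_assembly(self, seed):
        net, cons, x0 = self._two_met_instance(seed)
        grid = TimeGrid(0.0, 2.0, 5)
        weights = {"x2": 1.0}
        kw = dict(flux_bounds=None, conc_bounds={m: (0.0, 50.0) for m in net.metabolite_ids})
        prog = assemble_program(net, grid, cons, x0, objective_weights=weights,
                                lam=1e-3, conc_bounds=kw["conc_bounds"])
        sol = solve_program(prog, tol=1e-10)
        assert sol.is_optimal
        ref_obj, ref_w, (iv, ivp, ix, _) = generic_solve(
            net, grid, cons, x0, weights, lam=1e-3,
            conc_bounds=kw["conc_bounds"], conc_ub=50.0,
        )
        assert ref_obj is not None
        assert sol.objective == pytest.approx(ref_obj, rel=1e-6, abs=1e-6)
        for k in range(grid.n_points):
            for i, m in enumerate(net.metabolite_ids):
                assert sol.x[m].iloc[k] == pytest.approx(ref_w[ix(k, i)], rel=1e-4, abs=1e-5)

    def test_qcp_with_active_quadratic_matches_slsqp(self):
        net = lk.MetabolicNetwork(["x1", "x2"], ["v1", "v2"],
                                  np.array([[1.0, -1.0], [0.0, 1.0]]))
        g = lk.InteractionGroup(1, ("v2",), ("x1",), ("mass_action",))
        quad = lk.KineticsConstraint(
            g, "NLR", {"a": -0.8, "b": 2.5, "c": 0.3, "quadratic_active": True},
            diagnostics={"x_range": (0.0, 2.0)},
        )
        cons = [lr_constraint("v1", "x1", -0.2, 2.0), quad]
        grid = TimeGrid(0.0, 2.0, 5)
        weights = {"x2": 1.0}
        cb = {m: (0.0, 50.0) for m in net.metabolite_ids}
        prog = assemble_program(net, grid, cons, [0.5, 0.1],
                                objective_weights=weights, lam=1e-3, conc_bounds=cb)
        sol = solve_program(prog, tol=1e-10)
        assert sol.is_optimal
        ref_obj, _, _ = generic_solve(net, grid, cons, [0.5, 0.1], weights,
                                      lam=1e-3, conc_bounds=cb, conc_ub=50.0)
        assert ref_obj is not None
        assert sol.objective == pytest.approx(ref_obj, rel=1e-6, abs=1e-6)

    def test_osqp_backend_agrees_with_ipm(self):
        net, cons, x0 = self._two_met_instance(11)
        grid = TimeGrid(0.0, 2.0, 5)
        prog = assemble_program(net, grid, cons, x0, objective_weights={"x2": 1.0}, lam=1e-3)
        a = solve_program(prog, tol=1e-9, solver="ipm")
        b = solve_program(prog, tol=1e-9, solver="osqp")
        assert a.is_optimal and b.is_optimal
        assert a.objective == pytest.approx(b.objective, rel=1e-6)


class TestSolutionProperties:
    def test_residuals_within_tolerance_and_resolve_deterministic(
        self, branched_network, reference_model, reference_data
    ):
        cons = lk.fit_constraints(branched_network, reference_data, "NLR")
        grid = TimeGrid(0.0, 10.0, 50)
        prog = assemble_program(branched_network, grid, cons,
                                reference_model.x0_vector())
        a = solve_program(prog)
        b = solve_program(prog)
        assert a.is_optimal
        assert a.max_violation <= 1e-6
        np.testing.assert_allclose(a.x.to_numpy(), b.x.to_numpy(), atol=1e-9)
        assert a.objective == pytest.approx(b.objective, abs=1e-9)

    def test_downscaling_nonnegative_constraints_never_raises_objective(self, influx_network):
        grid = TimeGrid(0.0, 3.0, 4)
        cons = [lr_constraint("v_in", "x", 0.4, 2.0)]
        base = solve_program(assemble_program(
            influx_network, grid, cons, [1.0], objective_weights={"v_in": 1.0}))
        for f in (0.9, 0.5, 0.1):
            scaled = lk.scale_constraints(cons, ["v_in"], f)
            sol = solve_program(assemble_program(
                influx_network, grid, scaled, [1.0], objective_weights={"v_in": 1.0}))
            assert sol.objective <= base.objective + 1e-7

    def test_scale_by_one_reproduces_solution(self, branched_network, reference_model, reference_data):
        cons = lk.fit_constraints(branched_network, reference_data, "LR")
        same = lk.scale_constraints(cons, ["v2"], 1.0)
        grid = TimeGrid(0.0, 10.0, 50)
        a = lk.simulate_lkdfba(branched_network, cons, reference_model.x0_vector(), grid)
        b = lk.simulate_lkdfba(branched_network, same, reference_model.x0_vector(), grid)
        np.testing.assert_allclose(a.x.to_numpy(), b.x.to_numpy(), atol=1e-9)

    def test_fitted_models_beat_mean_predictor_on_training_data(
        self, branched_network, reference_data
    ):
        """End-to-end: at least one approach recapitulates the training data
        better than predicting each metabolite's mean."""
        baseline = np.mean([
            np.sqrt(np.mean((reference_data.concentrations[m]
                             - reference_data.concentrations[m].mean()) ** 2))
            / np.ptp(reference_data.concentrations[m])
            for m in branched_network.metabolite_ids
        ])
        best = min(
            -lk.LKDFBA(network=branched_network, approach=app).fit(reference_data).score(reference_data)
            for app in lk.APPROACHES
        )
        assert best < baseline
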