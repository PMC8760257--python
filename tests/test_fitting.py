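import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lkdfba as lk
from lkdfba.fitting import EPS_CONVEXITY, fit_dr, fit_hp, fit_lr, fit_nlr


def ols_line(x, v):
    """Closed-form OLS oracle: slope = cov/var, intercept through the means."""
    x, v = np.asarray(x, float), np.asarray(v, float)
    a = np.cov(x, v, bias=True)[0, 1] / np.var(x)
    return a, np.mean(v) - a * np.mean(x)


class TestLR:
    @pytest.mark.parametrize("x,v,expected", [
        ([1, 2, 3], [2, 4, 6], (2.0, 0.0)),
        ([1, 2, 3], [5, 5, 5], (0.0, 5.0)),
        ([0, 1, 2], [0, 1, 4], (2.0, -1.0 / 3.0)),
    ])
    def test_worked_examples(self, x, v, expected):
        con = fit_lr(np.asarray(v, float), np.asarray(x, float))
        assert con.params["a"] == pytest.approx(expected[0], abs=1e-9)
        assert con.params["b"] == pytest.approx(expected[1], abs=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=25),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_closed_form_ols(self, xs, seed):
        x = np.asarray(xs)
        rng = np.random.default_rng(seed)
        v = rng.normal(size=len(x))
        con = fit_lr(v, x)
        if np.var(x) == 0:
            assert con.params["a"] == 0.0
            assert con.params["b"] == pytest.approx(np.mean(v))
        else:
            a, b = ols_line(x, v)
            assert con.params["a"] == pytest.approx(a, rel=1e-7, abs=1e-9)
            assert con.params["b"] == pytest.approx(b, rel=1e-7, abs=1e-9)

    def test_zero_variance_flags_degenerate(self):
        con = fit_lr(np.array([1.0, 2.0, 3.0]), np.array([4.0, 4.0, 4.0]))
        assert con.params == {"a": 0.0, "b": 2.0}
        assert "degenerate" in con.diagnostics

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            fit_lr(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestNLR:
    def test_concave_data_keeps_quadratic(self):
        con = fit_nlr(np.array([0.0, 3.0, 4.0, 3.0]), np.array([0.0, 1.0, 2.0, 3.0]))
        assert con.params["quadratic_active"]
        assert con.params["a"] == pytest.approx(-1.0, abs=1e-9)
        assert con.params["b"] == pytest.approx(4.0, abs=1e-9)
        assert con.params["c"] == pytest.approx(0.0, abs=1e-9)

    def test_convex_data_falls_back_to_line(self):
        con = fit_nlr(np.array([0.0, 1.0, 4.0]), np.array([0.0, 1.0, 2.0]))
        assert not con.params["quadratic_active"]
        assert con.params["b"] == pytest.approx(2.0, abs=1e-9)      # linear slope
        assert con.params["c"] == pytest.approx(-1 / 3, abs=1e-9)   # intercept

    def test_exactly_linear_data_falls_back(self):
        con = fit_nlr(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert not con.params["quadratic_active"]
        assert con.params["b"] == pytest.approx(2.0, abs=1e-9)
        assert con.params["c"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_falls_back_with_diagnostic(self):
        con = fit_nlr(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert not con.params["quadratic_active"]
        assert "fallback" in con.diagnostics

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_never_active_with_nonnegative_curvature(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 5, size=rng.integers(3, 20))
        v = rng.normal(size=len(x))
        con = fit_nlr(v, x)
        if con.params["quadratic_active"]:
            assert con.params["a"] < -EPS_CONVEXITY


class TestDR:
    def test_collinear_controllers_reproduce_flux_at_training_rows(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        v = np.array([2.0, 4.0, 6.0])
        con = fit_dr(v, X, controllers=["m1", "m2"])
        assert con.diagnostics["explained_variance_ratio"] == pytest.approx(1.0)
        preds = [con.evaluate({"m1": r[0], "m2": r[1]}) for r in X]
        np.testing.assert_allclose(preds, v, atol=1e-9)

    def test_single_controller_equals_lr_predictions(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 4, 12)
        v = 1.5 * x + rng.normal(0, 0.2, 12)
        dr = fit_dr(v, x[:, None], controllers=["m"])
        ref = fit_lr(v, x)
        for xi in x:
            assert dr.evaluate({"m": xi}) == pytest.approx(ref.evaluate({"x": xi}), abs=1e-9)

    def test_orthogonal_equal_variance_columns_split_variance(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        v = np.array([1.0, -1.0, 0.0, 0.0])
        con = fit_dr(v, X, controllers=["m1", "m2"])
        assert con.diagnostics["explained_variance_ratio"] == pytest.approx(0.5)

    def test_loading_has_unit_norm_and_nonnegative_slope(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 3, size=(15, 3))
        v = X @ [1.0, -0.5, 2.0] + rng.normal(0, 0.1, 15)
        con = fit_dr(v, X, controllers=["a", "b", "c"])
        assert np.linalg.norm(con.params["loading"]) == pytest.approx(1.0)
        assert con.params["a"] >= 0

    def test_all_constant_controllers_degenerate(self):
        con = fit_dr(np.array([1.0, 2.0, 3.0]), np.ones((3, 2)), controllers=["a", "b"])
        assert con.params["a"] == 0.0
        assert con.params["b"] == pytest.approx(2.0)
        assert "degenerate" in con.diagnostics


class TestHP:
    def test_exact_hyperplane_recovered(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 1.0]])
        v = np.array([3.0, 0.0, 2.0, 4.0])
        con = fit_hp(v, X, controllers=["m1", "m2"])
        assert con.params["b"] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(con.params["a"], [2.0, -1.0], atol=1e-9)

    def test_single_controller_equals_lr(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 4, 10)
        v = rng.normal(size=10)
        hp = fit_hp(v, x[:, None], controllers=["m"])
        ref = fit_lr(v, x)
        assert hp.params["b"] == pytest.approx(ref.params["b"], abs=1e-9)
        assert hp.params["a"][0] == pytest.approx(ref.params["a"], abs=1e-9)

    def test_collinear_design_minimum_norm_predictions(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        v = np.array([2.0, 4.0, 6.0])
        con = fit_hp(v, X, controllers=["m1", "m2"])
        assert "rank_deficient" in con.diagnostics
        preds = [con.evaluate({"m1": r[0], "m2": r[1]}) for r in X]
        np.testing.assert_allclose(preds, v, atol=1e-9)


class TestScaleConstraints:
    def make_set(self):
        g = lk.InteractionGroup(1, ("v2",), ("x1",), ("mass_action",))
        lr = lk.KineticsConstraint(g, "LR", {"a": 2.0, "b": 4.0})
        g2 = lk.InteractionGroup(2, ("v3",), ("x2",), ("mass_action",))
        nlr = lk.KineticsConstraint(
            g2, "NLR", {"a": -1.0, "b": 4.0, "c": 2.0, "quadratic_active": True}
        )
        return [lr, nlr]

    def test_identity_factor(self):
        cons = self.make_set()
        out = lk.scale_constraints(cons, ["v2"], 1.0)
        assert [c.params for c in out] == [c.params for c in cons]
        assert out is not cons and out[0] is not cons[0]

    def test_halving_halves_rhs_pointwise(self):
        cons = self.make_set()
        out = lk.scale_constraints(cons, ["v2"], 0.5)
        assert out[0].params == {"a": 1.0, "b": 2.0}
        for x in np.linspace(0, 5, 7):
            assert out[0].evaluate({"x1": x}) == pytest.approx(0.5 * cons[0].evaluate({"x1": x}))
        assert out[1].params == cons[1].params  # untargeted constraint untouched

    def test_nlr_scaling_includes_c(self):
        cons = self.make_set()
        out = lk.scale_constraints(cons, ["v3"], 2.0)
        assert out[1].params["a"] == -2.0
        assert out[1].params["b"] == 8.0
        assert out[1].params["c"] == 4.0

    def test_composition_and_input_immutability(self):
        cons = self.make_set()
        before = [dict(c.params) for c in cons]
        fg = lk.scale_constraints(lk.scale_constraints(cons, ["v2"], 0.5), ["v2"], 0.4)
        direct = lk.scale_constraints(cons, ["v2"], 0.2)
        assert fg[0].params["a"] == pytest.approx(direct[0].params["a"])
        assert fg[0].params["b"] == pytest.approx(direct[0].params["b"])
        assert [dict(c.params) for c in cons] == before

    def test_unknown_target_raises(self):
        with pytest.raises(ValueError, match="ghost"):
            lk.scale_constraints(self.make_set(), ["ghost"], 0.5)


class TestConstraintValidationAndIO:
    def test_active_nlr_requires_negative_curvature(self):
        g = lk.InteractionGroup(1, ("v",), ("x",), ("mass_action",))
        with pytest.raises(ValueError, match="convex"):
            lk.KineticsConstraint(g, "NLR", {"a": 0.5, "b": 0.0, "c": 0.0, "quadratic_active": True})

    def test_round_trip_all_approaches(self, branched_network, reference_data, tmp_path):
        for approach in lk.APPROACHES:
            cons = lk.fit_constraints(branched_network, reference_data, approach)
            path = tmp_path / f"{approach}.json"
            lk.save_constraints(cons, path)
            back = lk.load_constraints(path)
            assert len(back) == len(cons)
            for c1, c2 in zip(cons, back):
                assert c1.group == c2.group
                assert c1.approach == c2.approach
                x = {m: 0.7 for m in branched_network.metabolite_ids}
                assert c2.evaluate(x) == pytest.approx(c1.evaluate(x), rel=1e-12)
        # files are structured text
        payload = json.loads((tmp_path / "HP.json").read_text())
        assert payload[0]["approach"] == "HP"

    def test_fit_constraints_requires_fluxes(self, branched_network, reference_data):
        ds = reference_data.copy()
        ds.fluxes = None
        with pytest.raises(ValueError, match="DFE"):
            lk.fit_constraints(branched_network, ds, "LR")

    def test_lag_pairing_shifts_series(self, branched_network, reference_data):
        lag0 = lk.fit_constraints(branched_network, reference_data, "LR", lag=0)
        lag1 = lk.fit_constraints(branched_network, reference_data, "LR", lag=1)
        assert lag1[0].diagnostics["n_points"] == lag0[0].diagnostics["n_points"] - 1
        assert any(
            c0.params["a"] != pytest.approx(c1.params["a"])
            for c0, c1 in zip(lag0, lag1)
        )
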