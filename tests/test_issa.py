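import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize

import seedshadow as ss


def strata_frame(strata, var="x"):
    """Strata from a list of (used_value, [control_values])."""
    rows = []
    for s, (used, controls) in enumerate(strata):
        rows.append({"stratum_id": f"s{s}", "case": True, var: used,
                     "animal_id": "a"})
        for c in controls:
            rows.append({"stratum_id": f"s{s}", "case": False, var: c,
                         "animal_id": "a"})
    return pd.DataFrame(rows)


def grid_search_loglik(beta_grid, strata, var="x"):
    """Exhaustive conditional-logit likelihood over a coefficient grid."""
    lls = []
    for b in np.atleast_2d(beta_grid):
        ll = 0.0
        for _, grp in strata.groupby("stratum_id"):
            eta = grp.drop(columns=["stratum_id", "case", "animal_id"])\
                .to_numpy() @ np.asarray(b)
            ll += eta[grp["case"].to_numpy()].item() - np.log(
                np.exp(eta).sum())
        lls.append(ll)
    return np.array(lls)


class TestFitTentative:
    def test_gamma_shape_recovered_within_ten_percent(self):
        rng = np.random.default_rng(42)
        steps = pd.DataFrame({
            "sl": rng.gamma(2.0, 100.0, size=5000),
            "ta": rng.vonmises(0.0, 1.0, size=5000)})
        tk = ss.fit_tentative(steps)
        assert tk.sl_shape == pytest.approx(2.0, rel=0.10)
        assert tk.sl_rate == pytest.approx(0.01, rel=0.10)

    def test_uniform_angles_give_kappa_near_zero(self):
        # independent streams: the length draws must not shift the angles
        steps = pd.DataFrame({
            "sl": np.random.default_rng(0).gamma(2.0, 100.0, size=5000),
            "ta": np.random.default_rng(1).uniform(-np.pi, np.pi,
                                                   size=5000)})
        tk = ss.fit_tentative(steps)
        assert tk.ta_kappa < 0.05

    def test_identical_angles_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        steps = pd.DataFrame({"sl": rng.gamma(2.0, 100.0, size=100),
                              "ta": np.zeros(100)})
        tk = ss.fit_tentative(steps)
        assert tk.degenerate
        assert tk.ta_kappa == pytest.approx(500.0)

    def test_too_few_steps_rejected(self):
        steps = pd.DataFrame({"sl": np.ones(10), "ta": np.zeros(10)})
        with pytest.raises(ValueError, match=">= 30"):
            ss.fit_tentative(steps)


class TestScreenCorrelation:
    def test_perfect_collinearity_excluded(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=100)})
        screen = ss.screen_correlation(df, ["a", "b", "c"])
        assert ("a", "b") in screen.excluded_pairs
        assert screen.matrix.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_variables_pass(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=10000),
                           "b": rng.normal(size=10000)})
        screen = ss.screen_correlation(df, ["a", "b"])
        assert abs(screen.matrix.loc["a", "b"]) < 0.05
        assert screen.excluded_pairs == []

    def test_threshold_is_strict_at_exactly_point_six(self):
        # orthogonal unit contrasts => exact correlation 0.6
        z1 = np.array([1.0, -1.0, 1.0, -1.0])
        z2 = np.array([1.0, 1.0, -1.0, -1.0])
        df = pd.DataFrame({"a": z1, "b": 0.6 * z1 + 0.8 * z2})
        screen = ss.screen_correlation(df, ["a", "b"], threshold=0.6)
        assert screen.matrix.loc["a", "b"] == pytest.approx(0.6, abs=1e-12)
        assert screen.excluded_pairs == []

    def test_constant_variable_reported_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        screen = ss.screen_correlation(df, ["a", "b"])
        assert "b" in screen.undefined


class TestFitClogit:
    def test_mirror_strata_force_zero(self):
        strata = strata_frame([(1.0, [0.0, 0.0]), (0.0, [1.0, 1.0])])
        m = ss.fit_clogit(strata, ("x",))
        assert m.converged
        assert m.coef["x"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_one_dimensional_grid_search(self):
        strata = strata_frame([(1.0, [0.0, 0.0]), (1.0, [0.0, 2.0])])
        m = ss.fit_clogit(strata, ("x",))
        grid = np.arange(-3, 3, 1e-4).reshape(-1, 1)
        lls = grid_search_loglik(grid, strata)
        best = grid[np.argmax(lls)][0]
        assert m.coef["x"] == pytest.approx(best, abs=1e-4)
        assert m.loglik == pytest.approx(lls.max(), abs=1e-6)

    def test_matches_two_dimensional_grid_search(self):
        rng = np.random.default_rng(8)
        rows = []
        for s in range(3):
            for j in range(4):
                rows.append({"stratum_id": f"s{s}", "case": j == 0,
                             "animal_id": "a",
                             "x": rng.normal(), "y": rng.normal()})
        strata = pd.DataFrame(rows)
        m = ss.fit_clogit(strata, ("x", "y"))
        if not m.converged:  # 3 random strata can separate; make sure not
            pytest.skip("random configuration separated")
        b = np.arange(-4, 4, 1e-3)
        # coordinate-wise comparison against a grid around the optimum
        for i, var in enumerate(("x", "y")):
            beta = np.tile(np.array([[m.coef["x"], m.coef["y"]]]),
                           (len(b), 1))
            beta[:, i] = b
            lls = grid_search_loglik(beta, strata)
            assert abs(b[np.argmax(lls)] - m.coef[var]) <= 1e-3 + 1e-9

    def test_separation_is_flagged_not_silent(self):
        strata = strata_frame([(1.0, [0.0, 0.0])])
        m = ss.fit_clogit(strata, ("x",))
        assert not m.converged
        assert m.diagnostics["separation"]

    def test_stratum_constant_offset_leaves_fit_unchanged(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(40):
            for j in range(5):
                rows.append({"stratum_id": f"s{s}", "case": j == 0,
                             "animal_id": "a",
                             "x": rng.normal() + (0.5 if j == 0 else 0.0),
                             "z": rng.normal()})
        strata = pd.DataFrame(rows)
        m0 = ss.fit_clogit(strata, ("x", "z"))
        shifted = strata.copy()
        offsets = {f"s{s}": v for s, v in enumerate(rng.normal(size=40) * 10)}
        shifted["x"] = shifted["x"] + shifted["stratum_id"].map(offsets)
        m1 = ss.fit_clogit(shifted, ("x", "z"))
        assert m1.coef["x"] == pytest.approx(m0.coef["x"], abs=1e-6)
        assert m1.coef["z"] == pytest.approx(m0.coef["z"], abs=1e-6)
        assert m1.loglik == pytest.approx(m0.loglik, abs=1e-6)

    def test_not_identifiable_raises(self):
        strata = strata_frame([(1.0, [1.0, 1.0]), (2.0, [2.0, 2.0])])
        strata["y"] = [0, 1, 0, 1, 0, 1]
        with pytest.raises(ValueError, match="not identifiable"):
            ss.fit_clogit(strata, ("x", "y"))

    def test_multiple_used_steps_rejected(self):
        strata = strata_frame([(1.0, [0.0])])
        strata.loc[1, "case"] = True
        with pytest.raises(ValueError, match="exactly one"):
            ss.fit_clogit(strata, ("x",))

    def test_vcov_consistent_with_se(self, strata_std):
        m = ss.fit_clogit(strata_std, ("canopy_height", "log_sl", "cos_ta"))
        np.testing.assert_allclose(
            np.sqrt(np.diag(m.vcov)),
            [m.se[v] for v in m.formula], rtol=1e-10)
        np.testing.assert_allclose(m.vcov, m.vcov.T, atol=1e-12)

    def test_agrees_with_scipy_optimizer_on_real_strata(self, strata_std):
        """Independent route: generic numeric optimiser on the same
        conditional likelihood, written from the definition."""
        formula = ("canopy_height", "swamp")
        m = ss.fit_clogit(strata_std, formula)
        df = strata_std

        def neg_ll(beta):
            ll = 0.0
            for _, grp in df.groupby("stratum_id"):
                eta = grp[list(formula)].to_numpy() @ beta
                mx = eta.max()
                ll += eta[grp["case"].to_numpy()].item()
                ll -= np.log(np.exp(eta - mx).sum()) + mx
            return -ll

        res = optimize.minimize(neg_ll, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        np.testing.assert_allclose(
            [m.coef[v] for v in formula], res.x, atol=2e-4)


class TestRelativeSelection:
    def model(self, beta):
        n = len(beta)
        return ss.SelectionModel(
            coef={f"v{i}": b for i, b in enumerate(beta)},
            se={f"v{i}": 0.1 for i in range(n)},
            vcov=np.eye(n) * 0.01, loglik=0.0, n_strata=10,
            converged=True, formula=tuple(f"v{i}" for i in range(n)))

    def test_identity(self):
        m = self.model([0.7, -0.2])
        assert ss.relative_selection(m, [1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_log_two_doubles(self):
        m = self.model([np.log(2.0)])
        assert ss.relative_selection(m, [1.0], [0.0]) == pytest.approx(2.0)

    @given(st.lists(st.floats(-2, 2), min_size=3, max_size=3),
           st.lists(st.floats(-5, 5), min_size=3, max_size=3),
           st.lists(st.floats(-5, 5), min_size=3, max_size=3))
    def test_matches_direct_exponential(self, beta, x1, x2):
        m = self.model(beta)
        expected = np.exp(np.dot(beta, np.subtract(x1, x2)))
        assert ss.relative_selection(m, x1, x2) == pytest.approx(
            expected, rel=1e-12)

    def test_requires_convergence_and_shape(self):
        m = self.model([0.5])
        m.converged = False
        with pytest.raises(ValueError, match="converge"):
            ss.relative_selection(m, [1.0], [0.0])
        m.converged = True
        with pytest.raises(ValueError, match="match"):
            ss.relative_selection(m, [1.0, 2.0], [0.0])


def test_model_json_roundtrip(tmp_path, strata_std):
    m = ss.fit_clogit(strata_std, ("canopy_height", "swamp"))
    path = tmp_path / "model.json"
    m.to_json(path)
    back = ss.SelectionModel.from_json(path)
    assert back.coef == m.coef
    assert back.formula == m.formula
    np.testing.assert_allclose(back.vcov, m.vcov)
    assert back.n_strata == m.n_strata
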