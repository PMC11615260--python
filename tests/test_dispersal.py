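import numpy as np
import pandas as pd
import pytest
from scipy import stats

import seedshadow as ss


def flat_stack(n=400, cell=100.0, swamp_mask=None):
    """Large featureless landscape for selection-free movement checks."""
    shape = (n, n)
    mk = lambda v: ss.RasterGrid(np.full(shape, float(v)), cell)  # noqa: E731
    swamp = (ss.RasterGrid(swamp_mask.astype(float), cell)
             if swamp_mask is not None else mk(0))
    return ss.LandscapeStack(mk(30), mk(0.5), mk(100), mk(200), swamp)


class TestGutPassage:
    def test_moment_fit_closed_forms(self):
        g = ss.fit_gut_passage(345, 39)
        assert g.gamma_shape == pytest.approx((345 / 39) ** 2)
        assert g.gamma_shape == pytest.approx(78.2544, abs=1e-4)
        assert g.gamma_scale == pytest.approx(39 ** 2 / 345)
        assert g.gamma_scale == pytest.approx(4.40870, abs=1e-4)
        g2 = ss.fit_gut_passage(162, 8)
        assert g2.gamma_shape == pytest.approx(410.0625, abs=1e-4)
        assert g2.gamma_scale == pytest.approx(0.395062, abs=1e-6)

    def test_mean_equals_spread_is_exponential(self):
        g = ss.fit_gut_passage(100, 100)
        assert g.gamma_shape == pytest.approx(1.0)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            ss.fit_gut_passage(0, 10)
        with pytest.raises(ValueError):
            ss.fit_gut_passage(100, -1)


class TestDepositionWeights:
    def test_mass_closure(self):
        w, tail = ss.deposition_weights(ss.fit_gut_passage(345, 39))
        assert w.sum() + tail == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()

    def test_peak_interval_covers_the_mean(self):
        w, _ = ss.deposition_weights(ss.fit_gut_passage(162, 8))
        # 162 min falls in step 9's interval (160, 180]
        assert np.argmax(w) + 1 == 9

    def test_near_delta_concentrates_in_one_step(self):
        w, tail = ss.deposition_weights(ss.fit_gut_passage(30, 1e-3))
        assert w[1] == pytest.approx(1.0, abs=1e-9)  # interval (20, 40]
        assert tail == pytest.approx(0.0, abs=1e-12)

    def test_weights_match_direct_cdf_differences(self):
        g = ss.fit_gut_passage(345, 39)
        w, tail = ss.deposition_weights(g, step_minutes=20, n_steps=50)
        f = stats.gamma.cdf(np.arange(51) * 20.0, a=(345 / 39) ** 2,
                            scale=39 ** 2 / 345)
        np.testing.assert_allclose(w, np.diff(f), atol=1e-12)
        assert tail == pytest.approx(1 - f[-1], abs=1e-12)


class TestSimulateTrajectory:
    def kernel(self, stack, beta=None, n_candidates=100):
        tk = ss.TentativeKernel(2.0, 0.01, 0.0, 0.5)
        return ss.RedistributionKernel(tk, beta or {}, stack,
                                       n_candidates=n_candidates)

    def test_same_seed_is_bit_identical(self, stack):
        kern = ss.RedistributionKernel(
            ss.TentativeKernel(2.0, 0.01, 0.0, 0.5),
            {"canopy_height": 0.3}, stack,
            standardization={"canopy_height": (25.0, 8.0)})
        a = ss.simulate_trajectory(kern, (1500.0, 1500.0), 30, rng_seed=7)
        b = ss.simulate_trajectory(kern, (1500.0, 1500.0), 30, rng_seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_start_off_raster_rejected(self, stack):
        kern = self.kernel(stack)
        with pytest.raises(ValueError, match="off-raster"):
            ss.simulate_trajectory(kern, (-1e6, 0.0), 10, 0)

    def test_null_selection_preserves_tentative_step_lengths(self):
        kern = self.kernel(flat_stack())
        centre = (20000.0, -20000.0)
        lengths = []
        for i in range(40):
            tr = ss.simulate_trajectory(kern, centre, 150, rng_seed=100 + i)
            lengths.append(tr.step_lengths)
        lengths = np.concatenate(lengths)
        # with beta = 0 every candidate is equally likely: step lengths
        # follow the tentative gamma
        p = stats.kstest(lengths, "gamma", args=(2.0, 0, 100.0)).pvalue
        assert p > 0.01

    def test_positive_swamp_selection_shifts_endpoints(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((400, 400), dtype=bool)
        mask[:, 200:] = True  # right half is swamp
        stack = flat_stack(swamp_mask=mask)
        start = (20000.0, -20000.0)  # on the boundary
        kern_null = self.kernel(stack)
        kern_sel = self.kernel(stack, beta={"swamp": 2.0})

        def frac_in_swamp(kern, seeds):
            hits = total = 0
            for s in seeds:
                tr = ss.simulate_trajectory(kern, start, 20, rng_seed=s)
                sw = stack.covariates_at_many(*tr.endpoints().T)["swamp"]
                hits += np.nansum(sw)
                total += np.isfinite(sw).sum()
            return hits / total

        f_null = frac_in_swamp(kern_null, range(40))
        f_sel = frac_in_swamp(kern_sel, range(40))
        assert f_sel > f_null + 0.1

        # enumeration oracle for the FIRST step from the boundary:
        # E[P(swamp)] = E[ sum w 1_swamp / sum w ] under the tentative draw
        tk = kern_sel.tentative
        probs = []
        for _ in range(3000):
            sl = rng.gamma(tk.sl_shape, 1 / tk.sl_rate, 100)
            ta = rng.vonmises(tk.ta_mu, tk.ta_kappa, 100)
            h = rng.uniform(-np.pi, np.pi)
            xs = start[0] + sl * np.cos(h + ta)
            in_swamp = xs >= 20000.0
            w = np.exp(2.0 * in_swamp)
            probs.append(w[in_swamp].sum() / w.sum())
        expected_first = np.mean(probs)
        first = []
        for s in range(2000):
            tr = ss.simulate_trajectory(kern_sel, start, 1, rng_seed=s)
            sw = stack.covariates_at_many(*tr.endpoints().T)["swamp"]
            first.append(sw[0])
        assert np.mean(first) == pytest.approx(expected_first, abs=0.05)


class TestSeedShadow:
    def one_step_traj(self, dx=300.0):
        pos = np.array([[0.0, 0.0], [dx, 0.0]])
        return ss.Trajectory(pos, np.array([dx]), np.array([0.0]), 20.0)

    def test_point_mass_is_conserved(self):
        sh = ss.seed_shadow([self.one_step_traj()], np.array([1.0]))
        assert sh.total_mass == pytest.approx(1.0, abs=1e-6)
        assert sh.distance_summary["median_m"] == pytest.approx(300.0,
                                                                abs=10.0)
        assert sh.distance_summary["max_m"] == pytest.approx(300.0)

    def test_zero_weights_give_zero_raster(self):
        sh = ss.seed_shadow([self.one_step_traj()], np.array([0.0]))
        assert sh.total_mass == 0.0
        assert sh.lam == 0.0

    def test_duplicating_trajectories_changes_nothing(self):
        trajs = [self.one_step_traj(200.0), self.one_step_traj(500.0)]
        w = np.array([1.0])
        a = ss.seed_shadow(trajs, w)
        b = ss.seed_shadow(trajs * 2, w, grid=a.deposition)
        np.testing.assert_allclose(a.deposition.values, b.deposition.values,
                                   atol=1e-12)

    def test_mass_conservation_and_lambda_definition(self, stack):
        kern = ss.RedistributionKernel(
            ss.TentativeKernel(2.0, 0.01, 0.0, 0.5),
            {"canopy_height": 0.3}, stack,
            standardization={"canopy_height": (25.0, 8.0)})
        trajs = [ss.simulate_trajectory(kern, (1500.0, 1500.0), 50,
                                        rng_seed=i) for i in range(30)]
        w, tail = ss.deposition_weights(ss.fit_gut_passage(345, 39))
        sh = ss.seed_shadow(trajs, w, tail_mass=tail)
        per_traj = np.mean([w[:tr.n_steps].sum() for tr in trajs])
        assert sh.total_mass == pytest.approx(per_traj, abs=1e-6)
        assert sh.lam == pytest.approx(
            sh.total_mass / sh.deposition.values.size, rel=1e-12)

    def test_lambda_shrinks_as_extent_grows(self):
        tr = self.one_step_traj()
        small = ss.RasterGrid(np.zeros((100, 100)), 10.0, (-500.0, 500.0))
        big = ss.RasterGrid(np.zeros((300, 300)), 10.0, (-1500.0, 1500.0))
        sh_small = ss.seed_shadow([tr], np.array([1.0]), grid=small)
        sh_big = ss.seed_shadow([tr], np.array([1.0]), grid=big)
        assert sh_small.total_mass == pytest.approx(sh_big.total_mass,
                                                    abs=1e-6)
        assert sh_big.lam < sh_small.lam

    def test_max_distance_bounded_by_kernel_reach(self, stack):
        kern = ss.RedistributionKernel(
            ss.TentativeKernel(2.0, 0.01, 0.0, 0.5), {}, stack)
        trajs = [ss.simulate_trajectory(kern, (1500.0, 1500.0), 50,
                                        rng_seed=i) for i in range(20)]
        w, _ = ss.deposition_weights(ss.fit_gut_passage(345, 39))
        sh = ss.seed_shadow(trajs, w)
        p999 = stats.gamma.ppf(0.999, a=2.0, scale=100.0)
        assert sh.distance_summary["median_m"] <= \
            sh.distance_summary["max_m"]
        assert sh.distance_summary["max_m"] <= 50 * p999

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            ss.seed_shadow([self.one_step_traj()], np.array([1.0]),
                           bandwidth=0.0)


class TestSamplePoints:
    def test_poisson_mean_matches_intensity(self):
        sh = ss.seed_shadow([ss.Trajectory(
            np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 100.0]]),
            np.array([100.0, np.sqrt(2) * 100]), np.zeros(2), 20.0)],
            np.array([0.4, 0.6]))
        counts = [len(ss.sample_seed_points(sh, 50, rng_seed=i))
                  for i in range(1000)]
        expected = 50 * sh.total_mass
        assert np.mean(counts) == pytest.approx(expected, rel=0.02)

    def test_zero_raster_yields_no_points(self):
        sh = ss.seed_shadow([ss.Trajectory(
            np.array([[0.0, 0.0], [100.0, 0.0]]), np.array([100.0]),
            np.zeros(1), 20.0)], np.array([0.0]))
        assert len(ss.sample_seed_points(sh, 100, rng_seed=1)) == 0

    def test_fixed_seed_reproduces_points(self):
        sh = ss.seed_shadow([self_traj()], np.array([1.0]))
        a = ss.sample_seed_points(sh, 200, rng_seed=3)
        b = ss.sample_seed_points(sh, 200, rng_seed=3)
        np.testing.assert_array_equal(a, b)


def self_traj():
    pos = np.array([[0.0, 0.0], [300.0, 0.0]])
    return ss.Trajectory(pos, np.array([300.0]), np.array([0.0]), 20.0)


class TestEvaluateMovementModel:
    def frame(self, values):
        return pd.DataFrame({"canopy_height": values})

    def test_identical_sets_have_zero_divergence(self):
        rng = np.random.default_rng(0)
        v = rng.normal(25, 5, 500)
        out = ss.evaluate_movement_model(self.frame(v), self.frame(v),
                                         self.frame(v), ["canopy_height"])
        assert out["canopy_height"]["tv_used_vs_simulated"] == 0.0

    def test_fitted_simulation_closer_than_null(self, stack, stack_std):
        tk = ss.TentativeKernel(2.0, 0.01, 0.0, 0.5)
        strata = ss.gen_strata(400, {"canopy_height": 0.8}, 10, tk, stack,
                               stack_std, seed=5)
        used = strata[strata["case"]]
        avail = strata[~strata["case"]]
        kern_fit = ss.RedistributionKernel(tk, {"canopy_height": 0.8},
                                           stack, stack_std)
        kern_null = ss.RedistributionKernel(tk, {}, stack, stack_std)

        def sim_endpoints(kern, seed0):
            rows = []
            for i in range(60):
                tr = ss.simulate_trajectory(kern, (1500.0, 1500.0), 30,
                                            rng_seed=seed0 + i)
                covs = stack.covariates_at_many(*tr.endpoints().T)
                mean, sd = stack_std["canopy_height"]
                rows.append((covs["canopy_height"] - mean) / sd)
            return pd.DataFrame({
                "canopy_height": np.concatenate(rows)}).dropna()

        sim_fit = sim_endpoints(kern_fit, 100)
        sim_null = sim_endpoints(kern_null, 500)
        d_fit = ss.evaluate_movement_model(
            used, avail, sim_fit,
            ["canopy_height"])["canopy_height"]["tv_used_vs_simulated"]
        d_null = ss.evaluate_movement_model(
            used, avail, sim_null,
            ["canopy_height"])["canopy_height"]["tv_used_vs_simulated"]
        assert d_null > d_fit

    def test_quantile_tables_are_monotone(self):
        rng = np.random.default_rng(2)
        out = ss.evaluate_movement_model(
            self.frame(rng.normal(size=300)),
            self.frame(rng.normal(size=300)),
            self.frame(rng.normal(size=300)), ["canopy_height"])
        q = out["canopy_height"]["quantiles"]
        for col in q.columns:
            assert q[col].is_monotonic_increasing

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ss.evaluate_movement_model(self.frame([]), self.frame([1.0]),
                                       self.frame([1.0]), ["canopy_height"])


def test_weighted_quantile_against_repetition():
    vals = np.array([1.0, 5.0, 10.0])
    w = np.array([2.0, 1.0, 1.0])
    expanded = np.repeat(vals, (2, 1, 1))
    assert ss.weighted_quantile(vals, w, 0.5) == pytest.approx(
        np.quantile(expanded, 0.5), abs=2.0)
    assert ss.weighted_quantile(vals, np.ones(3), [0.0, 1.0])[1] == 10.0


def test_tree_and_gut_passage_readers(tmp_path):
    geojson = tmp_path / "trees.geojson"
    geojson.write_text(
        '{"type": "FeatureCollection", "features": ['
        '{"type": "Feature", "geometry": {"type": "Point",'
        ' "coordinates": [1500.0, 1500.0]},'
        ' "properties": {"id": "t1", "species": "Staudtia kamerunensis"}}]}')
    trees = ss.read_trees(geojson)
    assert len(trees) == 1
    assert trees["x"].iloc[0] == 1500.0
    assert trees["species"].iloc[0] == "Staudtia kamerunensis"

    csv = tmp_path / "trees.csv"
    csv.write_text("id,species,x,y\nt2,Maesopsis eminii,10.0,20.0\n")
    trees2 = ss.read_trees(csv)
    assert trees2["y"].iloc[0] == 20.0

    gpt = tmp_path / "gpt.csv"
    gpt.write_text("hornbill_species,tree_species,mean_min,spread_min\n"
                   "BCH,Staudtia kamerunensis,345,39\n"
                   "WTH,Staudtia kamerunensis,162,8\n")
    models = ss.read_gut_passage_csv(gpt)
    assert len(models) == 2
    assert models[0].mean == 345
    assert models[1].gamma_shape == pytest.approx((162 / 8) ** 2)
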