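"""Inverse solver: error metric, k <-> D conversion, grid search, PSO."""

import numpy as np
import pytest

import rdapso as r
from rdapso.inverse import _parse_outlier_rule


def ratio_set(tau, sigma, days=None, bounds=None):
    tau = np.asarray(tau, float)
    sigma = np.asarray(sigma, float)
    days = np.arange(1, len(tau) + 1, dtype=float) if days is None else days
    bounds = 15.0 * np.arange(len(sigma) + 1) if bounds is None else bounds
    return r.RatioSet(temporal=tau, spatial=sigma, collection_days=days, zone_bounds=bounds)


class TestErrorMetric:
    def test_zero_iff_identical(self):
        a = ratio_set([0.6, 0.4], [0.3, 0.7])
        b = ratio_set([0.6, 0.4], [0.3, 0.7])
        assert r.error_E(a, b) == 0.0
        c = ratio_set([0.5, 0.5], [0.3, 0.7])
        assert r.error_E(a, c) > 0.0

    def test_euclidean_norm_by_hand(self):
        # sigma differs by (0.3, -0.3, 0), tau identical:
        # E = 1/2 * (sqrt(0.09 + 0.09) + 0) = 0.15 * sqrt(2)
        a = ratio_set([0.5, 0.5], [0.5, 0.5, 0.0])
        b = ratio_set([0.5, 0.5], [0.2, 0.8, 0.0])
        assert r.error_E(a, b) == pytest.approx(0.5 * 0.3 * np.sqrt(2))

    def test_symmetric_and_grid_checked(self):
        a = ratio_set([0.6, 0.4], [0.3, 0.7])
        b = ratio_set([0.2, 0.8], [0.5, 0.5])
        assert r.error_E(a, b) == pytest.approx(r.error_E(b, a))
        c = ratio_set([0.6, 0.4], [0.3, 0.7], days=np.array([2.0, 5.0]))
        with pytest.raises(ValueError, match="different day/zone grids"):
            r.error_E(a, c)


class TestStepDiffusionConversion:
    @pytest.mark.parametrize(
        "k,expected",
        [(35.0, 36.75), (36.87, 40.78), (71.99, 155.48), (120.67, 436.84)],
    )
    def test_published_conversions(self, k, expected):
        assert r.k_to_D(k, h=0.1, S=12) == pytest.approx(expected, abs=0.005)

    def test_round_trip_and_degenerate_zero(self):
        for D in (0.5, 36.75, 400.0):
            assert r.k_to_D(r.D_to_k(D)) == pytest.approx(D, rel=1e-14)
        for k in (0.1, 35.0, 120.67):
            assert r.D_to_k(r.k_to_D(k)) == pytest.approx(k, rel=1e-14)
        assert r.k_to_D(0.0) == 0.0


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, recovery_scenario):
        spec, layout, census, obs = recovery_scenario
        walk = r.WalkConfig(k=1.0, n_days=spec.n_days, N=500, reps=1)
        gs = r.grid_search(obs, layout, walk, (35, 35), (10, 10), resolution=1, seed=0)
        assert gs.best_k == 35 and gs.best_q == 10
        assert gs.init_box == {"k": (35.0, 35.0), "q": (10.0, 10.0)}

    def test_argmin_cell_brackets_the_truth(self, recovery_scenario):
        # coarse landscape around synthetic data generated at k=35, q=10
        spec, layout, census, obs = recovery_scenario
        walk = r.WalkConfig(k=1.0, n_days=spec.n_days, N=1500, reps=2)
        gs = r.grid_search(obs, layout, walk, (15, 55), (5, 30), resolution=5, seed=1)
        k_lo, k_hi = gs.init_box["k"]
        assert k_lo <= spec.k <= k_hi
        assert np.isfinite(gs.errors).all()
        # unique global minimum cell
        assert (gs.errors == gs.errors.min()).sum() == 1

    def test_empty_range_rejected(self, recovery_scenario):
        spec, layout, census, obs = recovery_scenario
        walk = r.WalkConfig(k=1.0, n_days=spec.n_days, N=100, reps=1)
        with pytest.raises(ValueError, match="empty parameter range"):
            r.grid_search(obs, layout, walk, (30, 20), (5, 10), seed=0)


class TestPSO:
    def test_gbest_error_never_increases(self, recovery_scenario):
        spec, layout, census, obs = recovery_scenario
        walk = r.WalkConfig(k=1.0, n_days=spec.n_days, N=500, reps=1)
        config = r.PSOConfig(k_bounds=(15, 55), q_bounds=(5, 30),
                             n_particles=6, n_generations=4)
        res = r.pso_optimize(obs, layout, walk, config, seed=12)
        assert np.all(np.diff(res.gbest_history) <= 1e-15)
        assert res.E == res.gbest_history[-1]

    def test_pso_refines_the_grid_minimum(self, recovery_scenario):
        spec, layout, census, obs = recovery_scenario
        walk = r.WalkConfig(k=1.0, n_days=spec.n_days, N=1000, reps=2)
        gs = r.grid_search(obs, layout, walk, (15, 55), (5, 30), resolution=4, seed=3)
        config = r.PSOConfig(k_bounds=(15, 55), q_bounds=(5, 30),
                             n_particles=10, n_generations=6)
        res = r.pso_optimize(obs, layout, walk, config, init_box=gs.init_box, seed=4)
        assert res.E <= gs.best_error

    def test_degenerate_init_box_with_zero_velocity_stays_put(self, recovery_scenario):
        spec, layout, census, obs = recovery_scenario
        walk = r.WalkConfig(k=1.0, n_days=spec.n_days, N=300, reps=1)
        config = r.PSOConfig(k_bounds=(15, 55), q_bounds=(5, 30),
                             n_particles=3, n_generations=3,
                             fixed={"p": 0.0, "s_e": 1.0})
        box = {"k": (35.0, 35.0), "q": (10.0, 10.0)}
        res = r.pso_optimize(obs, layout, walk, config, init_box=box, seed=5)
        assert (res.k, res.q, res.p, res.s_e) == (35.0, 10.0, 0.0, 1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_particles"):
            r.PSOConfig(k_bounds=(1, 2), q_bounds=(1, 2), n_particles=1)
        with pytest.raises(ValueError, match="degenerate bounds"):
            r.PSOConfig(k_bounds=(2, 2), q_bounds=(1, 2))
        with pytest.raises(ValueError, match="s_e bounds"):
            r.PSOConfig(k_bounds=(1, 2), q_bounds=(1, 2), s_e_bounds=(0.0, 1.0))


class TestReplicateAggregation:
    def test_step_parameter_identifiable_while_trap_params_trade_off(self, recovery_result):
        # q, p and s_e compensate for one another across runs; the derived
        # diffusion coefficient varies much less than the trap description
        tup = np.array(recovery_result.tuples)
        k, q, s_e = tup[:, 0], tup[:, 1], tup[:, 3]
        D = np.array([r.k_to_D(v) for v in k])
        cv = lambda v: v.std(ddof=1) / v.mean()
        assert cv(D) < cv(q * s_e)

    def test_outlier_rules_parse(self):
        assert _parse_outlier_rule("mean+1.0sd") == 1.0
        assert _parse_outlier_rule("mean+0.5sd") == 0.5
        with pytest.raises(ValueError):
            _parse_outlier_rule("median")

    def test_published_mean_k_conversions_per_study(self, center_study, cairns_study):
        assert r.k_to_D(center_study.reported_mean_k) == pytest.approx(40.78, abs=0.005)
        assert r.k_to_D(cairns_study.reported_mean_k) == pytest.approx(436.84, abs=0.005)

    def test_identical_runs_have_no_outliers_and_zero_spread(self, monkeypatch):
        # aggregate logic in isolation: stub out the expensive optimizers
        import rdapso.inverse as inv

        tup = (35.0, 10.0, 0.0, 1.0, 0.02)
        monkeypatch.setattr(inv, "grid_search",
                            lambda *a, **k: r.GridSearchResult(
                                k_values=np.array([35.0]), q_values=np.array([10.0]),
                                errors=np.array([[0.02]]), best_k=35.0, best_q=10.0,
                                best_error=0.02, init_box={"k": (35, 35), "q": (10, 10)}))
        monkeypatch.setattr(inv, "pso_optimize",
                            lambda *a, **k: r.PSOResult(*tup, gbest_history=np.array([0.02])))
        obs = ratio_set([0.6, 0.4], [0.3, 0.7])
        layout = r.StudyLayout(release=(0.0, 0.0), zone_bounds=[0.0, 15.0, 30.0])
        walk = r.WalkConfig(k=1.0, n_days=2, N=10, reps=1)
        config = r.PSOConfig(k_bounds=(15, 55), q_bounds=(5, 30))
        res = inv.run_replicates(obs, layout, walk, config, n_runs=4, seed=0)
        assert res.kept.all()
        assert res.k_mean == 35.0 and res.k_sd == 0.0
        assert res.D == pytest.approx(36.75)
        assert res.D_ci == pytest.approx((36.75, 36.75))
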