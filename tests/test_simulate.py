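"""Synthetic-data generators: SNR calibration, design structure, and the
benchmark harness."""

import numpy as np
import pytest
from scipy.special import expit

from hierridge.simulate import (
    SimScenario,
    benchmark,
    binary_scenario,
    continuous_scenario,
    default_continuous_gamma,
    discrete_scenario,
    simulate,
    solve_sigma_beta,
    _ar1_normal,
)


class TestSolveSigmaBeta:
    def test_definition(self, rng):
        # construct Z whose empirical covariance quadratic form is known
        Z = rng.standard_normal((500, 3))
        gamma = np.array([1.0, -2.0, 0.5])
        quad = gamma @ np.cov(Z, rowvar=False) @ gamma
        sb = solve_sigma_beta(gamma, Z, snr_gamma=quad)  # target SNR = quad
        assert sb == pytest.approx(1.0, rel=1e-12)

    def test_quadrupling_snr_halves_sigma(self, rng):
        Z = rng.standard_normal((200, 4))
        g = rng.standard_normal(4)
        assert solve_sigma_beta(g, Z, 4.0) == pytest.approx(
            solve_sigma_beta(g, Z, 1.0) / 2, rel=1e-12
        )

    def test_round_trip_identity(self):
        for sc in [
            discrete_scenario(n=30, n_test=10, p=300, seed=5),
            continuous_scenario(n=30, n_test=10, p=200, q=150, seed=5),
            binary_scenario(n=60, n_test=30, p=200, q=150, seed=5),
        ]:
            ds = simulate(sc)
            g = ds.gamma_true
            achieved = (g @ np.cov(ds.Z, rowvar=False) @ g) / ds.sigma_beta**2
            assert achieved == pytest.approx(sc.snr_gamma, abs=1e-12)

    def test_null_meta_signal_rejected(self):
        with pytest.raises(ValueError, match="signal is zero"):
            solve_sigma_beta(np.zeros(3), np.random.default_rng(0).random((50, 3)), 1.0)
        with pytest.raises(ValueError):
            solve_sigma_beta(np.ones(2), np.ones((10, 2)), -1.0)


class TestScenarios:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimScenario(rho_X=1.0)
        with pytest.raises(ValueError):
            SimScenario(snr_gamma=0.0)
        with pytest.raises(ValueError):
            SimScenario(z_density=0.0)

    def test_structured_gamma_pattern(self):
        g = default_continuous_gamma(250)
        assert g.size == 250
        assert np.count_nonzero(g) == 100
        assert np.allclose(g[:50], 0.01) and np.allclose(g[75:100], 0.03)
        with pytest.raises(ValueError, match="q >= 150"):
            default_continuous_gamma(120)

    def test_section_defaults(self):
        assert discrete_scenario().mu0 == 0.2
        assert continuous_scenario().mu0 == 0.5
        assert binary_scenario().family == "binomial"
        assert discrete_scenario().n_test == 1000


class TestSimulate:
    def test_deterministic_given_seed(self):
        sc = discrete_scenario(n=20, n_test=10, p=50, seed=7)
        a, b = simulate(sc), simulate(sc)
        assert np.array_equal(a.X_train, b.X_train)
        assert np.array_equal(a.y_test, b.y_test)
        assert np.array_equal(a.Z, b.Z)

    def test_shapes_and_no_empty_meta_columns(self):
        sc = discrete_scenario(n=25, n_test=15, p=60, q=6, seed=1)
        ds = simulate(sc)
        assert ds.X_train.shape == (25, 60)
        assert ds.X_test.shape == (15, 60)
        assert ds.Z.shape == (60, 6)
        assert np.all(ds.Z.sum(axis=0) > 0)
        assert set(np.unique(ds.Z)) <= {0.0, 1.0}

    def test_discrete_density_near_target(self):
        ds = simulate(discrete_scenario(n=5, n_test=5, p=3000, q=6, seed=2))
        assert ds.Z.mean() == pytest.approx(0.2, abs=0.02)

    def test_continuous_meta_columns_uncorrelated_when_rho_zero(self):
        sc = continuous_scenario(n=5, n_test=5, p=2000, q=150, seed=3)
        ds = simulate(sc)
        C = np.corrcoef(ds.Z[:, :10], rowvar=False)
        off = C[np.triu_indices(10, 1)]
        assert np.max(np.abs(off)) < 3 / np.sqrt(2000)

    def test_feature_covariance_is_ar1(self):
        X = _ar1_normal(np.random.default_rng(0), 5000, 8, 0.5)
        emp = np.cov(X, rowvar=False)
        i, j = np.indices((8, 8))
        assert np.max(np.abs(emp - 0.5 ** np.abs(i - j))) < 0.05

    def test_binary_event_rate_matches_logistic_intercept(self):
        # vanishing coefficient signal: event rate ~ logistic(mu0) = 0.622
        sc = binary_scenario(
            n=4000, n_test=10, p=150, q=150, seed=4,
            gamma=np.full(150, 1e-9), snr_gamma=1.0,
        )
        ds = simulate(sc)
        rate = ds.y_train.mean()
        assert rate == pytest.approx(expit(0.5), abs=3 * 0.48 / np.sqrt(4000))

    def test_null_scenario_is_pure_noise(self):
        # gamma ~ 0 and sigma_beta ~ 0 make y essentially pure noise around mu0
        sc = discrete_scenario(
            n=100, n_test=200, p=40, q=6, seed=8,
            gamma=np.full(6, 1e-9), snr_gamma=1e4,
        )
        ds = simulate(sc)
        assert np.max(np.abs(ds.beta_true)) < 1e-6
        assert ds.y_train.mean() == pytest.approx(sc.mu0, abs=4 / np.sqrt(100))
        assert ds.y_train.var() == pytest.approx(sc.sigma_y**2, rel=0.5)


class TestParameterRecovery:
    def test_gamma_recovered_under_strong_snr(self):
        # highly informative meta-features: the fitted gamma should track
        # the generating gamma across replications
        gamma = np.array([0.5, 0.3, 0.1, -0.1, -0.3, -0.5])
        from hierridge import HierarchicalRidge

        cors = []
        for r in range(15):
            sc = discrete_scenario(
                n=400, n_test=10, p=200, q=6, snr_gamma=50.0, gamma=gamma, seed=300 + r
            )
            ds = simulate(sc)
            cv = HierarchicalRidge(ds.y_train, ds.X_train, ds.Z).fit_cv(
                k=5, seed=r, n_lambda=6
            )
            g = cv.results.gamma
            if g.size == 0:  # ridge row selected: no meta coefficients
                cors.append(0.0)
            else:
                cors.append(np.corrcoef(g, gamma)[0, 1])
        assert np.median(cors) > 0.5


class TestBenchmark:
    def test_tidy_output_and_determinism(self):
        sc = discrete_scenario(n=60, n_test=60, p=40, q=4, seed=10,
                               gamma=np.full(4, 0.1))
        tab = benchmark(sc, reps=2, k=4, n_lambda=4, seed=10)
        assert set(tab.columns) == {"rep", "method", "metric", "value"}
        assert len(tab) == 2 * 3
        assert set(tab["method"]) == {"twolevel", "ridge", "augmented"}
        tab2 = benchmark(sc, reps=2, k=4, n_lambda=4, seed=10)
        assert np.allclose(tab["value"], tab2["value"])

    def test_external_predictions_hook(self):
        sc = discrete_scenario(n=40, n_test=30, p=20, q=3, seed=11,
                               gamma=np.full(3, 0.1))
        calls = []

        def dummy(ds, rep):
            calls.append(rep)
            return np.full(ds.y_test.size, ds.y_train.mean())

        tab = benchmark(
            sc, methods=("dummy",), reps=2, k=4, n_lambda=3, seed=11,
            external_predictions={"dummy": dummy},
        )
        assert calls == [0, 1]
        assert np.all(tab["value"] <= 0.05)  # constant predictor has R^2 <= 0

    def test_binary_metric_is_auc(self):
        sc = binary_scenario(n=80, n_test=80, p=30, seed=12,
                             q=4, gamma=np.full(4, 0.5))
        tab = benchmark(sc, methods=("ridge",), reps=1, k=4, n_lambda=3, seed=12)
        assert tab["metric"].iloc[0] == "test_auc"
        assert 0 <= tab["value"].iloc[0] <= 1


class TestNoiseMetaFeatureGrowth:
    def test_extra_noise_meta_features_hurt_two_level_but_not_ridge(self):
        # growing q with a fixed signal block only adds noise meta-features:
        # the two-level advantage should shrink while standard ridge,
        # which never sees Z, stays flat in expectation
        from hierridge import HierarchicalRidge
        from sklearn.metrics import r2_score

        reps = 6
        res = {q: {"twolevel": [], "ridge": []} for q in (150, 500)}
        for q in (150, 500):
            for r in range(reps):
                sc = continuous_scenario(
                    n=200, n_test=300, p=500, q=q, snr_gamma=1.0, seed=700 + r
                )
                ds = simulate(sc)
                two = HierarchicalRidge(ds.y_train, ds.X_train, ds.Z).fit_cv(
                    k=5, seed=r, n_lambda=8
                )
                one = HierarchicalRidge(ds.y_train, ds.X_train).fit_cv(
                    k=5, seed=r, n_lambda=8
                )
                res[q]["twolevel"].append(r2_score(ds.y_test, two.predict(ds.X_test)))
                res[q]["ridge"].append(r2_score(ds.y_test, one.predict(ds.X_test)))
        two_drop = np.mean(res[150]["twolevel"]) - np.mean(res[500]["twolevel"])
        assert two_drop >= -0.01  # performance nonincreasing in q (MC tolerance)
        # per-dataset advantage over ridge (which never sees Z) must shrink
        adv = {
            q: np.mean(np.array(res[q]["twolevel"]) - np.array(res[q]["ridge"]))
            for q in (150, 500)
        }
        assert adv[150] > adv[500]
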