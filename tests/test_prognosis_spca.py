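import numpy as np
import pandas as pd
import pytest

from hifbind.prognosis_spca import (
    GOOD_PROGNOSIS,
    POOR_PROGNOSIS,
    PatientRecord,
    cox_fit,
    cox_fit_batch,
    km_estimator,
    loo_cv,
    median_split_eval,
    prognostic_score,
    spca_fit,
    stratify_cohort,
    univariate_screen,
)
from hifbind.synthetic_data import SimulationConfig, simulate_cohort


def _patient(age=50, stage=1, metastasis=False, deceased=False, time=100.0,
             event=False, id="p1"):
    return PatientRecord(id, age, stage, metastasis, deceased, time, event)


class TestPrognosticScore:
    def test_all_indicators_false(self):
        score, group = prognostic_score(_patient(age=55, stage=2))
        assert (score, group) == (0, GOOD_PROGNOSIS)

    def test_all_indicators_true(self):
        score, group = prognostic_score(
            _patient(age=65, stage=3, metastasis=True, deceased=True, event=True)
        )
        assert (score, group) == (4, POOR_PROGNOSIS)

    def test_score_one_is_good(self):
        score, group = prognostic_score(_patient(age=61))
        assert (score, group) == (1, GOOD_PROGNOSIS)

    def test_score_two_is_poor(self):
        score, group = prognostic_score(_patient(age=61, stage=4))
        assert (score, group) == (2, POOR_PROGNOSIS)

    def test_age_sixty_not_over(self):
        score, _ = prognostic_score(_patient(age=60))
        assert score == 0


class TestPatientRecord:
    def test_invalid_stage(self):
        with pytest.raises(ValueError):
            _patient(stage=5)

    def test_nonpositive_time(self):
        with pytest.raises(ValueError):
            _patient(time=0.0)

    def test_event_implies_deceased(self):
        with pytest.raises(ValueError):
            _patient(event=True, deceased=False)


class TestStratifyCohort:
    def test_missing_rows_excluded(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "age": [65.0, np.nan],
                "stage": [3, 2],
                "metastasis": [True, False],
                "deceased": [False, False],
                "time": [100.0, 50.0],
                "event": [False, False],
            }
        )
        out = stratify_cohort(df)
        assert out["id"].tolist() == ["a"]
        assert out.loc[0, "score"] == 3

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            stratify_cohort(pd.DataFrame({"id": ["a"]}))


def brute_force_km(times, events):
    """Hand product-limit: walk distinct event times, multiply (1 - d/n)."""
    pairs = sorted(zip(times, events))
    out = {}
    s = 1.0
    for t in sorted({t for t, e in pairs if e}):
        n_at_risk = sum(1 for tt, _ in pairs if tt >= t)
        d = sum(1 for tt, e in pairs if tt == t and e)
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


class TestKmEstimator:
    def test_no_events(self):
        km = km_estimator([5, 6, 7], [False, False, False])
        assert np.all(km["evaluate"]([1, 10, 100]) == 1.0)

    def test_two_events_by_hand(self):
        km = km_estimator([1, 2], [True, True])
        np.testing.assert_allclose(km["survival"], [0.5, 0.0])
        np.testing.assert_allclose(km["evaluate"]([0.5, 1.5, 2.5]), [1.0, 0.5, 0.0])

    def test_all_censored(self):
        km = km_estimator([5, 5, 5], [False] * 3)
        assert km["evaluate"]([4.9])[0] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([], [])

    def test_exhaustive_small_fixtures(self, rng):
        # every fixture with <= 5 subjects vs the hand oracle
        for _ in range(200):
            n = int(rng.integers(1, 6))
            times = rng.integers(1, 6, size=n).astype(float)
            events = rng.random(n) < 0.6
            km = km_estimator(times, events)
            oracle = brute_force_km(times, events)
            for t, s in oracle.items():
                assert km["evaluate"]([t])[0] == pytest.approx(s, abs=1e-12)


class TestCoxFit:
    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for _ in range(5):
            n = 120
            x = rng.standard_normal(n)
            t = rng.exponential(np.exp(-0.7 * x)) + 0.01
            t = np.round(t, 2) + 0.01  # induce some ties
            e = rng.random(n) < 0.8
            if e.sum() < 2:
                continue
            mine = cox_fit(x, t, e)
            cph = lifelines.CoxPHFitter().fit(
                pd.DataFrame({"x": x, "T": t, "E": e}), "T", "E"
            )
            assert mine.coef == pytest.approx(float(cph.params_.iloc[0]), abs=1e-4)
            assert mine.se == pytest.approx(
                float(cph.standard_errors_.iloc[0]), abs=1e-4
            )

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1.0] * 10, np.arange(1, 11.0), [True] * 10)

    def test_single_event_degenerate_no_crash(self):
        res = cox_fit([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [True, False, False])
        assert not res.converged and np.isnan(res.hazard_ratio)

    def test_ci_contains_hazard_ratio(self, rng):
        x = rng.standard_normal(100)
        t = rng.exponential(np.exp(-x)) + 0.01
        res = cox_fit(x, t, np.ones(100, bool))
        assert res.ci95[0] < res.hazard_ratio < res.ci95[1]

    def test_null_calibration(self, rng):
        # 200 independent null covariates in a single batch fit
        n = 200
        t = rng.exponential(1.0, n)
        e = np.ones(n, bool)
        X = rng.standard_normal((n, 200))
        res = cox_fit_batch(X, t, e)
        frac = np.mean(res["pvalue"] < 0.05)
        assert 0.01 <= frac <= 0.1

    def test_parameter_recovery(self, rng):
        hits = 0
        for _ in range(20):
            z = rng.standard_normal(400)
            t = rng.exponential(np.exp(-z)) + 1e-4  # scale exp(-z): hazard exp(z)
            res = cox_fit(z, t, np.ones(400, bool))
            if abs(res.coef - 1.0) < 0.25:
                hits += 1
        assert hits >= 16  # >= 80%

    def test_binary_covariate_agrees_with_logrank(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test

        for _ in range(25):
            n = 60
            grp = rng.random(n) < 0.5
            t = rng.exponential(np.where(grp, 0.5, 1.0)) + 0.01
            e = np.ones(n, bool)
            if grp.sum() < 2 or (~grp).sum() < 2:
                continue
            res = cox_fit(grp.astype(float), t, e)
            lr = logrank_test(t[grp], t[~grp], e[grp], e[~grp])
            # direction: coef > 0 iff group 1 has higher hazard (shorter times)
            direction_cox = np.sign(res.coef)
            direction_lr = np.sign(np.median(t[~grp]) - np.median(t[grp]))
            if lr.p_value < 0.2:  # only compare when there is a real signal
                assert direction_cox == direction_lr


class TestUnivariateScreen:
    def test_null_pass_rate(self, rng):
        n, g = 150, 100
        X = rng.standard_normal((n, g))
        t = rng.exponential(1.0, n)
        kept = univariate_screen(X, [f"g{i}" for i in range(g)], t,
                                 np.ones(n, bool))
        sigma = np.sqrt(g * 0.05 * 0.95)
        assert abs(len(kept) - 0.05 * g) <= 3 * sigma + 1

    def test_planted_genes_all_pass(self, rng):
        n, g = 400, 10
        z = rng.standard_normal(n)
        X = z[:, None] * 1.0 + rng.normal(0, 0.3, (n, g))
        t = rng.exponential(np.exp(-z)) + 1e-4
        kept = univariate_screen(X, [f"g{i}" for i in range(g)], t,
                                 np.ones(n, bool))
        assert len(kept) == g

    def test_alpha_zero_empty(self, rng):
        X = rng.standard_normal((50, 5))
        kept = univariate_screen(X, list("abcde"), rng.exponential(1, 50),
                                 np.ones(50, bool), alpha=0.0)
        assert kept == []

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            univariate_screen(np.ones((10, 1)), ["a"], np.arange(1, 11.0),
                              np.ones(10, bool))


class TestSpcaFit:
    def test_rank_one_equal_loadings_closed_form(self, rng):
        g, n = 6, 200
        z = rng.standard_normal(n)
        X = np.repeat(z[:, None], g, axis=1) + rng.normal(0, 1e-9, (n, g))
        t = rng.exponential(np.exp(-z)) + 1e-4
        model, scores = spca_fit(X, [f"g{i}" for i in range(g)], t,
                                 np.ones(n, bool))
        np.testing.assert_allclose(np.abs(model.weights), 1 / np.sqrt(g), atol=1e-6)

    def test_two_identical_genes(self, rng):
        z = rng.standard_normal(100)
        X = np.column_stack([z, z])
        t = rng.exponential(np.exp(-z)) + 1e-4
        model, _ = spca_fit(X, ["a", "b"], t, np.ones(100, bool))
        np.testing.assert_allclose(np.abs(model.weights),
                                   [1 / np.sqrt(2)] * 2, atol=1e-9)

    def test_sign_oriented_towards_hazard(self, rng):
        z = rng.standard_normal(300)
        X = z[:, None] * np.array([1.0, -1.0]) + rng.normal(0, 0.2, (300, 2))
        t = rng.exponential(np.exp(-z)) + 1e-4  # scale exp(-z): high z -> high hazard
        model, scores = spca_fit(X, ["a", "b"], t, np.ones(300, bool))
        assert np.corrcoef(scores, z)[0, 1] > 0.9

    def test_block_structure(self, rng):
        n = 400
        z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
        block1 = z1[:, None] + rng.normal(0, 0.3, (n, 4))
        block2 = z2[:, None] + rng.normal(0, 0.3, (n, 4))
        X = np.column_stack([block1, block2])
        t = rng.exponential(np.exp(-z1)) + 1e-4
        genes = [f"g{i}" for i in range(8)]
        e = np.ones(n, bool)
        # the supervised step: survival-coupled block survives the screen
        kept = univariate_screen(X, genes, t, e)
        block1_kept = [g for g in kept if int(g[1]) < 4]
        assert len(block1_kept) == 4 and len(kept) < 8
        cols = [genes.index(g) for g in kept]
        model, _ = spca_fit(X[:, cols], kept, t, e)
        w = np.abs(model.weights)
        in_block1 = np.array([int(g[1]) < 4 for g in kept])
        assert w[in_block1].mean() >= 2 * (w[~in_block1].mean() if (~in_block1).any() else 0.0)

    def test_invariant_to_permutations(self, rng):
        n, g = 100, 5
        X = rng.standard_normal((n, g)) + rng.standard_normal(n)[:, None]
        t = rng.exponential(1, n) + 1e-4
        e = np.ones(n, bool)
        genes = [f"g{i}" for i in range(g)]
        model, _ = spca_fit(X, genes, t, e)
        perm_p = rng.permutation(n)
        perm_g = rng.permutation(g)
        model_p, _ = spca_fit(X[perm_p][:, perm_g], [genes[j] for j in perm_g],
                              t[perm_p], e[perm_p])
        np.testing.assert_allclose(model_p.weights, model.weights[perm_g],
                                   atol=1e-8)

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha"):
            spca_fit(np.ones((10, 1)), ["a"], np.arange(1, 11.0),
                     np.ones(10, bool))


class TestLooCv:
    def test_duplicated_patients_identical_folds(self, rng):
        base_x = rng.standard_normal(6)
        X = np.tile(base_x, (12, 1))
        X = X + np.tile(rng.standard_normal((4, 6)), (3, 1))[:12]
        t = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        e = np.ones(12, bool)
        scores = loo_cv(X, [f"g{i}" for i in range(6)], t, e, alpha=1.0)
        # identical patients must get identical out-of-fold scores
        for i in range(4):
            group = scores[i::4]
            np.testing.assert_allclose(group, group[0], atol=1e-8)

    def test_minimum_size_enforced(self, rng):
        with pytest.raises(ValueError):
            loo_cv(rng.standard_normal((5, 3)), list("abc"),
                   np.arange(1, 6.0), np.ones(5, bool))

    def test_failed_fold_gives_nan(self, rng):
        n = 15
        X = rng.standard_normal((n, 3))
        t = rng.exponential(1, n) + 0.01
        scores = loo_cv(X, list("abc"), t, np.ones(n, bool), alpha=1e-9)
        assert np.isnan(scores).all()

    def test_custom_screen_and_fit_is_used(self, rng):
        from hifbind.prognosis_spca import _default_screen_and_fit

        n = 15
        z = rng.standard_normal(n)
        X = z[:, None] + rng.normal(0, 0.3, (n, 4))
        t = rng.exponential(np.exp(-z)) + 0.01
        e = np.ones(n, bool)
        fold_sizes = []

        def recording(x, genes, times, events, alpha):
            fold_sizes.append(x.shape[0])
            return _default_screen_and_fit(x, genes, times, events, alpha)

        loo_cv(X, list("abcd"), t, e, alpha=1.0, screen_and_fit=recording)
        assert fold_sizes == [n - 1] * n


class TestMedianSplitEval:
    def test_strong_ordering_significant(self, rng):
        n = 120
        z = rng.standard_normal(n)
        t = rng.exponential(np.exp(-2 * z)) + 1e-4
        fit = median_split_eval(z, t, np.ones(n, bool))
        assert fit.hazard_ratio > 1
        assert fit.pvalue < 0.01
        assert set(fit.km_curves) == {"above_median", "below_median"}

    def test_random_scores_null(self, rng):
        covered = 0
        for _ in range(20):
            n = 100
            t = rng.exponential(1.0, n)
            fit = median_split_eval(rng.standard_normal(n), t, np.ones(n, bool))
            if fit.ci95[0] <= 1.0 <= fit.ci95[1]:
                covered += 1
        assert covered >= 18 * 0.9  # >= 90% of 20, allow one boundary miss

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            median_split_eval([1.0] * 10, np.arange(1, 11.0), np.ones(10, bool))

    def test_minimal_cohort_runs(self):
        fit = median_split_eval([1.0, 2.0, 3.0, 4.0], [5.0, 4.0, 2.0, 1.0],
                                np.ones(4, bool))
        assert np.isfinite(fit.hazard_ratio) or not np.isfinite(fit.pvalue)


class TestCohortPipeline:
    def test_null_cohort_loo_scores_uncorrelated(self):
        nonsig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, n_patients=80, latent_effect=0.0)
            expr, clinical, _ = simulate_cohort(cfg, [f"g{i}" for i in range(8)])
            t = clinical["time"].to_numpy()
            e = clinical["event"].to_numpy(dtype=bool)
            scores = loo_cv(expr.to_numpy(), list(expr.columns), t, e, alpha=0.2)
            ok = np.isfinite(scores)
            if ok.sum() < 10:
                nonsig += 1
                continue
            res = cox_fit(scores[ok], t[ok], e[ok])
            if not np.isfinite(res.pvalue) or res.pvalue > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * n_seeds

    def test_weight_sign_recovery(self):
        cfg = SimulationConfig(seed=2, n_patients=400, latent_effect=1.0)
        genes = [f"g{i}" for i in range(20)]
        expr, clinical, truth = simulate_cohort(cfg, genes)
        t = clinical["time"].to_numpy()
        e = clinical["event"].to_numpy(dtype=bool)
        kept = univariate_screen(expr.to_numpy(), genes, t, e)
        assert len(kept) >= 2
        model, _ = spca_fit(expr[kept].to_numpy(), kept, t, e)
        loadings = truth.set_index("gene").loc[kept, "loading"].to_numpy()
        match = np.mean(np.sign(model.weights) == np.sign(loadings))
        assert match >= 0.9
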