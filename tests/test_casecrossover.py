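import numpy as np
import pandas as pd
import pytest

from ozsesmod.casecrossover import (
    CaseCrossoverStratum,
    CovariateSpec,
    NonIdentifiableError,
    Stage1Error,
    adjusted_day_of_year,
    build_referent_sets,
    build_stratum_design,
    conditional_loglik,
    exclude_sparse_zctas,
    fit_conditional_logistic,
    natural_cubic_spline_basis,
    run_stage1_city,
)
from ozsesmod.simulate import generate_study
from tests.conftest import city_exposure, make_config


def stratum(x_rows, case_index=0, weight=1.0, cols=("x",), sid=0):
    X = np.atleast_2d(np.asarray(x_rows, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    return CaseCrossoverStratum(
        stratum_id=sid,
        dates=list(range(X.shape[0])),
        case_index=case_index,
        X=X,
        columns=list(cols),
        weight=weight,
    )


class TestReferentSets:
    def test_calendar_enumeration(self):
        refs = build_referent_sets("2002-07-17", ("2002-01-01", "2002-12-31"))
        assert [r.strftime("%Y-%m-%d") for r in refs] == [
            "2002-07-03", "2002-07-10", "2002-07-24", "2002-07-31",
        ]

    def test_three_or_four_referents(self):
        period = ("2002-01-01", "2004-12-31")
        rng = np.random.default_rng(0)
        days = pd.date_range(*period)
        for d in rng.choice(len(days), 60, replace=False):
            refs = build_referent_sets(days[d], period)
            assert len(refs) in (3, 4)
            assert all(r.month == days[d].month and r.year == days[d].year for r in refs)
            assert all(r.dayofweek == days[d].dayofweek for r in refs)

    def test_four_occurrence_month_gives_three_referents(self):
        # Feb 2002 (28 days) has exactly four of each weekday
        refs = build_referent_sets("2002-02-14", ("2002-01-01", "2002-12-31"))
        assert len(refs) == 3

    def test_outside_period_error(self):
        with pytest.raises(ValueError):
            build_referent_sets("2003-01-01", ("2002-01-01", "2002-12-31"))


class TestSpline:
    def test_boundary_days_evaluate(self):
        doy = np.arange(1, 367, dtype=float)
        knots = np.quantile(doy, np.linspace(0, 1, 6))
        basis = natural_cubic_spline_basis(np.array([1.0, 60.0, 366.0]), knots)
        assert np.all(np.isfinite(basis))
        assert basis.shape == (3, 5)

    def test_linear_beyond_boundary_knots(self):
        # natural spline: second differences vanish outside the boundary
        knots = np.array([10.0, 30.0, 50.0, 70.0, 90.0, 110.0])
        x = np.array([111.0, 120.0, 129.0])
        b = natural_cubic_spline_basis(x, knots)
        second_diff = b[2] - 2 * b[1] + b[0]
        assert np.allclose(second_diff, 0.0, atol=1e-8)

    def test_adjusted_doy_alignment(self):
        # Mar 1 maps to 61 in leap and non-leap years alike; Feb 29 is 60
        dates = pd.DatetimeIndex(["2004-02-29", "2004-03-01", "2003-03-01", "2003-02-28"])
        doy = adjusted_day_of_year(dates)
        assert list(doy) == [60.0, 61.0, 61.0, 59.0]


class TestStratumDesign:
    def test_matched_covariates_constant_and_polys_hand_computed(self, tiny_study):
        expo = city_exposure(tiny_study, "A")
        zcta = expo.o3.columns[0]
        case = "2002-07-17"
        refs = build_referent_sets(case, ("2002-01-01", "2002-12-31"))
        s = build_stratum_design(
            {"zcta": zcta, "case_date": case, "referent_dates": refs},
            expo,
            CovariateSpec(),
        )
        df = pd.DataFrame(s.X, columns=s.columns)
        # matching makes day-of-week and season identical across rows
        plain = [
            c for c in s.columns
            if (c.startswith("dow_") or c.startswith("season_")) and ":" not in c
        ]
        for c in plain:
            assert df[c].nunique() == 1
        # polynomial terms equal hand-computed powers of the 3-day MA temperature
        t = expo.tmax_ma02.loc[s.dates].to_numpy()
        assert np.allclose(df["tmax_ma02_p1"], t)
        assert np.allclose(df["tmax_ma02_p2"], t**2)
        assert np.allclose(df["tmax_ma02_p3"], t**3)
        d = expo.dew_ma02.loc[s.dates].to_numpy()
        assert np.allclose(df["dew_ma02_p3"], d**3)

    def test_missing_exposure_rows_removed(self, tiny_study):
        expo = city_exposure(tiny_study, "A")
        zcta = expo.o3.columns[0]
        # first study day: its own MA is undefined -> case row removed -> dropped
        s = build_stratum_design(
            {"zcta": zcta, "case_date": "2002-01-01",
             "referent_dates": build_referent_sets("2002-01-01", ("2002-01-01", "2002-12-31"))},
            expo,
            CovariateSpec(),
        )
        assert s is None


class TestConditionalLogit:
    def test_paired_binary_closed_form(self):
        # 7 case-exposed and 3 control-exposed discordant pairs: bhat = log(7/3)
        strata = [stratum([1.0, 0.0], case_index=0, sid=i) for i in range(7)]
        strata += [stratum([0.0, 1.0], case_index=0, sid=7 + i) for i in range(3)]
        fit = fit_conditional_logistic(strata, focus="x")
        assert fit.converged
        assert fit.params["x"] == pytest.approx(np.log(7 / 3), abs=1e-6)
        # McNemar-style variance of the paired conditional MLE: 1/7 + 1/3
        assert fit.cov_params.loc["x", "x"] == pytest.approx(1 / 7 + 1 / 3, rel=1e-4)

    def test_weighted_strata_equal_replicated_strata(self):
        strata_rep = [stratum([1.0, 0.0], sid=i) for i in range(7)]
        strata_rep += [stratum([0.0, 1.0], sid=7 + i) for i in range(3)]
        strata_w = [
            stratum([1.0, 0.0], weight=7.0, sid=0),
            stratum([0.0, 1.0], weight=3.0, sid=1),
        ]
        f1 = fit_conditional_logistic(strata_rep)
        f2 = fit_conditional_logistic(strata_w)
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-10)
        assert f1.cov_params.loc["x", "x"] == pytest.approx(
            f2.cov_params.loc["x", "x"], rel=1e-8
        )

    def test_matches_dense_grid_search(self):
        rng = np.random.default_rng(11)
        strata = [
            stratum(rng.uniform(0, 1, size=4), case_index=int(rng.integers(4)), sid=i)
            for i in range(3)
        ]
        fit = fit_conditional_logistic(strata, focus="x")

        def loglik(b):  # independent hand-rolled conditional log-likelihood
            tot = 0.0
            for s in strata:
                eta = s.X[:, 0] * b
                tot += eta[s.case_index] - np.log(np.exp(eta).sum())
            return tot

        grid = np.linspace(-20, 20, 400_001)
        best = grid[np.argmax([loglik(b) for b in grid[:: 1000]]) * 1000]
        fine = np.linspace(best - 0.1, best + 0.1, 20_001)
        b_star = fine[np.argmax([loglik(b) for b in fine])]
        assert fit.params["x"] == pytest.approx(b_star, abs=1e-4)

    def test_no_within_stratum_variation_error(self):
        strata = [stratum([5.0, 5.0], sid=i) for i in range(4)]
        with pytest.raises(NonIdentifiableError):
            fit_conditional_logistic(strata, focus="x")

    def test_loglik_at_zero_equals_minus_log_sizes(self):
        rng = np.random.default_rng(2)
        strata = [
            stratum(rng.normal(size=k), case_index=0, sid=i)
            for i, k in enumerate([2, 3, 4, 5])
        ]
        ll0 = conditional_loglik(strata, np.zeros(1))
        assert ll0 == pytest.approx(-sum(np.log([2, 3, 4, 5])))

    def test_stratum_constant_covariate_cancels(self):
        rng = np.random.default_rng(3)
        base = [
            stratum(rng.uniform(0, 2, size=4), case_index=int(rng.integers(4)), sid=i)
            for i in range(12)
        ]
        f0 = fit_conditional_logistic(base, focus="x")
        aug = []
        for i, s in enumerate(base):
            X = np.column_stack([s.X[:, 0], np.full(4, float(i + 1))])
            aug.append(
                CaseCrossoverStratum(s.stratum_id, s.dates, s.case_index, X, ["x", "const"])
            )
        f1 = fit_conditional_logistic(aug, focus="x")
        assert "const" in f1.dropped_columns
        assert f1.params["x"] == pytest.approx(f0.params["x"], abs=1e-8)

    def test_referent_order_invariance(self):
        rng = np.random.default_rng(4)
        xs = [rng.uniform(0, 2, size=4) for _ in range(10)]
        cases = [int(rng.integers(4)) for _ in range(10)]
        strata = [stratum(x, case_index=c, sid=i) for i, (x, c) in enumerate(zip(xs, cases))]
        perm_strata = []
        for i, (x, c) in enumerate(zip(xs, cases)):
            order = rng.permutation(4)
            perm_strata.append(stratum(x[order], case_index=int(np.argmax(order == c)), sid=i))
        f1 = fit_conditional_logistic(strata)
        f2 = fit_conditional_logistic(perm_strata)
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-10)

    def test_against_statsmodels_conditional_logit(self):
        # independent implementation cross-check on a 2-covariate problem
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(5)
        rows, ys, groups = [], [], []
        true_b = np.array([0.8, -0.5])
        for g in range(60):
            X = rng.normal(size=(4, 2))
            p = np.exp(X @ true_b)
            case = rng.choice(4, p=p / p.sum())
            rows.append(X)
            ys.append(np.eye(4)[case])
            groups.extend([g] * 4)
        X = np.vstack(rows)
        y = np.concatenate(ys)
        sm_fit = ConditionalLogit(y, X, groups=np.array(groups)).fit(disp=0)
        strata = []
        for g in range(60):
            Xg = X[4 * g: 4 * g + 4]
            case = int(np.argmax(y[4 * g: 4 * g + 4]))
            strata.append(
                CaseCrossoverStratum(g, list(range(4)), case, Xg, ["x1", "x2"])
            )
        fit = fit_conditional_logistic(strata)
        assert np.allclose(fit.params.to_numpy(), sm_fit.params, atol=1e-4)
        assert np.allclose(
            fit.cov_params.to_numpy(), np.asarray(sm_fit.cov_params()), rtol=1e-4
        )


class TestSparseExclusion:
    def test_threshold_boundary(self):
        counts = pd.Series({"a": 49, "b": 50, "c": 51})
        kept, excl = exclude_sparse_zctas(counts)
        assert kept == ["b", "c"] and excl == ["a"]

    def test_registry_with_twelve_sparse(self):
        rng = np.random.default_rng(6)
        counts = pd.Series(rng.integers(50, 5000, size=191), index=[f"z{i}" for i in range(191)])
        sparse = rng.choice(191, size=12, replace=False)
        counts.iloc[sparse] = rng.integers(0, 50, size=12)
        kept, excl = exclude_sparse_zctas(counts)
        assert len(kept) == 179 and len(excl) == 12

    def test_no_sparse_zctas(self):
        kept, excl = exclude_sparse_zctas(pd.Series([50, 60]))
        assert excl == []


class TestStage1Runner:
    def test_error_when_all_zctas_sparse(self, tiny_study):
        expo = city_exposure(tiny_study, "A")
        vis = tiny_study.visits[tiny_study.visits["city"] == "A"].head(30)
        with pytest.raises(Stage1Error):
            run_stage1_city(vis, expo, city="A")

    def test_null_city_mean_estimate_near_zero(self):
        # >= 200 ZCTAs, no confounding, theta_z = 0 everywhere
        cfg = make_config(
            cities=("N",),
            zctas_per_city=(220,),
            study_periods={"N": ("2002-01-01", "2002-12-31")},
            alpha0=0.0,
            gamma={},
            tau=0.0,
            confounding_strength=0.0,
            baseline_rate_range=(0.3, 1.5),
            seed=42,
        )
        study = generate_study(cfg)
        expo = city_exposure(study, "N")
        res = run_stage1_city(study.visits, expo, city="N")
        est = res.estimates[res.estimates["converged"]]
        assert len(est) >= 200
        mean = est["beta_hat"].mean()
        se = est["beta_hat"].std(ddof=1) / np.sqrt(len(est))
        assert abs(mean) < 2 * se + 1e-12

    def test_estimates_unbiased_for_generated_truth(self):
        # regression of beta_hat on true theta_z has slope ~ 1
        cfg = make_config(
            cities=("U",),
            zctas_per_city=(150,),
            study_periods={"U": ("2002-01-01", "2003-12-31")},
            tau=0.01,
            baseline_rate_range=(0.2, 1.5),
            seed=21,
        )
        study = generate_study(cfg)
        expo = city_exposure(study, "U")
        res = run_stage1_city(study.visits, expo, city="U")
        est = res.estimates[res.estimates["converged"]]
        theta = study.truth.theta_series().loc[est.index]
        A = np.column_stack([np.ones(len(est)), theta.to_numpy()])
        coef, res_ss, *_ = np.linalg.lstsq(A, est["beta_hat"].to_numpy(), rcond=None)
        dof = len(est) - 2
        s2 = res_ss[0] / dof
        se_slope = np.sqrt(s2 * np.linalg.inv(A.T @ A)[1, 1])
        assert abs(coef[1] - 1.0) < 3 * se_slope

    def test_estimates_reported_per_kept_zcta(self, tiny_study):
        expo = city_exposure(tiny_study, "A")
        vis = tiny_study.visits[tiny_study.visits["city"] == "A"]
        res = run_stage1_city(vis, expo, city="A")
        counts = vis.groupby("zcta").size()
        assert set(res.estimates.index) == set(counts.index[counts >= 50])
        assert (res.estimates["n_visits"] >= 50).all()
        assert (res.estimates.loc[res.estimates["converged"], "var_hat"] > 0).all()
        assert "Stage 1" in res.summary()
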