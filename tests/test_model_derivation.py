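import math

import numpy as np
import pandas as pd
import pytest

from latedating import model_derivation as md
from latedating.model_derivation import (
    CANDIDATE_MODELS,
    CandidateModel,
    SingularDesignError,
    cross_validate_kfold,
    cross_validate_leave_site_out,
    derive_models,
    fit_model,
    fit_to_equation,
    predict_ga,
    select_model,
    standardized_error,
)


def make_lnlinear_data(
    rng,
    n_participants=500,
    visits=2,
    a=-60.0,
    b=105.0,
    c=58.0,
    noise_sd=5.0,
    sites=("A", "B", "C"),
    cluster_sd=0.0,
    signal="tcd_fl",
):
    """Scans with GA = a + b*lnTCD + c*lnFL + eps; BPD/AC carry no GA signal."""
    rows = []
    for i in range(n_participants):
        site = sites[i % len(sites)]
        cluster_effect = rng.normal(0, cluster_sd)
        for v in range(visits):
            tcd = rng.uniform(2.2, 5.2)
            fl = rng.uniform(3.0, 7.5)
            ac = rng.uniform(18.0, 34.0)
            bpd = rng.uniform(5.0, 9.5)
            if signal == "tcd_fl":
                ga = a + b * math.log(tcd) + c * math.log(fl)
            elif signal == "ac":
                ga = a + 120.0 + 130.0 * math.log(ac) - 240.0
            else:  # pure noise
                ga = 210.0
            ga += cluster_effect + rng.normal(0, noise_sd)
            rows.append(
                {
                    "visit_id": f"p{i}-v{v}",
                    "participant_id": f"p{i}",
                    "site": site,
                    "window": "W1" if v == 0 else "W2",
                    "ga_gold_days": ga,
                    "tcd_cm": tcd,
                    "fl_cm": fl,
                    "ac_cm": ac,
                    "bpd_cm": bpd,
                    "hc_cm": rng.uniform(20.0, 33.0),
                }
            )
    return pd.DataFrame(rows)


def normal_equations_oracle(df, covariates):
    """Brute-force least squares via the normal equations."""
    X = np.column_stack(
        [np.ones(len(df))] + [np.log(df[f"{p.lower()}_cm"].to_numpy()) for p in covariates]
    )
    y = df["ga_gold_days"].to_numpy()
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestStandardizedError:
    def test_perfect_prediction(self):
        assert standardized_error(200.0, 200.0) == 0.0

    def test_worked_value(self):
        assert standardized_error(210.0, 200.0) == pytest.approx(0.5)

    def test_symmetry_in_squared_error(self):
        assert standardized_error(190.0, 200.0) == pytest.approx(0.5)

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            standardized_error(200.0, 0.0)
        with pytest.raises(ValueError):
            standardized_error(200.0, -3.0)


class TestFitModel:
    def test_matches_normal_equations_oracle(self, rng):
        df = make_lnlinear_data(rng, n_participants=40)
        model = CandidateModel("model2", ("TCD", "FL"))
        fit = fit_model(df, model)
        oracle = normal_equations_oracle(df, model.covariates)
        assert np.allclose(fit.coefficients, oracle, atol=1e-8)

    def test_coefficient_recovery(self, rng):
        df = make_lnlinear_data(rng, n_participants=1000)
        fit = fit_model(df, CandidateModel("model2", ("TCD", "FL")))
        for est, se, truth in zip(fit.coefficients, fit.cluster_robust_se, (-60.0, 105.0, 58.0)):
            assert abs(est - truth) < 3.5 * se

    def test_duplicated_rows_leave_estimates_unchanged(self, rng):
        df = make_lnlinear_data(rng, n_participants=60)
        model = CandidateModel("model2", ("TCD", "FL"))
        doubled = pd.concat([df, df], ignore_index=True)
        assert fit_model(df, model).coefficients == pytest.approx(
            fit_model(doubled, model).coefficients, abs=1e-9
        )

    def test_nested_adjusted_r2(self, rng):
        df = make_lnlinear_data(rng, n_participants=300)
        complete = df.dropna()
        full = fit_model(complete, CandidateModel("model1", ("TCD", "BPD", "FL", "AC")))
        small = fit_model(complete, CandidateModel("model2", ("TCD", "FL")))
        assert full.adjusted_r2 >= small.adjusted_r2 - 0.01

    def test_cluster_robust_se_exceeds_classical_with_correlated_clusters(self, rng):
        import statsmodels.api as sm

        # perfectly correlated clusters: each participant's visit duplicated
        df = make_lnlinear_data(rng, n_participants=200, visits=1)
        doubled = pd.concat([df, df], ignore_index=True)
        model = CandidateModel("model2", ("TCD", "FL"))
        fit = fit_model(doubled, model)
        X = sm.add_constant(
            np.column_stack([np.log(doubled["tcd_cm"]), np.log(doubled["fl_cm"])])
        )
        classical = sm.OLS(doubled["ga_gold_days"].to_numpy(), X).fit().bse
        for robust_se, classical_se in zip(fit.cluster_robust_se, classical):
            assert robust_se > classical_se

    def test_singular_design_raises(self, rng):
        df = make_lnlinear_data(rng, n_participants=50)
        df["bpd_cm"] = df["tcd_cm"]  # lnBPD == lnTCD
        with pytest.raises(SingularDesignError, match="lnTCD"):
            fit_model(df, CandidateModel("model3", ("TCD", "BPD")))

    def test_too_few_rows_rejected(self, rng):
        df = make_lnlinear_data(rng, n_participants=1, visits=1)
        with pytest.raises(ValueError, match="complete-case"):
            fit_model(df, CandidateModel("model2", ("TCD", "FL")))

    def test_complete_case_handling(self, rng):
        df = make_lnlinear_data(rng, n_participants=100)
        df.loc[:20, "fl_cm"] = np.nan
        fit = fit_model(df, CandidateModel("model2", ("TCD", "FL")))
        assert fit.n_obs == df["fl_cm"].notna().sum()


class TestPredict:
    def test_prediction_at_covariate_mean_equals_mean_response(self, rng):
        df = make_lnlinear_data(rng, n_participants=200)
        fit = fit_model(df, CandidateModel("model2", ("TCD", "FL")))
        mean_scan = {
            "tcd_cm": math.exp(np.log(df["tcd_cm"]).mean()),
            "fl_cm": math.exp(np.log(df["fl_cm"]).mean()),
        }
        assert fit.predict(mean_scan) == pytest.approx(
            df["ga_gold_days"].mean(), abs=1e-8
        )

    def test_registered_equation_matches_direct_predict(self, rng):
        df = make_lnlinear_data(rng, n_participants=100)
        fit = fit_model(df, CandidateModel("model2", ("TCD", "FL")))
        eq = fit_to_equation(fit)
        from latedating.dating_equations import ga_from_biometry

        for _, row in df.head(20).iterrows():
            assert ga_from_biometry(row, eq) == pytest.approx(
                fit.predict(row), abs=1e-12
            )

    def test_missing_covariate_propagates(self, rng):
        df = make_lnlinear_data(rng, n_participants=50)
        fit = fit_model(df, CandidateModel("model2", ("TCD", "FL")))
        assert math.isnan(fit.predict({"tcd_cm": 3.0}))

    def test_monotone_in_each_covariate(self, rng):
        df = make_lnlinear_data(rng, n_participants=400)
        fit = fit_model(df, CandidateModel("model2", ("TCD", "FL")))
        assert fit.coefficients[1] > 0 and fit.coefficients[2] > 0

    def test_predict_ga_on_frame(self, rng):
        df = make_lnlinear_data(rng, n_participants=30)
        fit = fit_model(df, CandidateModel("model2", ("TCD", "FL")))
        preds = predict_ga(fit, df)
        assert len(preds) == len(df) and preds.notna().all()


class TestKFold:
    def test_determinism(self, rng):
        df = make_lnlinear_data(rng, n_participants=120)
        model = CandidateModel("model2", ("TCD", "FL"))
        a = cross_validate_kfold(df, model, seed=11)
        b = cross_validate_kfold(df, model, seed=11)
        assert a == b

    def test_different_seed_changes_folds(self, rng):
        df = make_lnlinear_data(rng, n_participants=120)
        model = CandidateModel("model2", ("TCD", "FL"))
        assert cross_validate_kfold(df, model, seed=1).fold_errors != cross_validate_kfold(
            df, model, seed=2
        ).fold_errors

    def test_true_model_beats_intercept_only(self, rng):
        df = make_lnlinear_data(rng, n_participants=250)
        good = cross_validate_kfold(df, CandidateModel("model2", ("TCD", "FL")), seed=3)
        null = cross_validate_kfold(df, CandidateModel("null", ()), seed=3)
        assert good.summary_error < null.summary_error

    def test_leave_one_cluster_out_degenerate_k(self, rng):
        df = make_lnlinear_data(rng, n_participants=12)
        model = CandidateModel("model2", ("TCD", "FL"))
        cv = cross_validate_kfold(df, model, k=12, seed=0)
        assert len(cv.fold_errors) == 12
        assert math.isfinite(cv.summary_error) and cv.summary_error >= 0

    def test_k_too_small_or_large(self, rng):
        df = make_lnlinear_data(rng, n_participants=10)
        model = CandidateModel("model2", ("TCD", "FL"))
        with pytest.raises(ValueError):
            cross_validate_kfold(df, model, k=1)
        with pytest.raises(ValueError):
            cross_validate_kfold(df, model, k=11)

    def test_folds_partition_participants(self, rng):
        # duplicate visits of one participant must never straddle folds:
        # give one participant an extreme outlier pair and check the per-fold
        # errors spike in exactly one fold
        df = make_lnlinear_data(rng, n_participants=50)
        idx = df["participant_id"] == "p0"
        df.loc[idx, "ga_gold_days"] += 120.0
        cv = cross_validate_kfold(df, CandidateModel("model2", ("TCD", "FL")), seed=5)
        spikes = [e for e in cv.fold_errors if e > np.median(cv.fold_errors) * 5]
        assert len(spikes) == 1

    def test_summary_statistic_options(self, rng):
        df = make_lnlinear_data(rng, n_participants=60)
        model = CandidateModel("model2", ("TCD", "FL"))
        mean_cv = cross_validate_kfold(df, model, seed=0, summary="mean")
        median_cv = cross_validate_kfold(df, model, seed=0, summary="median")
        sum_cv = cross_validate_kfold(df, model, seed=0, summary="sum")
        assert median_cv.summary_error <= mean_cv.summary_error <= sum_cv.summary_error


class TestLeaveSiteOut:
    def test_exchangeable_sites_give_similar_errors(self, rng):
        df = make_lnlinear_data(rng, n_participants=600)
        cv = cross_validate_leave_site_out(df, CandidateModel("model2", ("TCD", "FL")))
        errs = np.array(cv.fold_errors)
        assert len(errs) == 3
        assert errs.max() / errs.min() < 1.5

    def test_two_site_input_gives_two_folds(self, rng):
        df = make_lnlinear_data(rng, n_participants=100, sites=("A", "B"))
        cv = cross_validate_leave_site_out(df, CandidateModel("model2", ("TCD", "FL")))
        assert cv.fold_labels == ("A", "B")

    def test_single_site_rejected(self, rng):
        df = make_lnlinear_data(rng, n_participants=50, sites=("A",))
        with pytest.raises(ValueError, match="2 sites"):
            cross_validate_leave_site_out(df, CandidateModel("model2", ("TCD", "FL")))

    def test_shifted_site_still_finite(self, rng):
        df = make_lnlinear_data(rng, n_participants=150)
        df.loc[df["site"] == "C", "ga_gold_days"] -= 10.0
        cv = cross_validate_leave_site_out(df, CandidateModel("model2", ("TCD", "FL")))
        assert all(math.isfinite(e) for e in cv.fold_errors)


class TestSelectModel:
    def test_tcd_fl_signal_selects_model2(self, rng):
        df = make_lnlinear_data(rng, n_participants=400, signal="tcd_fl")
        fits, kfold, _ = derive_models(df, seed=1)
        sel = select_model(df, fits, kfold)
        assert sel.chosen.name == "model2"
        assert sel.final_fit.n_obs == fits["model2"].n_obs

    def test_ac_signal_selects_model4(self, rng):
        df = make_lnlinear_data(rng, n_participants=400, signal="ac")
        fits, kfold, _ = derive_models(df, seed=1)
        sel = select_model(df, fits, kfold)
        assert sel.chosen.name == "model4"

    def test_all_noise_still_selects_something(self, rng):
        df = make_lnlinear_data(rng, n_participants=200, signal="noise")
        fits, kfold, _ = derive_models(df, seed=1)
        sel = select_model(df, fits, kfold)
        assert sel.chosen.name in ("model2", "model3", "model4")

    def test_exact_tie_is_flagged_and_broken_deterministically(self, rng):
        df = make_lnlinear_data(rng, n_participants=200)
        df["ac_cm"] = df["fl_cm"]  # model4 becomes numerically identical to model2
        parsimonious = [m for m in CANDIDATE_MODELS if m.name != "model1"]
        fits, kfold, _ = derive_models(df, candidates=parsimonious, seed=1)
        sel = select_model(df, fits, kfold)
        assert sel.near_tie
        assert sel.chosen.name in ("model2", "model4")

    def test_ranking_covers_all_candidates(self, rng):
        df = make_lnlinear_data(rng, n_participants=200)
        fits, kfold, _ = derive_models(df, seed=1)
        sel = select_model(df, fits, kfold)
        assert set(sel.ranking["model"]) == {m.name for m in CANDIDATE_MODELS}

    def test_candidate_roster_matches_shipped_models(self):
        expected = {
            "model1": ("TCD", "BPD", "FL", "AC"),
            "model2": ("TCD", "FL"),
            "model3": ("TCD", "BPD"),
            "model4": ("TCD", "AC"),
        }
        assert {m.name: m.covariates for m in CANDIDATE_MODELS} == expected
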