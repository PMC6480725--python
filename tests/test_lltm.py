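"""Marginal-likelihood LLTM fitting, prediction and model comparison."""

import numpy as np
import pytest

from ansig.lltm import (
    bootstrap_item_se,
    compare_models,
    fit_lltm,
    fit_lltm_error,
    fit_rasch_mml,
    predict_difficulties,
    saturated_properties,
)
from ansig.qmatrix import ItemPropertyMatrix, build_qmatrix, expand_item_properties
from ansig.rasch import ResponseMatrix
from ansig.reference import LLTM_COEFFICIENTS, reference_items
from conftest import TRUE_ETA, TRUE_INTERCEPT, simulate_lltm_responses


class TestPrediction:
    def test_reference_coefficients_reproduce_published_predictions(self):
        """-(c + q'b) from the published coefficient table, per item model."""
        q = build_qmatrix("ansig", range(3, 14))
        pred = predict_difficulties(LLTM_COEFFICIENTS, q)
        assert pred[4] == pytest.approx(-3.24, abs=0.005)
        assert pred[8] == pytest.approx(0.01, abs=0.005)
        assert pred[12] == pytest.approx(1.54, abs=0.005)
        assert pred[13] == pytest.approx(1.54, abs=0.005)
        # full published column to accumulated-rounding tolerance (three
        # two-decimal coefficients can drift the sum by up to ~0.015)
        ref = reference_items()
        for item, row in ref.iterrows():
            assert pred[row.item_model] == pytest.approx(row.lltm, abs=0.02), item

    def test_all_zero_profile_gives_negated_intercept(self):
        q = build_qmatrix("holzman", [1])  # model 1 has an all-zero row there
        pred = predict_difficulties(
            {"intercept": 2.5, "eta": {k: 9.9 for k in q.operator_names}}, q)
        assert pred[1] == pytest.approx(-2.5)

    def test_operator_mismatch_raises(self):
        q = build_qmatrix("ansig", [3])
        with pytest.raises(ValueError, match="mismatch"):
            predict_difficulties({"intercept": 0, "eta": {"RD": 1.0}}, q)


class TestFitLLTM:
    def test_profile_grid_oracle_one_covariate(self):
        """Marginal likelihood matches a quadrature grid search, 3 items."""
        rng = np.random.default_rng(2)
        cov = np.array([[0.0], [1.0], [2.0]])
        props = ItemPropertyMatrix(item_ids=("a", "b", "c"), model_ids=(0, 1, 2),
                                   operator_names=("w",), covariates=cov)
        theta = rng.normal(0, 1.0, 400)
        easi = 0.5 - 0.8 * cov[:, 0]
        p = 1 / (1 + np.exp(-(theta[:, None] + easi[None, :])))
        rm = ResponseMatrix.from_array((rng.random(p.shape) < p).astype(float),
                                       item_ids=["a", "b", "c"])
        fit = fit_lltm(rm, props)

        # oracle: dense grid over (c, b) with sd profiled on a coarse grid
        from scipy.special import roots_hermitenorm

        nodes, wts = roots_hermitenorm(91)
        X = rm.scores.to_numpy()

        def loglik(c, b, sd):
            easi = c + b * cov[:, 0]
            L = sd * nodes[:, None] + easi[None, :]
            A = X @ L.T - np.logaddexp(0, L).sum(axis=1)[None, :]
            A = A + np.log(wts / np.sqrt(2 * np.pi))[None, :]
            m = A.max(axis=1, keepdims=True)
            return float((m[:, 0] + np.log(np.exp(A - m).sum(axis=1))).sum())

        best = max(((c, b, sd)
                    for c in np.arange(fit.intercept - 0.2, fit.intercept + 0.2, 0.02)
                    for b in np.arange(fit.eta.iloc[0] - 0.2, fit.eta.iloc[0] + 0.2, 0.02)
                    for sd in np.arange(0.7, 1.4, 0.05)),
                   key=lambda t: loglik(*t))
        assert fit.intercept == pytest.approx(best[0], abs=0.02)
        assert fit.eta.iloc[0] == pytest.approx(best[1], abs=0.02)

    def test_quadrature_insensitive_beyond_default(self, study_responses,
                                                   study_properties):
        lo = fit_lltm(study_responses, study_properties, n_quad=31, se=False)
        hi = fit_lltm(study_responses, study_properties, n_quad=121, se=False)
        assert np.abs(lo.fitted_difficulties - hi.fitted_difficulties).max() < 0.02
        assert lo.marg_loglik == pytest.approx(hi.marg_loglik, abs=0.05)

    def test_recovers_generating_coefficients(self, study_responses,
                                              study_properties):
        fit = fit_lltm(study_responses, study_properties)
        for name, true in TRUE_ETA.items():
            assert fit.eta[name] == pytest.approx(true, abs=4 * fit.se_eta[name])
        assert fit.intercept == pytest.approx(TRUE_INTERCEPT, abs=0.5)
        assert fit.person_var == pytest.approx(1.09 ** 2, abs=0.35)
        assert fit.n_params == 7  # intercept + 5 operators + person variance

    def test_saturated_model_equals_marginal_rasch(self):
        rng = np.random.default_rng(8)
        delta = np.linspace(-1, 1, 6)
        theta = rng.normal(0, 1, 500)
        p = 1 / (1 + np.exp(-(theta[:, None] - delta[None, :])))
        rm = ResponseMatrix.from_array((rng.random(p.shape) < p).astype(float))
        mml = fit_rasch_mml(rm)
        sat = fit_lltm(rm, saturated_properties(rm.item_ids), se=False)
        assert np.allclose(mml.fitted_difficulties, sat.fitted_difficulties,
                           atol=1e-6)
        d = mml.fitted_difficulties.to_numpy()
        assert np.corrcoef(d, delta)[0, 1] > 0.9

    def test_rank_deficient_properties_raise(self, study_responses, study_qmatrix):
        dup = ItemPropertyMatrix(
            item_ids=tuple(study_responses.item_ids),
            model_ids=tuple(range(len(study_responses.item_ids))),
            operator_names=("x", "y"),
            covariates=np.ones((len(study_responses.item_ids), 2)))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lltm(study_responses, dup)


class TestFitLLTMError:
    def test_zero_residual_variance_detected_at_boundary(self, study_properties):
        rm = simulate_lltm_responses(study_properties, 400, seed=31,
                                     item_resid_sd=0.0)
        plain = fit_lltm(rm, study_properties, se=False)
        err = fit_lltm_error(rm, study_properties, se=False)
        assert err.item_resid_var < 0.05
        assert err.deviance <= plain.deviance + 1e-9
        assert err.n_params == plain.n_params + 1

    def test_unit_residual_variance_recovered(self, study_properties):
        rm = simulate_lltm_responses(study_properties, 600, seed=32,
                                     item_resid_sd=1.0)
        err = fit_lltm_error(rm, study_properties, se=False)
        assert 0.5 < err.item_resid_var < 1.5
        assert err.item_residuals is not None
        plain = fit_lltm(rm, study_properties, se=False)
        assert err.deviance <= plain.deviance

    def test_person_estimates_agree_across_models(self, study_responses,
                                                  study_properties):
        from ansig.rasch import estimate_persons, fit_rasch_cml
        import pandas as pd

        cml = fit_rasch_cml(study_responses)
        pe = estimate_persons(cml, study_responses)
        lltm = fit_lltm(study_responses, study_properties, se=False)
        err = fit_lltm_error(study_responses, study_properties, se=False)
        df = pd.concat([pe.theta.rename("rasch"),
                        lltm.person_theta.rename("lltm"),
                        err.person_theta.rename("err")], axis=1).dropna()
        corr = df.corr()
        assert (corr.to_numpy() > 0.99).all()


class TestBootstrapAndComparison:
    def test_aic_bic_formulas(self):
        from ansig.lltm import LLTMFit
        import pandas as pd

        f = LLTMFit(eta=pd.Series(dtype=float), intercept=0.0, person_var=1.0,
                    item_resid_var=0.0, marg_loglik=-100.0, n_params=5,
                    fitted_difficulties=pd.Series(dtype=float),
                    se_eta=pd.Series(dtype=float), n_obs=1000)
        assert f.aic == pytest.approx(210.0)
        assert f.bic() == pytest.approx(234.54, abs=0.01)

    def test_bootstrap_se_calibrated_against_replications(self, study_properties):
        rm = simulate_lltm_responses(study_properties, 300, seed=40)
        fit = fit_lltm(rm, study_properties, se=False)
        boot = bootstrap_item_se(fit, rm, study_properties, n_iter=30, seed=1)
        assert boot["n_success"] == 30
        # independent replications from the true process
        reps = []
        for s in range(30):
            rep = simulate_lltm_responses(study_properties, 300, seed=500 + s)
            reps.append(fit_lltm(rep, study_properties, se=False).eta.to_numpy())
        emp_sd = np.array(reps).std(axis=0, ddof=1)
        boot_sd = boot["se_eta"].to_numpy()[1:]
        assert np.all(np.abs(boot_sd - emp_sd) / emp_sd < 0.6)
        rep1 = bootstrap_item_se(fit, rm, study_properties, n_iter=5, seed=9)
        rep2 = bootstrap_item_se(fit, rm, study_properties, n_iter=5, seed=9)
        assert np.allclose(rep1["se_eta"], rep2["se_eta"])

    def test_bootstrap_rejects_tiny_n_iter(self, study_properties):
        rm = simulate_lltm_responses(study_properties, 100, seed=41)
        fit = fit_lltm(rm, study_properties, se=False)
        with pytest.raises(ValueError):
            bootstrap_item_se(fit, rm, study_properties, n_iter=1, seed=0)

    def test_nested_comparison_table(self, study_responses, study_properties):
        plain = fit_lltm(study_responses, study_properties, se=False)
        err = fit_lltm_error(study_responses, study_properties, se=False)
        cmp = compare_models([plain, err], nested_pairs=[(0, 1)])
        assert list(cmp.table.index) == ["lltm", "lltm_error"]
        row = cmp.lr_tests.iloc[0]
        assert row.df == 1
        assert row.statistic >= 0

    def test_holzman_likelihood_never_exceeds_ansig(self, study_responses,
                                                    study_properties):
        """The nested four-determinant scheme cannot fit better."""
        from ansig.qmatrix import from_frame

        qa = build_qmatrix("ansig", range(3, 14))
        # drop the aliased extrapolation column (identical to PD) so the
        # restricted model is identified; the spanned model is unchanged
        qh = from_frame(build_qmatrix("holzman", range(3, 14)).to_frame()
                        .drop(columns="Ex"), scheme="holzman")
        assign = list(zip(study_properties.item_ids, study_properties.model_ids))
        pa = expand_item_properties(qa, assign)
        ph = expand_item_properties(qh, assign)
        fa = fit_lltm(study_responses, pa, se=False)
        fh = fit_lltm(study_responses, ph, se=False)
        assert fh.marg_loglik <= fa.marg_loglik + 1e-6

    def test_mismatched_data_fingerprints_raise(self, study_properties):
        a = fit_lltm(simulate_lltm_responses(study_properties, 100, seed=50),
                     study_properties, se=False)
        b = fit_lltm(simulate_lltm_responses(study_properties, 120, seed=51),
                     study_properties, se=False)
        with pytest.raises(ValueError, match="same observed"):
            compare_models([a, b])
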