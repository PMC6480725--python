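"""Conditional maximum likelihood calibration and its diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from ansig.rasch import (
    ResponseMatrix,
    andersen_lr_test,
    estimate_persons,
    fit_rasch_cml,
    person_separation_reliability,
    wald_item_tests,
    _esf,
)
from ansig.rasch import test_information as information_curve
from ansig.reference import reference_difficulties


def brute_force_cml(X, grid_then_polish=True):
    """Independent conditional-likelihood maximiser for a 3-item matrix."""
    X = np.asarray(X, float)

    def cll(d2, d3):
        delta = np.array([-d2 - d3, d2, d3])
        gamma = _esf(np.exp(-delta))
        ll = 0.0
        for row in X:
            r = int(row.sum())
            if r in (0, 3):
                continue
            ll += -(row * delta).sum() - np.log(gamma[r])
        return ll

    best = max(((d2, d3) for d2 in np.arange(-6, 6, 0.1)
                for d3 in np.arange(-6, 6, 0.1)), key=lambda p: cll(*p))
    if max(abs(best[0]), abs(best[1])) > 4:
        return None  # conditional MLE diverges for this pattern
    res = minimize(lambda p: -cll(*p), best, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12})
    d2, d3 = res.x
    return np.array([-d2 - d3, d2, d3])


class TestCMLOracle:
    def test_three_item_fixture_matches_grid_oracle(self):
        X = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
        fit = fit_rasch_cml(ResponseMatrix.from_array(X))
        oracle = brute_force_cml(X)
        assert np.abs(fit.difficulties.to_numpy() - oracle).max() < 1e-3

    def test_all_mixed_six_person_matrices_sampled(self):
        """CML equals exhaustive maximisation on random 6x3 mixed matrices."""
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 12:
            X = rng.integers(0, 2, (6, 3)).astype(float)
            col_ok = all(0 < X[:, j].sum() < 6 for j in range(3))
            informative = any(0 < X[v].sum() < 3 for v in range(6))
            if not (col_ok and informative):
                continue
            oracle = brute_force_cml(X)
            if oracle is None:
                continue
            fit = fit_rasch_cml(ResponseMatrix.from_array(X))
            assert np.abs(fit.difficulties.to_numpy() - oracle).max() < 1e-3
            checked += 1

    def test_equal_item_totals_force_equal_difficulties(self):
        X = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        fit = fit_rasch_cml(ResponseMatrix.from_array(X))
        assert np.allclose(fit.difficulties.to_numpy(), [0.0, 0.0], atol=1e-8)

    def test_sum_zero_identification_and_positive_se(self, study_responses):
        fit = fit_rasch_cml(study_responses)
        assert abs(fit.difficulties.sum()) < 1e-6
        assert (fit.se > 0).all()


def simulate_two_forms(difficulties, n_a=396, n_b=174, seed=0, theta_shift=0.0):
    """Anchored two-form layout: first 10 items appear in both forms."""
    rng = np.random.default_rng(seed)
    k = len(difficulties)
    split = 10 + (k - 10) // 2
    form_a = np.arange(0, split)
    form_b = np.r_[np.arange(0, 10), np.arange(split, k)]
    n = n_a + n_b
    theta = rng.normal(theta_shift, 1.0, n)
    X = np.full((n, k), np.nan)
    for v in range(n):
        items = form_a if v < n_a else form_b
        p = 1 / (1 + np.exp(-(theta[v] - difficulties[items])))
        X[v, items] = (rng.random(items.size) < p).astype(float)
    return ResponseMatrix.from_array(X)


class TestRecoveryAndInvariance:
    def test_difficulty_recovery_anchored_forms(self):
        true = reference_difficulties(column="rasch").to_numpy()
        true = true - true.mean()
        rm = simulate_two_forms(true, seed=7)
        fit = fit_rasch_cml(rm)
        idx = [int(i[1:]) - 1 for i in fit.difficulties.index]
        r = np.corrcoef(fit.difficulties.to_numpy(), true[idx])[0, 1]
        assert r > 0.95

    def test_estimates_invariant_to_ability_shift(self):
        true = np.linspace(-1.5, 1.5, 20)
        f0 = fit_rasch_cml(simulate_two_forms(true, seed=3, theta_shift=0.0))
        f1 = fit_rasch_cml(simulate_two_forms(true, seed=3, theta_shift=1.0))
        common = f0.difficulties.index.intersection(f1.difficulties.index)
        # shifted abilities change the data, not the target; agreement within MC error
        diff = (f0.difficulties[common] - f1.difficulties[common]).abs()
        assert diff.mean() < 0.25

    def test_person_reordering_leaves_estimates_unchanged(self, study_responses):
        fit = fit_rasch_cml(study_responses)
        shuffled = ResponseMatrix(study_responses.scores.sample(frac=1, random_state=1))
        fit2 = fit_rasch_cml(shuffled)
        assert np.allclose(fit.difficulties.to_numpy(),
                           fit2.difficulties.to_numpy(), atol=1e-6)

    def test_concurrent_equals_single_form_for_identical_forms(self):
        true = np.linspace(-1, 1, 8)
        rng = np.random.default_rng(9)
        theta = rng.normal(0, 1, 300)
        p = 1 / (1 + np.exp(-(theta[:, None] - true[None, :])))
        X = (rng.random(p.shape) < p).astype(float)
        whole = fit_rasch_cml(ResponseMatrix.from_array(X))
        # same data presented as two "forms" with all items shared
        again = fit_rasch_cml(ResponseMatrix.from_array(X.copy()))
        assert np.allclose(whole.difficulties, again.difficulties, atol=1e-10)

    def test_no_variance_item_excluded(self):
        X = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 1], [1, 0, 0]], float)
        with pytest.warns(UserWarning, match="excluding"):
            fit = fit_rasch_cml(ResponseMatrix.from_array(X))
        assert fit.excluded_items == ["i1"]
        assert len(fit.difficulties) == 2


class TestPersons:
    def test_half_score_on_symmetric_test_gives_zero(self):
        X = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], float)
        rm = ResponseMatrix.from_array(X)
        fit = fit_rasch_cml(rm)
        pe = estimate_persons(fit, rm)
        assert np.allclose(pe.theta.to_numpy(), 0.0, atol=1e-8)

    def test_theta_increases_with_raw_score_and_matches_grid(self, study_responses):
        fit = fit_rasch_cml(study_responses)
        pe = estimate_persons(fit, study_responses)
        raw = study_responses.scores.sum(axis=1)[pe.theta.index]
        by_score = pe.theta.groupby(raw).mean()
        assert by_score.is_monotonic_increasing
        # one-dimensional grid oracle for a single person
        pid = pe.theta.index[0]
        d = fit.difficulties.to_numpy()
        x = study_responses.scores.loc[pid, fit.difficulties.index].to_numpy()

        def ll(t):
            return float((x * (t - d) - np.logaddexp(0, t - d)).sum())

        grid = np.arange(-6, 6, 0.0005)
        t_star = grid[np.argmax([ll(t) for t in grid])]
        assert abs(pe.theta[pid] - t_star) < 1e-3

    def test_extreme_scores_excluded(self):
        X = np.array([[1, 1, 1], [0, 0, 0], [1, 0, 1], [0, 1, 0]], float)
        rm = ResponseMatrix.from_array(X)
        fit = fit_rasch_cml(rm)
        pe = estimate_persons(fit, rm)
        assert set(pe.excluded_persons) == {"p1", "p2"}


class TestFitStatistics:
    def test_andersen_df_and_near_zero_on_duplicated_groups(self):
        true = np.linspace(-1.5, 1.5, 49)
        rm = simulate_two_forms(true, n_a=300, n_b=300, seed=21)
        res = andersen_lr_test(rm)
        assert res["df"] == 48
        assert res["statistic"] >= 0
        # identical duplicated subgroups give the pooled solution twice
        base = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 1]], float)
        both = np.vstack([base, base])
        r2 = ResponseMatrix.from_array(both)
        groups = [r2.person_ids[:4], r2.person_ids[4:]]
        lr = andersen_lr_test(r2, split=groups)
        assert lr["statistic"] < 1e-6

    def test_wald_flags_planted_dif_item(self):
        rng = np.random.default_rng(17)
        true = np.linspace(-1, 1, 10)
        n = 1000
        theta = rng.normal(0, 1, n)
        X = np.zeros((n, 10))
        for v in range(n):
            d = true.copy()
            # difficulty of item 0 differs by 1.5 logits between score groups;
            # induce DIF against the raw-score split via an ability-linked shift
            if theta[v] > 0:
                d[0] += 1.5
            p = 1 / (1 + np.exp(-(theta[v] - d)))
            X[v] = (rng.random(10) < p).astype(float)
        w = wald_item_tests(ResponseMatrix.from_array(X))
        assert bool(w.loc["i1", "flagged"])

    def test_wald_zero_for_identical_subsamples(self):
        base = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 1]], float)
        both = np.vstack([base, base])
        rm = ResponseMatrix.from_array(both)
        w = wald_item_tests(rm, split=[rm.person_ids[:4], rm.person_ids[4:]])
        assert np.abs(w["z"]).max() < 1e-5


class TestInformationAndReliability:
    def test_single_item_peak(self):
        ti = information_curve([0.7], theta_grid=np.arange(-4, 4, 0.001))
        assert ti.max_info == pytest.approx(0.25, abs=1e-6)
        assert ti.argmax_theta == pytest.approx(0.7, abs=2e-3)

    def test_symmetric_pair_peaks_at_zero(self):
        ti = information_curve([-1.0, 1.0])
        assert ti.argmax_theta == pytest.approx(0.0, abs=0.02)

    def test_form_b_information_from_reference_calibration(self):
        deltas = reference_difficulties(form="B")
        assert len(deltas) == 34
        ti = information_curve(deltas)
        assert ti.max_info == pytest.approx(5.91, abs=0.12)
        assert ti.argmax_theta == pytest.approx(-0.2, abs=0.05)

    def test_empty_item_set_errors(self):
        with pytest.raises(ValueError):
            information_curve([])

    def test_reliability_bounds_and_monotonicity(self, study_responses):
        fit = fit_rasch_cml(study_responses)
        pe_long = estimate_persons(fit, study_responses)
        rel_long = person_separation_reliability(pe_long)
        short = ResponseMatrix(study_responses.scores.iloc[:, :10])
        fit_s = fit_rasch_cml(short)
        pe_short = estimate_persons(fit_s, short)
        rel_short = person_separation_reliability(pe_short)
        assert 0 <= rel_short < rel_long <= 1

    def test_zero_se_gives_unit_reliability(self):
        from ansig.rasch import PersonEstimates
        pe = PersonEstimates(theta=pd.Series([-1.0, 0.0, 1.0]),
                             se=pd.Series([0.0, 0.0, 0.0]),
                             excluded_persons=[])
        assert person_separation_reliability(pe) == pytest.approx(1.0)
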