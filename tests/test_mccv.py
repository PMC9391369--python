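"""The MCCV prediction engine: splits, scaling, penalty selection, intervals,
permutation significance and the three-criterion rule."""

import numpy as np
import pytest

from protsurv.mccv import (
    MCCVConfig,
    PredictionScheme,
    MarkerResult,
    MCCVMarkerEvaluator,
    mccv_split,
    scale_split,
    select_penalty,
    run_marker_mccv,
    run_permutation_null,
    bootstrap_intervals,
    marker_significance,
    apply_significance_rule,
    evaluate_marker,
)


def _fast_config(**kw):
    base = dict(n_repeats=25, n_permutation_repeats=15, n_boot=50,
                master_seed=5, bonferroni_m=10)
    base.update(kw)
    return MCCVConfig(**base)


class TestSplit:
    def test_sizes_88_patients(self, rng):
        y = np.array([0] * 22 + [1] * 66)
        tr, va = mccv_split(88, y, 0.85, rng)
        assert len(va) == 14 and len(tr) == 74
        assert sorted(np.concatenate([tr, va]).tolist()) == list(range(88))

    def test_stratified_both_classes(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        for _ in range(20):
            tr, va = mccv_split(20, y, 0.85, rng)
            assert {0, 1} <= set(y[va]) and {0, 1} <= set(y[tr])

    def test_deterministic_given_seed(self):
        y = np.array([0] * 22 + [1] * 66)
        a = mccv_split(88, y, 0.85, np.random.default_rng(9))
        b = mccv_split(88, y, 0.85, np.random.default_rng(9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_impossible_split_errors(self, rng):
        with pytest.raises(ValueError):
            mccv_split(4, np.array([1, 1, 1, 1]), 0.85, rng)
        with pytest.raises(ValueError):
            mccv_split(4, np.array([0, 1, 1, 1]), 0.85, rng)  # one 0 only


class TestScaling:
    def test_minmax_example(self):
        tr, va = scale_split(np.array([[2.0], [4.0], [6.0]]),
                             np.array([[1.0], [3.0]]))
        assert tr.ravel().tolist() == [0.0, 0.5, 1.0]
        assert va.ravel().tolist() == [0.0, 1.0]  # own statistics, no transfer

    def test_constant_feature_maps_to_zero(self):
        tr, _ = scale_split(np.array([[5.0], [5.0], [5.0]]),
                            np.array([[5.0]]), method="minmax")
        assert np.all(tr == 0.0)
        tr, _ = scale_split(np.array([[5.0], [5.0]]), np.array([[5.0]]),
                            method="zscore")
        assert np.all(tr == 0.0)

    def test_zscore_population_sd(self):
        tr, _ = scale_split(np.array([[2.0], [4.0], [6.0]]),
                            np.array([[0.0]]), method="zscore")
        assert np.allclose(tr.ravel(), [-1.224744871, 0.0, 1.224744871])


class TestPenaltySelection:
    def test_single_grid_value(self, rng):
        X = rng.normal(size=(40, 1))
        y = rng.integers(0, 2, 40)
        y[:5] = 1
        y[-5:] = 0
        cfg = _fast_config(penalty_grid=(3.7,))
        assert select_penalty(X, y.astype(float), cfg, rng) == 3.7

    def test_separable_marker_reaches_perfect_inner_auroc(self, rng):
        from protsurv._solver import fit_l1_logistic, predict_proba, auroc

        y = np.array([0] * 20 + [1] * 20, dtype=float)
        X = (y * 2 - 1).reshape(-1, 1) + rng.normal(0, 0.05, size=(40, 1))
        cfg = _fast_config()
        c = select_penalty(X, y, cfg, rng)
        w, b = fit_l1_logistic(X, y, c)
        assert auroc(predict_proba(X, w, b), y) == 1.0

    def test_noise_marker_inner_auroc_near_half(self, rng):
        """Chance-level markers do not manufacture inner-fold skill."""
        from protsurv._solver import fit_l1_logistic, predict_proba, auroc

        scores = []
        for _ in range(30):
            y = rng.permutation(np.array([0.0] * 20 + [1.0] * 40))
            X = rng.normal(size=(60, 1))
            c = select_penalty(X, y, _fast_config(), rng)
            w, b = fit_l1_logistic(X, y, c)
            scores.append(auroc(predict_proba(X, w, b), y))
        assert abs(np.mean(scores) - 0.5) < 0.12


class TestMarkerRun:
    def test_perfect_marker(self):
        y = np.array([0] * 25 + [1] * 63)
        marker = y.astype(float)
        run = run_marker_mccv(marker, None, y, _fast_config(), "perfect")
        from protsurv._solver import auroc

        assert auroc(run["probabilities"], run["labels"]) > 0.99

    def test_beta_count_matches_repeats(self):
        y = np.array([0] * 25 + [1] * 63)
        rng = np.random.default_rng(0)
        run = run_marker_mccv(rng.normal(size=88), None, y,
                              _fast_config(n_repeats=12), "m")
        assert len(run["betas"]) == 12
        assert len(run["repeat_aurocs"]) == 12

    def test_noise_marker_interval_covers_half(self):
        """Pure-noise markers: the permutation AUROC interval straddles 0.5."""
        y = np.array([0] * 22 + [1] * 66)
        rng = np.random.default_rng(3)
        null = run_permutation_null(rng.normal(size=88), None, y,
                                    _fast_config(n_permutation_repeats=60), "m")
        lo, hi = np.percentile(null["aurocs"], [2.5, 97.5])
        assert lo <= 0.5 <= hi
        assert abs(null["aurocs"].mean() - 0.5) < 0.06

    def test_permutation_deterministic(self):
        y = np.array([0] * 22 + [1] * 66)
        x = np.random.default_rng(1).normal(size=88)
        a = run_permutation_null(x, None, y, _fast_config(), "m")
        b = run_permutation_null(x, None, y, _fast_config(), "m")
        assert np.array_equal(a["betas"], b["betas"])

    def test_label_flip_antisymmetry(self):
        """For a fixed split and penalty, flipping labels mirrors the
        validation AUROC around 0.5 and negates the fitted marker beta."""
        from protsurv._solver import auroc, fit_l1_logistic, predict_proba

        y = np.array([0] * 30 + [1] * 58)
        rng = np.random.default_rng(2)
        x = rng.normal(size=88) + 0.8 * y
        tr, va = mccv_split(88, y, 0.85, np.random.default_rng(7))
        X = x.reshape(-1, 1)
        X_tr, X_va = scale_split(X[tr], X[va])
        w, b = fit_l1_logistic(X_tr, y[tr].astype(float), 1.0)
        wf, bf = fit_l1_logistic(X_tr, 1.0 - y[tr], 1.0)
        a = auroc(predict_proba(X_va, w, b), y[va])
        # the flipped model's scores rank the original positives lowest
        a_flip = auroc(predict_proba(X_va, wf, bf), y[va])
        assert a_flip == pytest.approx(1.0 - a, abs=1e-6)
        assert np.allclose(w, -wf, atol=1e-4)


class TestBootstrap:
    def test_degenerate_perfect_predictions(self, rng):
        probs = np.array([0.0] * 10 + [1.0] * 10)
        labels = probs.copy()
        out = bootstrap_intervals(probs, labels, betas=[1.0, 2.0], n_boot=50,
                                  rng=rng)
        assert (out["auroc_q2_5"], out["auroc_median"], out["auroc_q97_5"]) \
            == (1.0, 1.0, 1.0)

    def test_beta_percentiles_are_direct(self, rng):
        betas = np.arange(101, dtype=float)
        probs = np.array([0.2, 0.8] * 20)
        labels = np.array([0, 1] * 20)
        out = bootstrap_intervals(probs, labels, betas, 20, rng)
        assert out["beta_q2_5"] == pytest.approx(np.percentile(betas, 2.5))
        assert out["beta_median"] == pytest.approx(50.0)
        assert out["beta_q97_5"] == pytest.approx(np.percentile(betas, 97.5))

    def test_interval_shrinks_with_pooled_n(self, rng):
        widths = []
        for n in (100, 1000):
            probs = np.clip(rng.normal(0.5, 0.2, n), 0, 1)
            labels = (rng.random(n) < probs).astype(float)
            out = bootstrap_intervals(probs, labels, [0.0, 1.0], 200, rng)
            widths.append(out["auroc_q97_5"] - out["auroc_q2_5"])
        assert widths[1] < widths[0]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_intervals([0.1, 0.9], [1, 1], [0.0], 10, rng)


class TestSignificance:
    def test_identical_samples(self):
        x = np.arange(50, dtype=float)
        p_raw, p_adj = marker_significance(x, x.copy(), 218)
        assert p_raw == pytest.approx(1.0)
        assert p_adj == 1.0

    def test_disjoint_supports(self):
        a = np.linspace(0, 1, 200)
        b = np.linspace(5, 6, 200)
        p_raw, _ = marker_significance(a, b, 1)
        assert p_raw < 1e-10

    def test_bonferroni_arithmetic(self):
        # m = 181 proteins + 37 binarized clinical characteristics
        assert min(1.0, 0.0001 * 218) == pytest.approx(0.0218)
        a = np.linspace(0, 1, 200)
        b = np.linspace(5, 6, 200)
        raw, adj = marker_significance(a, b, 218)
        assert adj == pytest.approx(min(1.0, raw * 218))


def _result(**kw):
    base = dict(marker="m", auroc_q2_5=0.6, auroc_median=0.65,
                auroc_q97_5=0.7, beta_q2_5=1.0, beta_median=2.0,
                beta_q97_5=3.0, perm_beta_q2_5=-1.0, perm_beta_q97_5=1.0,
                p_raw=0.001, p_adjusted=0.02)
    base.update(kw)
    return MarkerResult(**base)


class TestSignificanceRule:
    def test_reported_marker_profile_is_significant(self):
        """Interval pattern of a strongly predictive coagulation factor:
        AUROC 0.658 [0.634, 0.685], beta 2.188 [1.261, 3.443]."""
        r = _result(auroc_q2_5=0.634, auroc_median=0.658, auroc_q97_5=0.685,
                    beta_q2_5=1.261, beta_median=2.188, beta_q97_5=3.443)
        assert apply_significance_rule(r) is True

    def test_beta_interval_containing_zero_fails(self):
        r = _result(beta_q2_5=-0.2, beta_median=0.1, beta_q97_5=0.4)
        assert apply_significance_rule(r) is False

    def test_low_auroc_fails(self):
        r = _result(auroc_q2_5=0.40, auroc_median=0.45, auroc_q97_5=0.49)
        assert apply_significance_rule(r) is False

    def test_permutation_interval_excluding_zero_fails(self):
        r = _result(perm_beta_q2_5=0.5, perm_beta_q97_5=1.5)
        assert apply_significance_rule(r) is False


class TestSchemes:
    def test_one_year_labelling(self):
        scheme = PredictionScheme(outcome="one_year_survival")
        survived = np.array([1, 0, 0, 1])
        followup = np.array([5.0, 0.4, 3.0, 0.2])
        # only deaths within one year count as events; early censoring without
        # death is labelled survived
        assert scheme.labels(survived, followup).tolist() == [1, 0, 1, 1]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            PredictionScheme(outcome="five_year")
        with pytest.raises(ValueError):
            PredictionScheme(covariates=("weather",))


class TestEstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = MCCVMarkerEvaluator(n_repeats=5, n_permutation_repeats=5)
        params = est.get_params()
        assert params["n_repeats"] == 5
        est2 = clone(est).set_params(n_repeats=7)
        assert est2.get_params()["n_repeats"] == 7

    def test_fit_produces_results(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        y = np.array([0] * 25 + [1] * 63)
        X = pd.DataFrame({"signal": y + rng.normal(0, 0.3, 88),
                          "noise": rng.normal(size=88)})
        est = MCCVMarkerEvaluator(n_repeats=15, n_permutation_repeats=10,
                                  random_state=1).fit(X, y)
        assert est.marker_names_ == ["signal", "noise"]
        frame = est.results_frame()
        assert frame.shape[0] == 2
        sig_row = frame.set_index("marker").loc["signal"]
        noise_row = frame.set_index("marker").loc["noise"]
        assert sig_row["auroc_median"] > noise_row["auroc_median"]
        assert est.config_.bonferroni_m == 2


def test_evaluate_marker_covariate_adjustment(patient_data):
    """Adding a genuinely predictive covariate (PGD) does not destroy a true
    marker's performance."""
    cfg = _fast_config(n_repeats=40, n_permutation_repeats=20)
    x = patient_data["matrix"].values.loc["P001"].to_numpy()
    y = patient_data["labels"]
    base = evaluate_marker(x, patient_data["site_covariates"], y, cfg, "P001")
    pgd = patient_data["clinical"]["pgd"].to_numpy(dtype=float).reshape(-1, 1)
    cov = np.hstack([patient_data["site_covariates"], pgd])
    adj = evaluate_marker(x, cov, y, cfg, "P001")
    assert adj.auroc_median > base.auroc_median - 0.1
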