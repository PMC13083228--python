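"""Clock ensembles, stable clocks, age-gap correction, and classifiers."""

import numpy as np
import pandas as pd
import pytest

import ecmclock as ec
from ecmclock._stats import welch_t_test
from ecmclock.clocks import SEX_FEATURE, ClockModel

from conftest import make_cohort


class TestClockModel:
    def test_serialization_roundtrip(self, tmp_path):
        model = ClockModel(["P0", "P1"], [0.5, -0.2], 40.0, [3.0, 4.0], [1.0, 2.0],
                           "L2", 0.1)
        path = tmp_path / "clock.json"
        model.save(path)
        back = ClockModel.load(path)
        assert back.feature_ids == model.feature_ids
        assert np.allclose(back.coefficients, model.coefficients)
        assert back.lam == model.lam

    def test_missing_feature_listed(self):
        model = ClockModel(["P0", "MISSING"], [0.5, 0.2], 40.0, [3, 3], [1, 1], "L2", 0.1)
        ab = pd.DataFrame({"P0": [8.0, 9.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="MISSING"):
            model.predict(ab)

    def test_train_scaling_is_leakage_free(self):
        """A sample's prediction is unchanged by other test samples."""
        model = ClockModel(["P0", "P1"], [1.0, 1.0], 50.0, [3.0, 3.0], [1.0, 1.0],
                           "L2", 0.1)
        ab = pd.DataFrame({"P0": [8.0, 64.0], "P1": [16.0, 32.0]}, index=["a", "b"])
        both = model.predict(ab, scaling="train")
        alone = model.predict(ab.iloc[:1], scaling="train")
        assert both[0] == pytest.approx(alone[0])

    def test_self_scaling_differs_unless_stats_match(self):
        model = ClockModel(["P0"], [2.0], 50.0, [3.0], [1.0], "L2", 0.1)
        # cohort whose log2 statistics equal the training stats
        ab_same = pd.DataFrame({"P0": [4.0, 16.0]})  # log2 = [2, 4]: mean 3, sd 1
        assert np.allclose(model.predict(ab_same, scaling="self"),
                           model.predict(ab_same, scaling="train"))
        ab_diff = pd.DataFrame({"P0": [4.0, 64.0]})
        assert not np.allclose(model.predict(ab_diff, scaling="self"),
                               model.predict(ab_diff, scaling="train"))


class TestStableClock:
    def test_single_protein_matches_closed_form_ridge(self):
        """n=5 design: coefficient equals (X'X + λI)^-1 X'y on centered data."""
        ages = np.array([20.0, 35.0, 50.0, 65.0, 80.0])
        ab = np.exp2(np.linspace(3, 5, 5) + 0.1 * np.array([1, -1, 0, 1, -1]))
        cohort = make_cohort(ab[:, None], ages)
        lam = 2.5
        est = ec.StableClock(proteins=["P0"], alphas=[lam], random_state=0)
        est.fit(cohort.abundance, ages)
        L = np.log2(ab)
        x = (L - L.mean()) / L.std(ddof=0)
        xc = x - x.mean()
        yc = ages - ages.mean()
        beta = (xc @ yc) / (xc @ xc + lam)
        assert est.coef_[0] == pytest.approx(beta, rel=1e-9)

    def test_tiny_lambda_matches_ols(self):
        rng = np.random.default_rng(1)
        n = 30
        ages = rng.uniform(20, 80, n)
        L = np.column_stack([0.05 * ages + rng.normal(0, 0.2, n),
                             rng.normal(4, 1, n)])
        cohort = make_cohort(np.exp2(L), ages)
        est = ec.StableClock(proteins=["P0", "P1"], alphas=[1e-8], random_state=0)
        est.fit(cohort.abundance, ages)
        X = (L - L.mean(0)) / L.std(0, ddof=0)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), ages, rcond=None)[0]
        assert np.allclose(est.coef_, ols[1:], atol=1e-6)

    def test_refit_identical(self, clock_setup):
        _, ann, cohort, truth = clock_setup
        proteins = list(truth.index[truth["is_aging"]])
        a = ec.fit_stable_clock(cohort, proteins, seed=3)
        b = ec.fit_stable_clock(cohort, proteins, seed=3)
        assert np.allclose(a.coefficients, b.coefficients)
        assert a.lam == b.lam

    def test_sex_excluded_by_default(self, clock_setup):
        _, ann, cohort, truth = clock_setup
        model = ec.fit_stable_clock(cohort, list(truth.index[truth["is_aging"]]))
        assert SEX_FEATURE not in model.feature_ids

    def test_predict_age_consistency(self, clock_setup):
        _, ann, cohort, truth = clock_setup
        proteins = list(truth.index[truth["is_aging"]])
        est = ec.StableClock(proteins=proteins, random_state=0)
        est.fit(cohort.abundance, cohort.ages.to_numpy())
        pred = ec.predict_age(est.model_, cohort)
        r = np.corrcoef(pred, cohort.ages)[0, 1]
        assert r == pytest.approx(est.in_sample_r_, abs=1e-12)
        assert r > 0.95


class TestEnsemble:
    def test_same_seed_identical(self, clock_setup):
        _, ann, cohort, _ = clock_setup
        sub = cohort.subset(protein_ids=cohort.protein_ids[:80])
        a = ec.run_clock_ensemble(sub, ann, mode="ecm", n_permutations=4,
                                  train_size=60, seed=5)
        b = ec.run_clock_ensemble(sub, ann, mode="ecm", n_permutations=4,
                                  train_size=60, seed=5)
        assert np.allclose(a.test_r_, b.test_r_)
        assert all(pa.selected == pb.selected
                   for pa, pb in zip(a.permutations_, b.permutations_))

    def test_ecm_mode_restricted_to_matrisome(self, clock_setup):
        _, ann, cohort, _ = clock_setup
        sub = cohort.subset(protein_ids=cohort.protein_ids[:200])
        ens = ec.run_clock_ensemble(sub, ann, mode="ecm", n_permutations=3,
                                    train_size=60, seed=1)
        matrisome = set(ec.matrisome_ids(ann))
        for perm in ens.permutations_:
            assert set(perm.selected) <= matrisome
            assert set(perm.model.protein_ids) <= matrisome

    def test_random_clock_sizes_match(self, clock_setup):
        _, ann, cohort, _ = clock_setup
        sub = cohort.subset(protein_ids=cohort.protein_ids[:150])
        ens = ec.run_clock_ensemble(sub, ann, mode="ecm", n_permutations=4,
                                    train_size=60, seed=2)
        rnd = ec.run_random_clocks(sub, ens, seed=3)
        assert rnd.mode == "random"
        for pe, pr in zip(ens.permutations_, rnd.permutations_):
            if len(pe.selected):
                assert len(pr.selected) == len(pe.selected)
                assert pr.train_sample_ids == pe.train_sample_ids
                assert pr.model.penalty == "L2"

    def test_train_size_validation(self, clock_setup):
        _, ann, cohort, _ = clock_setup
        with pytest.raises(ValueError, match="train_size"):
            ec.run_clock_ensemble(cohort, ann, n_permutations=1,
                                  train_size=cohort.n_samples, seed=0)


class TestStabilitySelection:
    def test_strict_threshold_rule(self):
        ens = ec.PermutationClockEnsemble(mode="ecm", n_permutations=10)
        ens.selection_frequency_ = pd.Series({"P1": 0.6, "P2": 0.5, "P3": 0.4})
        assert set(ec.stability_selection(ens).proteins) == {"P1"}

    def test_zero_threshold_returns_ever_selected(self):
        ens = ec.PermutationClockEnsemble(mode="ecm", n_permutations=10)
        ens.selection_frequency_ = pd.Series({"P1": 0.6, "P2": 0.1, "P3": 0.0})
        assert set(ec.stability_selection(ens, threshold=0.0).proteins) == {"P1", "P2"}


class TestAgeGapCorrection:
    def test_affine_prediction_zero_gaps(self):
        ages = np.linspace(20, 80, 10)
        result = ec.correct_age_gap(0.5 * ages + 20.0, ages)
        assert result.correction_intercept == pytest.approx(20.0)
        assert result.correction_slope == pytest.approx(0.5)
        assert np.allclose(result.unbiased_gap, 0.0, atol=1e-9)

    def test_identity_prediction_unchanged(self):
        ages = np.linspace(20, 80, 10)
        result = ec.correct_age_gap(ages.copy(), ages)
        assert np.allclose(result.samples["unbiased_prediction"], ages)

    def test_post_correction_regression_is_identity(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 80, 100)
        pred = 0.7 * ages + 12 + rng.normal(0, 5, 100)
        result = ec.correct_age_gap(pred, ages)
        slope, intercept = np.polyfit(ages, result.samples["unbiased_prediction"], 1)
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert intercept == pytest.approx(0.0, abs=1e-7)

    def test_flat_clock_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            ec.correct_age_gap(np.full(10, 50.0), np.linspace(20, 80, 10))

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ec.correct_age_gap(np.linspace(20, 80, 10), np.full(10, 50.0))


class TestLoocvAuc:
    def test_perfect_separation(self):
        x = pd.DataFrame({"f": np.r_[np.zeros(6), np.ones(6)]})
        auc, probs = ec.loocv_auc(x, np.r_[np.zeros(6), np.ones(6)].astype(int),
                                  random_state=0)
        assert auc == 1.0

    def test_auc_equals_rank_statistic(self):
        """AUC of pooled probabilities equals the Mann–Whitney identity."""
        rng = np.random.default_rng(3)
        x = pd.DataFrame({"f": rng.normal(0, 1, 20) + np.r_[np.zeros(10), np.ones(10)]})
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        auc, probs = ec.loocv_auc(x, y, random_state=0)
        pos, neg = probs[y == 1].to_numpy(), probs[y == 0].to_numpy()
        mw = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert auc == pytest.approx(mw)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ec.loocv_auc(pd.DataFrame({"f": [1.0, 2.0]}), [1, 1])


class TestCompareAgeGaps:
    def test_welch_hand_computation(self):
        """x=[1,2,3] vs y=[4,5,6]: t = -3/sqrt(2/3), df = 4."""
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert df == pytest.approx(4.0)

    def test_group_table(self):
        rng = np.random.default_rng(4)
        gaps = pd.Series(np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 30)],
                         index=[f"s{i}" for i in range(60)])
        groups = pd.Series(["ctrl"] * 30 + ["case"] * 30, index=gaps.index)
        out = ec.compare_age_gaps(gaps, groups, reference="ctrl")
        assert out.loc["case", "p_value"] < 1e-6
        out_w = ec.compare_age_gaps(gaps, groups, reference="ctrl", test="wilcoxon")
        assert out_w.loc["case", "p_value"] < 1e-6

    def test_power_against_shifted_normal(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(50):
            x, y = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
            _, _, p = welch_t_test(x, y)
            rejections += p < 0.05
        assert rejections == 50  # d=2 at n=30: essentially always rejected
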