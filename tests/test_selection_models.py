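"""Fisher ranking, split protocol, feature-count selection and the RF/SVM
evaluation contract (isolation, determinism, null calibration)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import drowseeg as dg
from drowseeg.models import EvaluationResult, select_feature_count

from conftest import gaussian_table


class TestFisherScore:
    def test_uninformative_feature_scores_zero(self):
        frame = pd.DataFrame({"same": np.tile([1.0, 2.0, 3.0], 4)})
        labels = np.repeat([0, 1], 6)
        ranking = dg.fisher_score(dg.FeatureTable(frame, labels))
        assert ranking.loc[0, "score"] == pytest.approx(0.0, abs=1e-12)

    def test_separating_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 30)
        frame = pd.DataFrame(
            {
                "noise1": rng.standard_normal(60),
                "sep": labels * 10.0 + 0.01 * rng.standard_normal(60),
                "noise2": rng.standard_normal(60),
            }
        )
        ranking = dg.fisher_score(dg.FeatureTable(frame, labels))
        assert ranking.loc[0, "feature"] == "sep"

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        table = gaussian_table(40, 3, 1.5, seed=1)
        scores = dg.fisher_score(table)["score"].to_numpy()
        shifted = dg.FeatureTable(a * table.features + b, table.labels)
        scores2 = dg.fisher_score(shifted)["score"].to_numpy()
        np.testing.assert_allclose(scores2, scores, rtol=1e-6)

    def test_zero_within_class_variance_warns_and_ranks_first(self):
        labels = np.repeat([0, 1], 5)
        frame = pd.DataFrame(
            {
                "soft": np.random.default_rng(1).standard_normal(10),
                "hard": labels.astype(float),  # constant within each class
            }
        )
        with pytest.warns(UserWarning, match="zero within-class"):
            ranking = dg.fisher_score(dg.FeatureTable(frame, labels))
        assert ranking.loc[0, "feature"] == "hard"
        assert np.isinf(ranking.loc[0, "score"])

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"f": np.arange(10.0)})
        with pytest.raises(ValueError):
            dg.fisher_score(dg.FeatureTable(frame, np.zeros(10, dtype=int)))


class TestSplitPlan:
    def test_balanced_arithmetic(self):
        table = gaussian_table(300, 4, 0.0, seed=2)
        plan = dg.make_split(table, seed=0)
        assert plan.optimization_idx.size == 200
        assert plan.test_idx.size == 100
        assert plan.n_folds == 5
        for _, val in plan.folds:
            assert val.size == 40
        combined = np.sort(np.concatenate([plan.optimization_idx, plan.test_idx]))
        np.testing.assert_array_equal(combined, np.arange(300))

    def test_stratification(self):
        table = gaussian_table(300, 2, 0.0, seed=3)
        plan = dg.make_split(table, seed=1)
        y = table.labels
        assert abs(y[plan.test_idx].mean() - y.mean()) < 0.02

    def test_deterministic_under_seed(self):
        table = gaussian_table(90, 3, 0.0, seed=4)
        p1 = dg.make_split(table, seed=7)
        p2 = dg.make_split(table, seed=7)
        np.testing.assert_array_equal(p1.test_idx, p2.test_idx)
        for (a, _), (b, _) in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(a, b)
        p3 = dg.make_split(table, seed=8)
        assert not np.array_equal(p1.test_idx, p3.test_idx)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            dg.make_split(gaussian_table(10, 2, 0.0, seed=5), seed=0)

    def test_folds_within_optimization_set(self):
        table = gaussian_table(60, 2, 0.0, seed=6)
        plan = dg.make_split(table, seed=0)
        opt = set(plan.optimization_idx.tolist())
        for tr, va in plan.folds:
            assert set(tr.tolist()) | set(va.tolist()) <= opt
            assert not set(tr.tolist()) & set(va.tolist())


class TestFeatureCountSelection:
    def test_separating_prefix_found(self):
        """With one separating + 20 noise features, the selected prefix
        contains the separator and CV error is ~0 (several protocol seeds)."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            labels = np.repeat([0, 1], 45)
            rng.shuffle(labels)
            frame = pd.DataFrame(
                rng.standard_normal((90, 21)),
                columns=["sep"] + [f"n{i}" for i in range(20)],
            )
            frame["sep"] = labels * 6.0 + rng.standard_normal(90)
            table = dg.FeatureTable(frame, labels)
            plan = dg.make_split(table, seed)
            ranking = dg.fisher_score(table.subset(plan.optimization_idx))
            spec = dg.ModelSpec(family="rf", seed=seed)
            sel = select_feature_count(
                table, ranking, plan, spec, k_grid=[1, 2, 4, 8, 16, 21]
            )
            top = list(ranking["feature"].iloc[: sel.k_star])
            assert "sep" in top
            assert sel.cv_mse[sel.k_star] <= 0.05

    def test_all_noise_cv_error_near_half(self):
        table = gaussian_table(120, 8, 0.0, seed=8)
        plan = dg.make_split(table, seed=0)
        ranking = dg.fisher_score(table.subset(plan.optimization_idx))
        sel = select_feature_count(
            table, ranking, plan, dg.ModelSpec(family="rf", seed=0), k_grid=[2, 8]
        )
        # CV min over a small grid is optimistically biased; allow 3 sigma
        # around chance on 80 optimization rows
        assert abs(sel.cv_mse[sel.k_star] - 0.5) < 3 * np.sqrt(0.25 / 80) + 0.1

    def test_singleton_grid(self):
        table = gaussian_table(60, 4, 1.0, seed=9)
        plan = dg.make_split(table, seed=0)
        ranking = dg.fisher_score(table.subset(plan.optimization_idx))
        sel = select_feature_count(
            table, ranking, plan, dg.ModelSpec(family="svm", seed=0), k_grid=[3]
        )
        assert sel.k_star == 3

    def test_out_of_range_grid_rejected(self):
        table = gaussian_table(60, 4, 1.0, seed=9)
        plan = dg.make_split(table, seed=0)
        ranking = dg.fisher_score(table.subset(plan.optimization_idx))
        with pytest.raises(ValueError):
            select_feature_count(
                table, ranking, plan, dg.ModelSpec(family="rf", seed=0), k_grid=[9]
            )


class TestTrainAndTest:
    @pytest.mark.parametrize("family", ["rf", "svm"])
    def test_separated_classes_high_accuracy(self, family):
        """Class means 3 within-class sd apart: >= 95% test accuracy
        averaged over protocol seeds."""
        accs = []
        for seed in range(10):
            table = gaussian_table(150, 5, 3.0, seed=200 + seed, n_informative=5)
            res = dg.run_protocol(
                table, dg.ModelSpec(family=family, seed=seed), seed, k_grid=[1, 2, 5]
            )
            accs.append(res.accuracy_overall)
        assert np.mean(accs) >= 95.0

    def test_permuted_labels_chance_accuracy(self):
        rng = np.random.default_rng(31)
        correct = total = 0
        for seed in range(5):
            table = gaussian_table(120, 5, 3.0, seed=300 + seed)
            permuted = dg.FeatureTable(
                table.features, rng.permutation(table.labels)
            )
            res = dg.run_protocol(
                permuted, dg.ModelSpec(family="rf", seed=seed), seed, k_grid=[1, 5]
            )
            correct += res.confusion.trace()
            total += res.confusion.sum()
        acc = correct / total
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / total) + 0.05

    def test_single_class_training_rejected(self):
        table = gaussian_table(60, 3, 1.0, seed=10)
        plan = dg.make_split(table, seed=0)
        ranking = dg.fisher_score(table.subset(plan.optimization_idx))
        broken = dg.FeatureTable(table.features, np.zeros_like(table.labels) + 1)
        with pytest.raises(ValueError):
            dg.train_and_test(broken, ranking, 2, plan, dg.ModelSpec(family="rf"))

    def test_confusion_counts_sum_to_test_size(self):
        table = gaussian_table(90, 4, 2.0, seed=11)
        res = dg.run_protocol(table, dg.ModelSpec(family="svm", seed=0), 0, k_grid=[2])
        assert res.confusion.sum() == 30
        assert 0 <= res.accuracy_overall <= 100


class TestProtocolIntegrity:
    def test_test_set_isolation(self):
        """Perturbing test labels changes neither ranking, k*, nor the
        fitted model's predictions."""
        table = gaussian_table(120, 6, 1.5, seed=12)
        plan = dg.make_split(table, seed=3)
        spec = dg.ModelSpec(family="rf", seed=3)

        flipped_labels = table.labels.copy()
        flipped_labels[plan.test_idx] = 1 - flipped_labels[plan.test_idx]
        flipped = dg.FeatureTable(table.features, flipped_labels)

        r1 = dg.fisher_score(table.subset(plan.optimization_idx))
        r2 = dg.fisher_score(flipped.subset(plan.optimization_idx))
        pd.testing.assert_frame_equal(r1, r2)

        s1 = select_feature_count(table, r1, plan, spec, k_grid=[1, 3, 6])
        s2 = select_feature_count(flipped, r2, plan, spec, k_grid=[1, 3, 6])
        assert s1.k_star == s2.k_star

        res1 = dg.train_and_test(table, r1, s1.k_star, plan, spec)
        res2 = dg.train_and_test(flipped, r2, s2.k_star, plan, spec)
        # same predictions: flipping test labels flips the confusion rows
        np.testing.assert_array_equal(res1.confusion, res2.confusion[::-1])

    @pytest.mark.parametrize("family", ["rf", "svm"])
    def test_seed_exact_reproducibility(self, family):
        table = gaussian_table(90, 5, 1.0, seed=13)
        spec = dg.ModelSpec(family=family, seed=5)
        res1 = dg.run_protocol(table, spec, 5, k_grid=[1, 3, 5])
        res2 = dg.run_protocol(table, spec, 5, k_grid=[1, 3, 5])
        np.testing.assert_array_equal(res1.confusion, res2.confusion)
        assert res1.accuracy_overall == res2.accuracy_overall
        assert res1.n_features_selected == res2.n_features_selected


class TestDeltaAccuracy:
    def _result(self, acc, family="rf", sig=(1, 2)):
        return EvaluationResult(
            confusion=np.zeros((2, 2), dtype=int),
            accuracy_overall=acc,
            accuracy_per_class={"awake": acc, "drowsy": acc},
            n_features_selected=1,
            model_family=family,
            seed=0,
            plan_signature=sig,
        )

    def test_identical_results_zero(self):
        assert dg.delta_accuracy(self._result(90.0), self._result(90.0)) == 0.0

    def test_sign_convention(self):
        assert dg.delta_accuracy(self._result(95.0), self._result(90.0)) == -5.0

    def test_mismatched_plans_rejected(self):
        with pytest.raises(ValueError, match="plan"):
            dg.delta_accuracy(self._result(90.0, sig=(1,)), self._result(90.0, sig=(2,)))
        with pytest.raises(ValueError, match="famil"):
            dg.delta_accuracy(self._result(90.0, "rf"), self._result(90.0, "svm"))


class TestSVMTuning:
    def test_search_deterministic_and_within_ranges(self):
        table = gaussian_table(90, 4, 1.0, seed=14)
        plan = dg.make_split(table, seed=0)
        ranking = dg.fisher_score(table.subset(plan.optimization_idx))
        spec = dg.ModelSpec(family="svm", seed=2, search_budget=10)
        c1, g1 = dg.tune_svm(table, ranking, plan, spec)
        c2, g2 = dg.tune_svm(table, ranking, plan, spec)
        assert (c1, g1) == (c2, g2)
        assert 1e-2 <= c1 <= 1e3
        assert 1e-3 / 4 <= g1 <= 1e1 / 4

    def test_missing_values_rejected_upstream(self):
        frame = pd.DataFrame({"f": [1.0, np.nan, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            dg.FeatureTable(frame, np.array([0, 1, 0, 1]))
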