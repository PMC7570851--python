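"""Metrics, k-fold cross-validation and the comparison harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import etongue.evaluation as ev
from etongue.evaluation import (coeff_variation, compare_models, kfold_cv,
                                kfold_split, r_squared, rmse, rows_to_frame)
from etongue.ions import ION_ORDER


class TestRmse:
    def test_zero_for_identical_vectors(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_worked_example(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_single_pair_is_absolute_difference(self):
        assert rmse([10.0], [13.0]) == pytest.approx(3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance_and_nonnegativity(self, values):
        a = np.asarray(values)
        p = a + 1.5
        perm = np.random.default_rng(0).permutation(len(a))
        assert rmse(a, p) >= 0
        assert rmse(a[perm], p[perm]) == pytest.approx(rmse(a, p))


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_predictor_scores_zero(self):
        assert r_squared([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_hand_worked_example(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_zero_variance_actual_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            r_squared([2.0, 2.0], [1.0, 3.0])

    def test_never_exceeds_one_and_matches_pearson_for_affine_fits(self, rng):
        a = rng.normal(size=30)
        noisy = a + rng.normal(0, 0.5, 30)
        assert r_squared(a, noisy) <= 1.0
        # predictions that are the least-squares affine fit of the actuals:
        # R^2 collapses to the squared Pearson correlation
        slope, intercept = np.polyfit(a, noisy, 1)
        fitted = slope * a + intercept
        corr = np.corrcoef(a, noisy)[0, 1]
        assert r_squared(noisy, fitted) == pytest.approx(corr ** 2, abs=1e-10)


class TestCoeffVariation:
    def test_hand_worked_example(self):
        # per-sample SD 1 over grand mean 10 -> 10 %
        assert coeff_variation(np.array([[9.0, 10.0, 11.0]])) == \
            pytest.approx(10.0)

    def test_identical_replicates_give_zero(self):
        assert coeff_variation(np.array([[5.0, 5.0, 5.0]])) == 0.0

    def test_scale_invariance(self, rng):
        R = rng.uniform(1, 10, size=(6, 3))
        assert coeff_variation(3.7 * R) == pytest.approx(coeff_variation(R))

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            coeff_variation(np.array([[1.0], [2.0]]))

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(ValueError, match="zero grand mean"):
            coeff_variation(np.array([[1.0, -1.0]]))


class TestKfoldSplit:
    def test_leave_one_out_when_k_equals_n(self):
        folds = kfold_split(8, 8, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_balanced_disjoint_cover(self):
        folds = kfold_split(23, 10, seed=4)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        joined = np.concatenate(folds)
        assert sorted(joined) == list(range(23))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10, seed=0)


class TestKfoldCv:
    def test_perfect_oracle_scores_perfectly(self, small_dataset, monkeypatch):
        """A model that returns the true fold targets gets RMSE 0, R^2 1."""
        _, records = small_dataset
        truth = {r.sample_id: [r.targets[i] for i in ION_ORDER]
                 for r in records}
        order = sorted(records, key=lambda r: r.sample_id)
        folds = kfold_split(len(order), 3, seed=5)
        answers = iter([np.array([truth[order[i].sample_id] for i in f])
                        for f in folds])

        class Oracle:
            def fit(self, X, Y):
                return self

            def predict(self, X):
                return next(answers)

        monkeypatch.setattr(ev, "make_model",
                            lambda kind, seed=0, **kw: Oracle())
        rows = kfold_cv(records, "DKL", k=3, seed=5)
        for row in rows:
            assert row.rmse == pytest.approx(0.0, abs=1e-9)
            assert row.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_metrics_invariant_to_record_order(self, small_dataset):
        _, records = small_dataset
        kwargs = {"max_epochs": 10, "hidden": (6,)}
        a = kfold_cv(records, "ANN", k=3, seed=2, model_kwargs=kwargs)
        shuffled = list(records)
        np.random.default_rng(0).shuffle(shuffled)
        b = kfold_cv(shuffled, "ANN", k=3, seed=2, model_kwargs=kwargs)
        for ra, rb in zip(a, b):
            assert ra.rmse == rb.rmse
            assert ra.r_squared == rb.r_squared

    def test_too_many_folds_rejected(self, small_dataset):
        _, records = small_dataset
        with pytest.raises(ValueError):
            kfold_cv(records, "GP", k=100, seed=0)


class TestCompareModels:
    def test_report_shape_and_reproducibility(self, small_dataset):
        samples, records = small_dataset
        configs = {"ANN": {"max_epochs": 10, "hidden": (6,)},
                   "DKL": {"max_epochs": 10, "hidden": (6,), "n_features": 3}}

        def dataset_fn(seed):
            return records, None

        res1 = compare_models(dataset_fn, configs, seeds=[0], k=3)
        res2 = compare_models(dataset_fn, configs, seeds=[0], k=3)
        assert len(res1["per_seed"]) == len(ION_ORDER) * len(configs)
        assert len(res1["median"]) == len(ION_ORDER) * len(configs)
        pd.testing.assert_frame_equal(res1["per_seed"], res2["per_seed"])

    def test_model_failure_recorded_not_fatal(self, small_dataset):
        _, records = small_dataset
        configs = {"GP": {"init_length_scale": -1.0}}  # invalid -> error

        res = compare_models(lambda s: (records, None), configs, seeds=[0], k=3)
        assert res["per_seed"]["rmse_mgL"].isna().all()
        assert "error" in res["per_seed"].columns

    def test_replicate_cv_reported_with_array(self, small_dataset, noisy_array):
        _, records = small_dataset
        configs = {"ANN": {"max_epochs": 10, "hidden": (6,)}}
        res = compare_models(lambda s: (records, noisy_array), configs,
                             seeds=[1], k=3)
        cv = res["per_seed"]["cv_pct"]
        assert np.isfinite(cv).all() and (cv >= 0).all()

    def test_requires_at_least_one_seed(self, small_dataset):
        _, records = small_dataset
        with pytest.raises(ValueError):
            compare_models(lambda s: (records, None), {"GP": {}}, seeds=[])
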