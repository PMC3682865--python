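"""Dataset splitting, the evaluation metrics, and the per-class forest."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from shiftforge.model import (
    EvaluationResult,
    SuperClassRandomForest,
    UnknownBackendError,
    evaluate,
    load_models,
    pearson_corr,
    pooled_metrics,
    rmse,
    save_models,
    split_dataset,
    train_models,
)
from shiftforge.records import Dataset, TEST, TRAIN, AtomShiftRecord


def textbook_rmse(exp, pred):
    return math.sqrt(sum((e - p) ** 2 for e, p in zip(exp, pred))
                     / len(exp))


def textbook_corr(exp, pred):
    n = len(exp)
    me = sum(exp) / n
    mp = sum(pred) / n
    se = math.sqrt(sum((e - me) ** 2 for e in exp) / (n - 1))
    sp = math.sqrt(sum((p - mp) ** 2 for p in pred) / (n - 1))
    return sum(((e - me) / se) * ((p - mp) / sp)
               for e, p in zip(exp, pred)) / (n - 1)


class TestMetrics:
    def test_perfect_prediction(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert pearson_corr([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_evaluated_rmse(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(math.sqrt(25 / 2))

    def test_antisymmetry_of_corr(self):
        exp = [1.0, 2.5, 3.0, 0.5]
        assert pearson_corr(exp, [-x for x in exp]) == pytest.approx(-1.0)

    def test_matches_textbook_recomputation_on_random_vectors(self):
        """Direct recomputation from the metric definitions to 1e-12 on
        100 random small vectors, cross-checked against scipy."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            exp = rng.normal(size=n) * 10
            pred = exp + rng.normal(size=n)
            if np.std(exp, ddof=1) == 0 or np.std(pred, ddof=1) == 0:
                continue
            assert rmse(exp, pred) == pytest.approx(
                textbook_rmse(exp, pred), abs=1e-12)
            c = pearson_corr(exp, pred)
            assert c == pytest.approx(textbook_corr(exp, pred), abs=1e-12)
            assert c == pytest.approx(
                scipy.stats.pearsonr(exp, pred).statistic, abs=1e-10)

    def test_undefined_cases(self):
        assert pearson_corr([1.0], [1.0]) is None  # n < 2
        assert pearson_corr([1.0, 1.0], [0.0, 1.0]) is None  # zero var
        with pytest.raises(ValueError):
            rmse([], [])

    def test_evaluation_result_validates_ranges(self):
        with pytest.raises(ValueError):
            EvaluationResult("CA", 5, rmse=1.0, corr=1.5)
        with pytest.raises(ValueError):
            EvaluationResult("CA", 5, rmse=-1.0, corr=0.5)


def _records(n_structures, atoms_per_structure=10):
    recs = []
    for s in range(n_structures):
        for a in range(atoms_per_structure):
            recs.append(AtomShiftRecord(
                pdb_id=f"P{s:03d}", chain_index=1, residue_index=a + 1,
                residue_type="ALA", atom_name="CA",
                experimental_shift=52.5, features={"f": float(a)},
            ))
    return recs


class TestSplit:
    def test_60_40_on_ten_structures(self):
        ds = Dataset(records=_records(10))
        split_dataset(ds, 0.6, seed=0)
        train_ids = {r.pdb_id for r in ds.train_records}
        test_ids = {r.pdb_id for r in ds.test_records}
        assert len(train_ids) == 6 and len(test_ids) == 4
        assert len(ds.train_records) == 60 and len(ds.test_records) == 40

    def test_round_half_up_on_five_structures(self):
        ds = Dataset(records=_records(5))
        split_dataset(ds, 0.6, seed=1)
        assert len({r.pdb_id for r in ds.train_records}) == 3
        assert len({r.pdb_id for r in ds.test_records}) == 2

    def test_no_structure_straddles_the_split(self):
        ds = Dataset(records=_records(7))
        split_dataset(ds, 0.6, seed=2)
        assert not ({r.pdb_id for r in ds.train_records}
                    & {r.pdb_id for r in ds.test_records})

    def test_same_seed_reproduces_partition(self):
        a = Dataset(records=_records(9))
        b = Dataset(records=_records(9))
        split_dataset(a, 0.6, seed=5)
        split_dataset(b, 0.6, seed=5)
        assert a.partition == b.partition

    def test_new_seed_changes_membership_not_sizes(self):
        a = Dataset(records=_records(12))
        b = Dataset(records=_records(12))
        split_dataset(a, 0.6, seed=0)
        split_dataset(b, 0.6, seed=99)
        assert {r.pdb_id for r in a.train_records} != \
            {r.pdb_id for r in b.train_records}
        assert len(a.train_records) == len(b.train_records)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(Dataset(records=[]), 0.6, 0)

    def test_repartitioning_rejected(self):
        ds = Dataset(records=_records(4))
        split_dataset(ds, 0.6, seed=0)
        with pytest.raises(ValueError, match="already partitioned"):
            split_dataset(ds, 0.6, seed=0)


def synthetic_frame(n, seed=0, noise=0.0):
    """shift = 2*featA - featB (+ noise), single class."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "super_class": ["CA"] * n,
        "featA": rng.normal(size=n),
        "featB": rng.normal(size=n),
    })
    y = 2 * X["featA"].to_numpy() - X["featB"].to_numpy()
    if noise:
        y = y + rng.normal(0, noise, size=n)
    return X, y


class TestEstimator:
    def test_noiseless_linear_target_is_learned(self):
        X, y = synthetic_frame(2000, seed=3)
        est = SuperClassRandomForest(n_estimators=100, tune_mtry=False,
                                     random_state=0).fit(X, y)
        pred = est.predict(X)
        assert rmse(y, pred) < 0.1 * np.std(y)

    def test_small_class_skipped_with_warning(self, caplog):
        X, y = synthetic_frame(200, seed=4)
        X.loc[:9, "super_class"] = "CB"  # 10 rows < min_class_size
        est = SuperClassRandomForest(n_estimators=20, tune_mtry=False,
                                     random_state=0, min_class_size=50)
        with caplog.at_level("WARNING", logger="shiftforge"):
            est.fit(X, y)
        assert est.skipped_classes_ == ["CB"]
        assert "skipped" in caplog.text

    def test_unknown_backend_is_a_configuration_error(self):
        X, y = synthetic_frame(100)
        with pytest.raises(UnknownBackendError, match="no-such"):
            SuperClassRandomForest(backend="no-such").fit(X, y)

    def test_unfitted_predict_rejected(self):
        X, _ = synthetic_frame(10)
        with pytest.raises(ValueError, match="not fitted"):
            SuperClassRandomForest().predict(X)

    def test_sklearn_params_protocol(self):
        est = SuperClassRandomForest(n_estimators=7)
        assert est.get_params()["n_estimators"] == 7
        est.set_params(n_estimators=9)
        assert est.n_estimators == 9

    def test_missing_and_categorical_encoding_roundtrip(self):
        from shiftforge.records import MISSING

        rng = np.random.default_rng(8)
        n = 300
        cat = rng.choice(["a", "b"], size=n)
        num = rng.normal(size=n)
        num_vals = [MISSING if i % 7 == 0 else float(v)
                    for i, v in enumerate(num)]
        X = pd.DataFrame({"super_class": ["CA"] * n, "cat": cat,
                          "num": num_vals})
        y = np.where(cat == "a", 1.0, -1.0)
        est = SuperClassRandomForest(n_estimators=30, tune_mtry=False,
                                     random_state=0).fit(X, y)
        pred = est.predict(X)
        assert rmse(y, pred) < 0.1


class TestFeatureImportance:
    def test_single_driving_feature_ranks_first(self):
        rng = np.random.default_rng(5)
        n = 1500
        X = pd.DataFrame({
            "super_class": ["CA"] * n,
            "featA": rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        y = np.sin(X["featA"].to_numpy())
        est = SuperClassRandomForest(n_estimators=100, tune_mtry=False,
                                     random_state=0).fit(X, y)
        ranked = est.feature_importance()["CA"]
        assert ranked[0][0] == "featA"
        assert all(imp >= 0 for _, imp in ranked)
        assert [i for _, i in ranked] == sorted(
            (i for _, i in ranked), reverse=True)

    def test_pure_noise_feature_below_shuffled_label_baseline(self):
        """Impurity importance of a noise feature stays within the range
        observed when the labels carry no signal at all."""
        rng = np.random.default_rng(6)
        n = 800
        X = pd.DataFrame({
            "super_class": ["CA"] * n,
            "signal": rng.normal(size=n),
            "noise": rng.normal(size=n),
        })
        y = 3.0 * X["signal"].to_numpy()
        est = SuperClassRandomForest(n_estimators=60, tune_mtry=False,
                                     random_state=0).fit(X, y)
        imp = dict(est.feature_importance()["CA"])
        y_perm = rng.permutation(y)
        est0 = SuperClassRandomForest(n_estimators=60, tune_mtry=False,
                                      random_state=0).fit(X, y_perm)
        imp0 = dict(est0.feature_importance()["CA"])
        baseline = max(imp0.values())
        assert imp["noise"] <= baseline
        assert imp["signal"] > baseline

    def test_single_feature_model(self):
        X, y = synthetic_frame(300, seed=7)
        X = X[["super_class", "featA"]]
        y = X["featA"].to_numpy() ** 2
        est = SuperClassRandomForest(n_estimators=20, tune_mtry=False,
                                     random_state=0).fit(X, y)
        assert est.feature_importance()["CA"][0][0] == "featA"


@pytest.fixture(scope="module")
def fitted(small_dataset):
    import copy

    dataset = copy.deepcopy(small_dataset[0])
    split_dataset(dataset, 0.6, seed=0)
    model = train_models(dataset, n_estimators=60, min_class_size=20,
                         tune_mtry=False, seed=0)
    return dataset, model


class TestRecordLevelTraining:

    def test_parameter_recovery_bands(self, fitted):
        """Noiseless generator: near-interpolation on held-out
        structures; evaluation intermediates populated."""
        dataset, model = fitted
        results = evaluate(model, dataset)
        assert results
        for label, r in results.items():
            assert r.n > 0
            # noiseless target at toy scale: error well below the class
            # spread (full-scale recovery bands live in the acceptance
            # suite, which runs the study-sized corpus)
            assert r.rmse < max(0.2, 0.5 * r.sd_exp), (label, r.rmse)
            assert r.mean_exp is not None and r.sd_exp is not None

    def test_pooled_metrics_cover_test_atoms(self, fitted):
        dataset, model = fitted
        pooled_rmse, pooled_corr, n = pooled_metrics(model, dataset)
        assert n > 0
        assert pooled_corr > 0.99

    def test_persistence_round_trip(self, fitted, tmp_path):
        dataset, model = fitted
        save_models(model, tmp_path / "models")
        again = load_models(tmp_path / "models")
        from shiftforge.model import records_to_frame

        X, _ = records_to_frame(dataset.test_records,
                                feature_names=model.feature_names_in_)
        a = model.predict(X)
        b = again.predict(X)
        np.testing.assert_array_equal(a, b)
        assert again.classes_ == model.classes_
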