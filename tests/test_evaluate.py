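from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from sipgcn.cli_pipeline import PipelineConfig
from sipgcn.evaluate import (
    ConfusionCounts,
    classification_metrics,
    confusion,
    cross_validate,
    cross_validate_features,
    five_fold_split,
    roc_auc,
)
from sipgcn.synthetic_data import SyntheticSpec, generate_records


def fast_config(**kw):
    """Composition descriptors straight to KNN: no graph stage, fast for protocol tests.

    Note the AC scheme is deliberately not used here: autocovariance is
    mean-centred per profile column, so the generator's planted column-mean
    shift is invisible to it.
    """
    defaults = dict(feature_scheme="pssm_composition", classifier="knn", knn_k=3)
    defaults.update(kw)
    return PipelineConfig(**defaults)


class TestConfusion:
    def test_perfect_and_inverted(self):
        c = confusion([1, 0], [1, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)
        c = confusion([1, 0], [0, 1])
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 1, 1)

    def test_matches_bruteforce_counting(self, rng):
        y = rng.integers(0, 2, size=1000)
        p = rng.integers(0, 2, size=1000)
        c = confusion(y, p)
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)
        assert c.total == 1000

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert m == {"Acc": 1.0, "Spe": 1.0, "F1": 1.0, "MCC": 1.0}

    def test_symmetric_counts(self):
        m = classification_metrics(ConfusionCounts(TP=1, TN=1, FP=1, FN=1))
        assert m["Acc"] == m["Spe"] == m["F1"] == 0.5
        assert m["MCC"] == 0.0

    def test_exact_rational_example(self):
        m = classification_metrics(ConfusionCounts(TP=30, TN=900, FP=9, FN=61))
        assert m["F1"] == pytest.approx(60 / 130)
        expected_mcc = (30 * 900 - 9 * 61) / np.sqrt(39.0 * 961.0 * 91.0 * 909.0)
        assert m["MCC"] == pytest.approx(expected_mcc, rel=1e-12)

    def test_zero_denominator_conventions(self):
        # no negatives at all: Spe and MCC denominators vanish
        m = classification_metrics(ConfusionCounts(TP=5, TN=0, FP=0, FN=0))
        assert m["Spe"] == 0.0
        assert m["MCC"] == 0.0
        # no positives predicted or present: F1 denominator vanishes
        m = classification_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert m["F1"] == 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(TP=0, TN=0, FP=0, FN=0))

    def test_random_tables_match_fraction_arithmetic(self, rng):
        for _ in range(300):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + tn + fp + fn == 0:
                continue
            m = classification_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
            total = Fraction(tp + tn, tp + tn + fp + fn)
            assert m["Acc"] == pytest.approx(float(total), abs=1e-12)
            spe = Fraction(tn, tn + fp) if tn + fp else Fraction(0)
            assert m["Spe"] == pytest.approx(float(spe), abs=1e-12)
            f1 = Fraction(2 * tp, 2 * tp + fp + fn) if 2 * tp + fp + fn else Fraction(0)
            assert m["F1"] == pytest.approx(float(f1), abs=1e-12)

    def test_mcc_against_sklearn(self, rng):
        y = rng.integers(0, 2, size=400)
        p = rng.integers(0, 2, size=400)
        c = confusion(y, p)
        ours = classification_metrics(c)["MCC"]
        assert ours == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(
        tp=st.integers(0, 500),
        tn=st.integers(0, 500),
        fp=st.integers(0, 500),
        fn=st.integers(0, 500),
    )
    def test_any_confusion_table_matches_exact_arithmetic(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = classification_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        assert m["Acc"] == pytest.approx((tp + tn) / (tp + tn + fp + fn), abs=1e-12)
        assert 0.0 <= m["Acc"] <= 1.0 and 0.0 <= m["Spe"] <= 1.0
        assert 0.0 <= m["F1"] <= 1.0 and -1.0 <= m["MCC"] <= 1.0
        spe = tn / (tn + fp) if tn + fp else 0.0
        assert m["Spe"] == pytest.approx(spe, abs=1e-12)

    def test_swap_symmetry(self, rng):
        # swapping classes in both labels and predictions preserves MCC and Acc
        y = rng.integers(0, 2, size=200)
        p = rng.integers(0, 2, size=200)
        m1 = classification_metrics(confusion(y, p))
        m2 = classification_metrics(confusion(1 - y, 1 - p))
        assert m1["MCC"] == pytest.approx(m2["MCC"], abs=1e-12)
        assert m1["Acc"] == pytest.approx(m2["Acc"], abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.1])
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_all_tied_scores(self):
        auc, _ = roc_auc([1, 0, 1, 0], [0.5] * 4)
        assert auc == 0.5

    def test_mann_whitney_hand_example(self):
        # pos {0.8, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs won
        auc, _ = roc_auc([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2])
        assert auc == pytest.approx(0.75)

    def test_equals_pair_counting_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = rng.integers(0, 6, size=n) / 5.0  # discrete scores force ties
            auc, _ = roc_auc(y, s)
            pos = s[y == 1]
            neg = s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = rng.normal(size=100)
        a1, _ = roc_auc(y, s)
        a2, _ = roc_auc(y, np.exp(3 * s))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]
        s = rng.normal(size=200).round(1)  # ties included
        ours, _ = roc_auc(y, s)
        assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.2, 0.3])


class TestFiveFoldSplit:
    def test_ten_samples_five_equal_folds(self):
        folds = five_fold_split(10, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_yeast_sized_split(self):
        # 710 SIPs + 5511 non-SIPs = 6221 samples
        folds = five_fold_split(6221, seed=1)
        assert sorted(len(f) for f in folds) == [1244, 1244, 1244, 1244, 1245]

    def test_disjoint_and_exhaustive_over_many_seeds(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 2000))
            seed = int(rng.integers(0, 2**31))
            folds = five_fold_split(n, seed)
            flat = np.concatenate(folds)
            assert len(flat) == n
            assert len(np.unique(flat)) == n
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(n=st.integers(5, 3000), seed=st.integers(0, 2**31 - 1))
    def test_any_split_is_a_balanced_partition(self, n, seed):
        folds = five_fold_split(n, seed)
        flat = np.concatenate(folds)
        assert len(flat) == n and len(np.unique(flat)) == n
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_reproducible_from_seed(self):
        f1 = five_fold_split(103, seed=9)
        f2 = five_fold_split(103, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_stratified_option_balances_classes(self, rng):
        y = np.array([1] * 10 + [0] * 90)
        folds = five_fold_split(100, seed=0, stratify_labels=y)
        for f in folds:
            assert y[f].sum() == 2  # 10 positives / 5 folds

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            five_fold_split(4, seed=0)


@pytest.fixture(scope="module")
def tiny_dataset():
    spec = SyntheticSpec(n_pos=25, n_neg=25, length_range=(50, 80), shift=3.0, seed=8)
    return generate_records(spec)


class TestCrossValidate:
    def test_separable_data_high_accuracy(self, tiny_dataset):
        records, pssms = tiny_dataset
        report = cross_validate(records, pssms, fast_config(), repetitions=1, seed=4)
        assert report.mean["Acc"] >= 0.9

    def test_same_seed_identical_report(self, tiny_dataset):
        records, pssms = tiny_dataset
        r1 = cross_validate(records, pssms, fast_config(), repetitions=2, seed=13)
        r2 = cross_validate(records, pssms, fast_config(), repetitions=2, seed=13)
        assert r1.rows == r2.rows
        for a_rep, b_rep in zip(r1.fold_assignments, r2.fold_assignments):
            for a, b in zip(a_rep, b_rep):
                np.testing.assert_array_equal(a, b)

    def test_fold_assignments_identical_across_classifier_swap(self, tiny_dataset):
        records, pssms = tiny_dataset
        r_knn = cross_validate(records, pssms, fast_config(classifier="knn"), seed=2)
        r_elm = cross_validate(records, pssms, fast_config(classifier="elm"), seed=2)
        for a_rep, b_rep in zip(r_knn.fold_assignments, r_elm.fold_assignments):
            for a, b in zip(a_rep, b_rep):
                np.testing.assert_array_equal(a, b)

    def test_folds_partition_the_data(self, tiny_dataset):
        records, pssms = tiny_dataset
        report = cross_validate(records, pssms, fast_config(), repetitions=1, seed=0)
        flat = np.concatenate(report.fold_assignments[0])
        assert sorted(flat.tolist()) == list(range(len(records)))

    def test_aggregate_mean_is_arithmetic_mean_of_folds(self, tiny_dataset):
        records, pssms = tiny_dataset
        report = cross_validate(records, pssms, fast_config(), repetitions=1, seed=6)
        accs = [row["Acc"] for row in report.rows]
        assert report.mean["Acc"] == pytest.approx(np.mean(accs), abs=1e-12)
        assert report.std["Acc"] == pytest.approx(np.std(accs, ddof=1), abs=1e-12)

    def test_degenerate_fold_records_nan_auc(self, caplog):
        # 2 positives among 25: some folds necessarily single-class
        spec = SyntheticSpec(n_pos=2, n_neg=23, length_range=(50, 60), shift=0.0,
                             signal_cols=(), seed=3)
        records, pssms = generate_records(spec)
        report = cross_validate(records, pssms, fast_config(), repetitions=1, seed=1)
        aucs = report.metric_values("AUC")
        assert np.isnan(aucs).any()
        assert np.isfinite(report.mean["AUC"])  # aggregate skips undefined folds

    def test_single_class_dataset_raises(self):
        spec = SyntheticSpec(n_pos=0, n_neg=10, length_range=(50, 60), shift=0.0,
                             signal_cols=(), seed=0)
        records, pssms = generate_records(spec)
        with pytest.raises(ValueError, match="both classes"):
            cross_validate(records, pssms, fast_config(), seed=0)

    def test_report_json_roundtrip(self, tiny_dataset, tmp_path):
        import json

        records, pssms = tiny_dataset
        report = cross_validate(records, pssms, fast_config(), repetitions=1, seed=0)
        report.to_json(tmp_path / "r.json")
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["mean"]["Acc"] == report.mean["Acc"]
        assert "Average" in report.table()

    def test_gcn_pipeline_scores_from_heldout_embeddings(self):
        # end-to-end run through the graph stage with default hyperparameters
        spec = SyntheticSpec(n_pos=50, n_neg=50, length_range=(50, 70), shift=3.0, seed=5)
        records, pssms = generate_records(spec)
        cfg = PipelineConfig(classifier="rf", n_trees=50)
        report = cross_validate(records, pssms, cfg, repetitions=1, seed=7)
        assert report.mean["Acc"] >= 0.9
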