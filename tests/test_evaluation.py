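import math

import numpy as np
import pytest
from scipy import stats

from rna5hmc.evaluation import (
    ConfusionCounts,
    confusion,
    cross_validate,
    metrics,
    position_enrichment,
    roc_pr_auc,
    stratified_kfold,
)
from rna5hmc.model import ModelConfig
from rna5hmc.sequence_io import LabeledDataset, SiteWindow
from rna5hmc.synthetic_data import SimConfig, generate
from tests.conftest import random_window


class TestConfusion:
    def test_perfect(self):
        y = [1] * 4 + [0] * 4
        c = confusion(y, y)
        assert (c.TP, c.TN, c.FP, c.FN) == (4, 4, 0, 0)

    def test_inverted(self):
        actual = np.array([1] * 4 + [0] * 4)
        c = confusion(1 - actual, actual)
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 4, 4)

    def test_hand_case(self):
        actual = [1, 1, 1, 1, 0, 0, 0, 0]
        predicted = [1, 1, 1, 0, 1, 1, 0, 0]
        c = confusion(predicted, actual)
        assert (c.TP, c.FN, c.FP, c.TN) == (3, 1, 2, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_total_invariant(self):
        rng = np.random.default_rng(0)
        pred, act = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        assert confusion(pred, act).total == 50


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert m == {"Sn": 1.0, "Sp": 1.0, "ACC": 1.0, "MCC": 1.0}

    def test_inverted_classifier(self):
        m = metrics(ConfusionCounts(TP=0, TN=0, FP=50, FN=50))
        assert m["ACC"] == 0.0 and m["MCC"] == -1.0

    def test_hand_case(self):
        m = metrics(ConfusionCounts(TP=3, FN=1, TN=2, FP=2))
        assert m["Sn"] == pytest.approx(0.75)
        assert m["Sp"] == pytest.approx(0.5)
        assert m["ACC"] == pytest.approx(0.625)
        assert m["MCC"] == pytest.approx(4 / math.sqrt(240))

    def test_mcc_zero_denominator_convention(self):
        m = metrics(ConfusionCounts(TP=5, FN=0, TN=0, FP=5))
        assert m["MCC"] == 0.0

    def test_undefined_sn_reported_missing(self):
        m = metrics(ConfusionCounts(TP=0, FN=0, TN=3, FP=2))
        assert m["Sn"] is None and m["Sp"] == pytest.approx(0.6)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(TP=0, TN=0, FP=0, FN=0))

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pred = rng.integers(0, 2, 40)
            act = rng.integers(0, 2, 40)
            if len(np.unique(act)) < 2 or len(np.unique(pred)) < 2:
                continue
            m = metrics(confusion(pred, act))
            swapped = metrics(confusion(1 - pred, 1 - act))
            assert swapped["Sn"] == pytest.approx(m["Sp"])
            assert swapped["Sp"] == pytest.approx(m["Sn"])
            assert swapped["ACC"] == pytest.approx(m["ACC"])
            assert abs(swapped["MCC"]) == pytest.approx(abs(m["MCC"]))


class TestStratifiedKfold:
    def test_exact_stratification(self):
        y = [1] * 5 + [0] * 5
        folds = stratified_kfold(y, k=5, seed=0)
        for fold in folds:
            assert len(fold) == 2
            assert sum(y[i] for i in fold) == 1

    def test_determinism_and_seed_sensitivity(self):
        y = [1] * 20 + [0] * 20
        a = stratified_kfold(y, k=5, seed=1)
        b = stratified_kfold(y, k=5, seed=1)
        c = stratified_kfold(y, k=5, seed=2)
        assert all(np.array_equal(x, z) for x, z in zip(a, b))
        assert any(not np.array_equal(x, z) for x, z in zip(a, c))

    def test_class_smaller_than_k(self):
        with pytest.raises(ValueError):
            stratified_kfold([1, 1, 0, 0, 0, 0, 0], k=3)

    def test_partition_properties_random_sweep(self):
        rng = np.random.default_rng(12)
        for trial in range(100):
            n_pos = int(rng.integers(5, 40))
            n_neg = int(rng.integers(5, 40))
            k = int(rng.integers(2, 6))
            if min(n_pos, n_neg) < k:
                continue
            y = np.array([1] * n_pos + [0] * n_neg)
            folds = stratified_kfold(y, k=k, seed=trial)
            flat = np.concatenate(folds)
            assert len(flat) == len(y)
            assert len(np.unique(flat)) == len(y)  # disjoint + covering
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1
            global_frac = n_pos / (n_pos + n_neg)
            for f in folds:
                n_pos_fold = int(y[f].sum())
                assert abs(n_pos_fold - global_frac * len(f)) <= 1


class TestRocPrAuc:
    def test_perfect_ordering(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        actual = [0, 0, 1, 1]
        roc, pr, auc = roc_pr_auc(scores, actual)
        assert auc == pytest.approx(1.0)

    def test_reversed_ordering(self):
        _, _, auc = roc_pr_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert auc == pytest.approx(0.0)

    def test_roc_endpoints(self, rng):
        scores = rng.random(50)
        actual = rng.integers(0, 2, 50)
        roc, _, _ = roc_pr_auc(scores, actual)
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(21)
        scores = rng.random(2000)
        actual = np.array([1] * 1000 + [0] * 1000)
        _, _, auc = roc_pr_auc(scores, actual)
        assert abs(auc - 0.5) < 0.03

    def test_mann_whitney_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            n_pos, n_neg = rng.integers(5, 30, size=2)
            scores = rng.normal(size=n_pos + n_neg)
            actual = np.array([1] * n_pos + [0] * n_neg)
            _, _, auc = roc_pr_auc(scores, actual)
            u, _ = stats.mannwhitneyu(scores[:n_pos], scores[n_pos:])
            assert auc == pytest.approx(u / (n_pos * n_neg), rel=1e-9)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_pr_auc([0.2, 0.8], [1, 1])


class TestCrossValidate:
    def test_mean_equals_fold_mean(self):
        ds = generate(SimConfig(n_pos=30, n_neg=30, g_boost=0.4, seed=5))
        report = cross_validate(ds, k=5, seed=0)
        assert len(report.per_fold) == 5
        accs = [m["ACC"] for m in report.per_fold]
        assert report.mean["ACC"] == pytest.approx(np.mean(accs))

    def test_planted_signal_high_accuracy(self):
        ds = generate(SimConfig(n_pos=150, n_neg=150, g_boost=0.6, seed=6))
        report = cross_validate(ds, k=5, seed=0)
        assert report.mean["ACC"] >= 0.9
        assert report.auc >= 0.95

    def test_null_data_near_chance(self):
        ds = generate(SimConfig(n_pos=100, n_neg=100, seed=7))
        report = cross_validate(ds, k=5, seed=0)
        assert 0.35 <= report.mean["ACC"] <= 0.65  # small-n tolerance

    def test_fixed_feature_subset(self):
        ds = generate(SimConfig(n_pos=30, n_neg=30, g_boost=0.4, seed=8))
        report = cross_validate(ds, selection=list(range(164, 244)), k=3, seed=0)
        assert report.mean["ACC"] is not None

    def test_determinism(self):
        ds = generate(SimConfig(n_pos=30, n_neg=30, g_boost=0.3, seed=9))
        a = cross_validate(ds, k=3, seed=4)
        b = cross_validate(ds, k=3, seed=4)
        assert a.per_fold == b.per_fold
        assert a.auc == b.auc

    def test_nested_selection_not_optimistic(self):
        # selecting features on the full dataset leaks information into the
        # CV estimate; nested reselection per fold must not exceed it, as a
        # tendency across seeds (on null data the gap is large)
        wins = 0
        for seed in range(5):
            ds = generate(SimConfig(n_pos=150, n_neg=150, seed=500 + seed))
            leaky = cross_validate(ds, selection="sfs", sfs_step=81, k=5, seed=seed)
            nested = cross_validate(
                ds, selection="sfs", sfs_step=81, k=5, seed=seed, nested=True
            )
            wins += nested.mean["ACC"] <= leaky.mean["ACC"]
        assert wins >= 4


class TestPositionEnrichment:
    def test_identical_sets_zero_difference(self, windows_41):
        table = position_enrichment(windows_41, windows_41)
        assert np.allclose(table["difference"], 0.0)
        assert np.allclose(table["p_bonferroni"], 1.0)

    def test_planted_enrichment_at_position_38(self, rng):
        positives = []
        for i in range(200):
            seq = list(random_window(rng, wid=f"p{i}").seq)
            seq[37] = "A"  # force A at 1-based position 38
            positives.append(SiteWindow(id=f"p{i}", seq="".join(seq)))
        negatives = [random_window(rng, wid=f"n{i}") for i in range(200)]
        table = position_enrichment(positives, negatives)
        top = table.loc[table["difference"].idxmax()]
        assert (top["position"], top["nucleotide"]) == (38, "A")
        assert top["p_bonferroni"] < 0.01

    def test_frequencies_sum_to_one_per_position(self, windows_41, rng):
        other = [random_window(rng, wid=f"o{i}") for i in range(6)]
        table = position_enrichment(windows_41, other)
        for cls in ("freq_pos", "freq_neg"):
            sums = table.groupby("position")[cls].sum()
            assert np.allclose(sums, 1.0)

    def test_length_mismatch(self, windows_41):
        short = [SiteWindow(id="s", seq="ACGUC")]
        with pytest.raises(ValueError):
            position_enrichment(windows_41, short)

    def test_empty_sets(self, windows_41):
        with pytest.raises(ValueError):
            position_enrichment([], windows_41)
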