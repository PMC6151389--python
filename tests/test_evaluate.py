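import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinsel.dataset import LabelMatrix
from kinsel.evaluate import (
    ConfusionCounts,
    choose_threshold,
    confusion,
    diff_matrix,
    fisher_exact_2x2,
    fisher_vs_random,
    metrics,
    paired_rank_test,
    per_kinase_summary,
    roc,
)

from panel_tables import PANEL_ROWS, SUBSET_ROWS


def brute_force_auc(scores, labels):
    """Concordant-pair counting with ties worth one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hypergeom_fisher_p(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestConfusion:
    def test_tiny_examples(self):
        c = confusion(np.array([1, 0]), np.array([1, 0]))
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)
        c = confusion(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_counts_sum_to_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        labels = rng.integers(0, 2, n)
        calls = rng.integers(0, 2, n)
        assert confusion(labels, calls).total == n

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.array([1]), np.array([1, 0]))


class TestMetrics:
    @pytest.mark.parametrize("row", PANEL_ROWS, ids=lambda r: f"cutoff_{r[0]}uM")
    def test_panel_rows_reproduced(self, row):
        """Six derived metrics match the printed panel table at printed
        precision (within one unit in the last printed digit)."""
        cutoff, mcc, acc, sen, sel, tp, fp, tn, fn, ppv, npv = row
        r = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert r.mcc == pytest.approx(mcc, abs=0.01)
        assert r.acc * 100 == pytest.approx(acc, abs=0.01)
        assert r.sen * 100 == pytest.approx(sen, abs=0.01)
        assert r.sel * 100 == pytest.approx(sel, abs=0.01)
        assert r.ppv == pytest.approx(ppv, abs=0.01)
        assert r.npv == pytest.approx(npv, abs=0.01)

    @pytest.mark.parametrize("row", SUBSET_ROWS, ids=lambda r: r[0])
    def test_subset_rows_reproduced(self, row):
        """Comparison-subset rows print percents at one decimal; fractions at
        two."""
        _, mcc, acc, sen, sel, tp, fp, tn, fn, ppv, npv = row
        r = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert r.mcc == pytest.approx(mcc, abs=0.01)
        assert r.acc * 100 == pytest.approx(acc, abs=0.1)
        assert r.sen * 100 == pytest.approx(sen, abs=0.1)
        assert r.sel * 100 == pytest.approx(sel, abs=0.1)
        assert r.ppv == pytest.approx(ppv, abs=0.01)
        assert r.npv == pytest.approx(npv, abs=0.01)

    def test_perfect_classifier(self):
        r = metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (r.sen, r.sel, r.acc, r.mcc, r.ppv, r.npv) == (1, 1, 1, 1, 1, 1)

    def test_undefined_metrics_flagged(self):
        r = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert "mcc" in r.undefined and r.mcc == 0.0
        assert math.isnan(r.sen) and "sen" in r.undefined

    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200))
    @settings(max_examples=100, derandomize=True)
    def test_class_swap_symmetry_and_acc_identity(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        a = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        b = metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        prev = (tp + fn) / (tp + fp + tn + fn)
        if not (math.isnan(a.sen) or math.isnan(a.sel)):
            assert a.acc == pytest.approx(
                a.sen * prev + a.sel * (1 - prev), abs=1e-12
            )


class TestRoc:
    def test_perfect_separation(self):
        c = roc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert c.auc == 1.0
        assert c.fpr[0] == 0 and c.tpr[-1] == 1

    def test_constant_scores_give_half(self):
        c = roc(np.ones(10), np.array([1] * 5 + [0] * 5))
        assert c.auc == pytest.approx(0.5)

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(8, 25))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert roc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_score_negation_flips_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)  # continuous, no ties
        labels = rng.integers(0, 2, 30)
        assert roc(-scores, labels).auc == pytest.approx(
            1 - roc(scores, labels).auc, abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestPerKinaseSummary:
    def test_ranked_and_antiranked_columns(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        labels = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        s = per_kinase_summary(scores, labels)
        np.testing.assert_allclose(s.auc, [1.0, 0.0])

    def test_quartiles_of_engineered_aucs(self):
        # 5 actives vs 2 inactives (scores 10 and 20) per column; each active
        # scoring 5/15/25 wins 0/1/2 of its 2 pairs, so choosing the win
        # multiset fixes the column AUC exactly at (0.5, 0.6, 0.7, 0.8)
        win_sets = [(2, 1, 1, 1, 0), (2, 2, 1, 1, 0), (2, 2, 2, 1, 0),
                    (2, 2, 2, 2, 0)]
        pos_score = {0: 5.0, 1: 15.0, 2: 25.0}
        scores = np.array(
            [[pos_score[w] for w in ws] for ws in win_sets], dtype=float
        ).T  # rows = 5 actives, cols = 4 kinases
        scores = np.vstack([scores, np.full((1, 4), 10.0), np.full((1, 4), 20.0)])
        labels = np.vstack([np.ones((5, 4), dtype=int), np.zeros((2, 4), dtype=int)])
        s = per_kinase_summary(scores, labels)
        np.testing.assert_allclose(s.auc, [0.5, 0.6, 0.7, 0.8])
        assert s.median == pytest.approx(0.65)

    def test_summary_matches_sort_based_quantiles(self):
        rng = np.random.default_rng(23)
        n_k = 40
        scores = rng.random((30, n_k))
        labels = rng.integers(0, 2, (30, n_k))
        labels[0] = 1  # ensure both classes in every column
        labels[1] = 0
        s = per_kinase_summary(scores, labels)
        valid = np.sort(s.auc[~np.isnan(s.auc)])

        def quantile(sorted_v, q):
            # linear interpolation between closest ranks
            h = (len(sorted_v) - 1) * q
            lo = int(np.floor(h))
            hi = int(np.ceil(h))
            return sorted_v[lo] + (h - lo) * (sorted_v[hi] - sorted_v[lo])

        assert s.q1 == pytest.approx(quantile(valid, 0.25), abs=1e-12)
        assert s.median == pytest.approx(quantile(valid, 0.5), abs=1e-12)
        assert s.q3 == pytest.approx(quantile(valid, 0.75), abs=1e-12)
        assert s.minimum == valid[0] and s.maximum == valid[-1]
        iqr = s.q3 - s.q1
        assert s.whisker_low >= s.q1 - 1.5 * iqr
        assert s.whisker_high <= s.q3 + 1.5 * iqr

    def test_single_class_column_skipped(self):
        scores = np.array([[0.9, 0.5], [0.1, 0.5]])
        labels = np.array([[1, 1], [0, 1]])
        s = per_kinase_summary(scores, labels, ["a", "b"])
        assert s.skipped == ["b"]
        assert np.isnan(s.auc[1])


class TestChooseThreshold:
    def test_perfect_separation_midpoint(self):
        thr, val = choose_threshold(
            np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])
        )
        assert thr == pytest.approx(0.5)
        assert val == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self):
        from kinsel.evaluate import ConfusionCounts, confusion, metrics

        rng = np.random.default_rng(31)
        for _ in range(10):
            scores = np.round(rng.random(30), 2)
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            thr, val = choose_threshold(scores, labels)
            best = (-np.inf, -np.inf)
            distinct = np.unique(scores)
            cands = list((distinct[:-1] + distinct[1:]) / 2) + [distinct[-1] + 1]
            for t in cands:
                v = metrics(confusion(labels, (scores >= t).astype(int))).mcc
                if (v, t) > best:
                    best = (v, t)
            assert val == pytest.approx(best[0], abs=1e-12)
            assert thr == pytest.approx(best[1], abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold(np.array([0.4, 0.6]), np.array([1, 1]))


class TestPairedRankTest:
    def test_identical_vectors_give_p_one(self):
        v = np.linspace(0.5, 0.9, 8)
        stat, p = paired_rank_test(v, v)
        assert p == 1.0

    def test_exact_small_sample(self):
        # n = 5, all differences positive: two-sided p = 2 / 2^5
        a = np.array([0.6, 0.7, 0.8, 0.9, 0.95])
        b = a - np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        _, p = paired_rank_test(a, b)
        assert p == pytest.approx(2 / 32, abs=1e-12)

    def test_exact_and_normal_branches_agree(self):
        rng = np.random.default_rng(6)
        from scipy import stats

        for _ in range(5):
            a = rng.normal(size=12)
            b = a + rng.normal(scale=0.8, size=12)
            exact = stats.wilcoxon(a, b, zero_method="wilcox", method="exact")
            approx = stats.wilcoxon(a, b, zero_method="wilcox", method="approx")
            assert abs(exact.pvalue - approx.pvalue) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_rank_test(np.ones(3), np.zeros(3))


class TestFisher:
    def test_diagonal_table_matches_hypergeometric_enumeration(self):
        table = np.array([[10, 0], [0, 10]])
        assert fisher_exact_2x2(table) == pytest.approx(
            hypergeom_fisher_p(table), abs=1e-12
        )

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            table = rng.integers(0, 30, size=(2, 2))
            if table.sum() == 0:
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                hypergeom_fisher_p(table), rel=1e-9
            )

    def test_transpose_invariance(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            table = rng.integers(0, 40, size=(2, 2))
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_exact_2x2(table.T), abs=1e-12
            )

    def test_coin_flip_model_gives_p_one(self):
        # a model that is right on exactly half its calls is indistinguishable
        # from the coin-flip null
        p, table = fisher_vs_random(ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
        assert p == 1.0
        assert table[0].tolist() == [50, 50]

    def test_strong_model_significant(self):
        p, _ = fisher_vs_random(ConfusionCounts(tp=90, fp=10, tn=90, fn=10))
        assert p < 1e-6


class TestDiffMatrix:
    def _label(self, arr):
        arr = np.asarray(arr)
        return LabelMatrix(
            compounds=[f"c{i}" for i in range(arr.shape[0])],
            kinases=[f"k{j}" for j in range(arr.shape[1])],
            labels=arr,
            cutoff_uM=10.0,
        )

    def test_identical_matrices_all_correct(self):
        m = self._label([[1, 0], [0, 1]])
        _, counts = diff_matrix(m, self._label([[1, 0], [0, 1]]))
        assert counts == {"correct": 4, "fp": 0, "fn": 0}

    def test_single_false_positive(self):
        exp = self._label([[0, 0]])
        pred = self._label([[1, 0]])
        diff, counts = diff_matrix(exp, pred)
        assert counts == {"correct": 1, "fp": 1, "fn": 0}
        assert diff[0, 0] == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_counts_conservation(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(1, 8)), int(rng.integers(1, 8)))
        a = rng.integers(0, 2, shape)
        b = rng.integers(0, 2, shape)
        _, counts = diff_matrix(self._label(a), self._label(b))
        assert sum(counts.values()) == shape[0] * shape[1]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diff_matrix(self._label([[1]]), self._label([[1, 0]]))
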