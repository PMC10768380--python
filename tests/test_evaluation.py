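"""Folds, confusion metrics, ranking curves, recall@k, coverage, Wilcoxon."""
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from scipy import stats

from ttgcn.evaluation import (confusion_metrics, coverage, make_folds,
                              ranking_curves, recall_at_topk, wilcoxon_paired)


# ---- folds ----------------------------------------------------------------

def test_singleton_folds():
    f = make_folds(10, 10, seed=0)
    assert sorted(np.bincount(f.assignment)) == [1] * 10


def test_fold_sizes_near_equal_708():
    f = make_folds(708, 10, seed=1)
    sizes = np.bincount(f.assignment)
    assert sizes.sum() == 708
    assert set(sizes) <= {70, 71}
    assert sorted(sizes)[:2] == [70, 70]   # 708 = 8*71 + 2*70


def test_fold_determinism_and_validation():
    a = make_folds(50, 5, seed=3).assignment
    b = make_folds(50, 5, seed=3).assignment
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        make_folds(10, 0, seed=0)
    with pytest.raises(ValueError):
        make_folds(3, 5, seed=0)


# ---- confusion metrics -----------------------------------------------------

def test_perfect_predictor():
    m = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
    assert (m.tpr, m.fpr, m.precision, m.mcc) == (1.0, 0.0, 1.0, 1.0)


def test_symmetric_confusion_mcc_zero():
    # TP=1, FP=1, TN=1, FN=1
    m = confusion_metrics([1, 0, 0, 1], [1, 1, 0, 0])
    assert m.mcc == 0.0


def test_mcc_hand_arithmetic():
    # TP=6, FP=1, TN=91, FN=2 -> MCC = 544 / sqrt(7*8*92*93)
    y = [1] * 8 + [0] * 92
    p = [1] * 6 + [0] * 2 + [1] * 1 + [0] * 91
    m = confusion_metrics(y, p)
    expect = (6 * 91 - 1 * 2) / np.sqrt(7 * 8 * 92 * 93)
    assert m.mcc == pytest.approx(expect, abs=1e-12)
    assert m.tpr == pytest.approx(6 / 8)
    assert m.precision == pytest.approx(6 / 7)


def test_confusion_rejects_empty():
    with pytest.raises(ValueError):
        confusion_metrics([], [])


# ---- ranking curves --------------------------------------------------------

def brute_force_auroc(y, s):
    """Pairwise concordance count with half-credit ties."""
    y, s = np.asarray(y), np.asarray(s, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_aupr(y, s):
    """Step-wise precision-recall summation over the exhaustive threshold sweep."""
    y, s = np.asarray(y), np.asarray(s, dtype=float)
    order = np.argsort(-s, kind="stable")
    # group ties: evaluate at each unique threshold
    thresholds = np.unique(s)[::-1]
    P = y.sum()
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        sel = s >= t
        tp = int((y[sel] == 1).sum())
        prec = tp / sel.sum()
        rec = tp / P
        ap += (rec - prev_recall) * prec
        prev_recall = rec
    return ap


def test_perfect_and_tied_rankings():
    y = np.array([1, 0, 1, 0])
    a, p = ranking_curves(y, y.astype(float))
    assert (a, p) == (1.0, 1.0)
    a, _ = ranking_curves(y, np.zeros(4))
    assert a == 0.5


def test_ranking_matches_brute_force_oracles():
    rng = np.random.default_rng(0)
    for trial in range(20):
        n = int(rng.integers(8, 60))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        s = np.round(rng.normal(size=n), 1)   # rounding forces ties
        a, p = ranking_curves(y, s)
        assert a == pytest.approx(brute_force_auroc(y, s), abs=1e-9)
        assert p == pytest.approx(brute_force_aupr(y, s), abs=1e-9)


def test_single_class_rejected():
    with pytest.raises(ValueError, match="positive"):
        ranking_curves([1, 1], [0.1, 0.2])


# ---- recall@k and coverage -------------------------------------------------

def test_recall_topk_all_positives_on_top():
    n, p = 40, 3
    y = np.array([1] * p + [0] * (n - p))
    s = -np.arange(n, dtype=float)
    r = recall_at_topk(y, s, (5,))
    assert r[5] == min(1.0, np.ceil(0.05 * n) / p)


def test_recall_topk_matches_sort_oracle():
    rng = np.random.default_rng(1)
    for _ in range(10):
        n = 50
        y = (rng.random(n) < 0.2).astype(int)
        if y.sum() == 0:
            y[0] = 1
        s = np.round(rng.normal(size=n), 1)
        got = recall_at_topk(y, s)
        order = sorted(range(n), key=lambda i: (-s[i], y[i]))
        for k, v in got.items():
            top = order[: int(np.ceil(k / 100 * n))]
            assert v == pytest.approx(sum(y[i] for i in top) / y.sum())


def test_recall_requires_positives():
    with pytest.raises(ValueError):
        recall_at_topk(np.zeros(5, dtype=int), np.arange(5.0))


def test_coverage_extremes_and_bounds():
    y = np.array([1, 1, 0, 0, 0])
    assert coverage(y, np.array([5.0, 4, 3, 2, 1])) == 2        # P positives first
    y2 = np.array([0, 0, 0, 1])
    assert coverage(y2, np.array([4.0, 3, 2, 1])) == 4          # last of N
    rng = np.random.default_rng(2)
    for _ in range(10):
        y = (rng.random(30) < 0.3).astype(int)
        if y.sum() == 0:
            y[0] = 1
        s = np.round(rng.normal(size=30), 1)
        c = coverage(y, s)
        assert y.sum() <= c <= 30
        order = sorted(range(30), key=lambda i: (-s[i], y[i]))
        last = max(i for i, idx in enumerate(order) if y[idx] == 1)
        assert c == last + 1


# ---- Wilcoxon signed-rank --------------------------------------------------

def test_wilcoxon_identical_vectors():
    assert wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0


def test_wilcoxon_exact_all_positive_n5():
    # all five differences positive: exact two-sided p = 2/2^5
    a = np.array([1.0, 2, 3, 4, 5])
    assert wilcoxon_paired(a, np.zeros(5)) == pytest.approx(2 / 2**5)


def test_wilcoxon_exact_matches_enumeration():
    rng = np.random.default_rng(3)
    d = rng.normal(size=8)
    got = wilcoxon_paired(d, np.zeros(8))
    # exhaustive sign-flip enumeration oracle
    r = stats.rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    ws = [sum(ri for ri, s in zip(r, signs) if s)
          for signs in product([False, True], repeat=8)]
    ws = np.array(ws)
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    assert got == pytest.approx(min(1.0, 2 * min(p_le, p_ge)), abs=1e-12)


def test_wilcoxon_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(4)
    d = rng.normal(size=12)
    expect = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
    assert wilcoxon_paired(d, np.zeros(12)) == pytest.approx(expect, abs=1e-12)


def test_wilcoxon_large_n_approximation():
    rng = np.random.default_rng(5)
    d = rng.normal(loc=0.4, size=30)
    got = wilcoxon_paired(d, np.zeros(30))
    # Monte-Carlo sign-flip estimate of the two-sided exact p
    r = stats.rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    flips = rng.random((200_000, 30)) < 0.5
    ws = flips @ r
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    mc = min(1.0, 2 * min(p_le, p_ge))
    assert got == pytest.approx(mc, abs=0.01)


def test_wilcoxon_rejects_length_mismatch():
    with pytest.raises(ValueError):
        wilcoxon_paired([1.0], [1.0, 2.0])
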