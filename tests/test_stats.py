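"""Diagnostic statistics against independent oracles: enumeration,
jackknife, permutation, and frozen reference interval values."""

import numpy as np
import pytest

from mastsym.labels import BilateralLabel, EarCategory
from mastsym.network import BilateralPrediction
from mastsym.stats_eval import (
    clopper_pearson,
    delong_ci,
    delong_compare_one_sided,
    evaluate,
    mcnemar,
    roc_auc,
)


# -- AUC --------------------------------------------------------------------


def test_auc_examples():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5
    # 4 pairs: (0.35 vs 0.1) win, (0.35 vs 0.4) loss, (0.8 vs both) wins
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75


def test_auc_against_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(20):
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            continue
        s = np.round(rng.random(30), 1)  # coarse scores force ties
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_antisymmetry(rng):
    y = np.r_[np.zeros(10, int), np.ones(10, int)]
    s = rng.permutation(np.arange(20)).astype(float)  # tie-free
    assert roc_auc(s, y) + roc_auc(-s, y) == pytest.approx(1.0, abs=1e-12)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


# -- DeLong -----------------------------------------------------------------


def test_delong_point_equals_mann_whitney(rng):
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    s = rng.random(50)
    auc, lo, hi = delong_ci(s, y)
    assert auc == roc_auc(s, y)
    assert lo <= auc <= hi


def test_delong_alpha_monotone(rng):
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    s = rng.random(40) + 0.3 * y
    _, lo5, hi5 = delong_ci(s, y, alpha=0.05)
    _, lo1, hi1 = delong_ci(s, y, alpha=0.01)
    assert lo1 <= lo5 and hi1 >= hi5


def test_delong_variance_against_jackknife(rng):
    """DeLong structural-component variance tracks the leave-one-out
    jackknife variance of the AUC on a 40-sample set."""
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    s = rng.random(40) + 0.5 * y
    auc, lo, hi = delong_ci(s, y)
    var_delong = ((hi - lo) / (2 * 1.959963984540054)) ** 2
    loo = np.array([roc_auc(np.delete(s, i), np.delete(y, i)) for i in range(40)])
    var_jack = (len(loo) - 1) / len(loo) * ((loo - loo.mean()) ** 2).sum()
    assert var_delong == pytest.approx(var_jack, rel=0.10)


def test_delong_compare_degenerate_and_sign():
    y = np.r_[np.zeros(10, int), np.ones(10, int)]
    rng = np.random.default_rng(2)
    s = rng.random(20) + y
    assert delong_compare_one_sided(s, s.copy(), y) == 0.5
    s2 = rng.random(20) + 0.5 * y
    p = delong_compare_one_sided(s, s2, y)
    assert delong_compare_one_sided(s2, s, y) == pytest.approx(1 - p, abs=1e-12)


def test_delong_compare_against_permutation_oracle():
    """One-sided DeLong p agrees with a 10,000-draw permutation oracle
    that randomly exchanges the two models' scores within each subject."""
    rng = np.random.default_rng(31)
    n = 80
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    base = rng.random(n)
    s_a = np.clip(base + 0.35 * y + 0.12 * rng.standard_normal(n), 0, None)
    s_b = np.clip(base + 0.22 * y + 0.12 * rng.standard_normal(n), 0, None)
    p_delong = delong_compare_one_sided(s_a, s_b, y)

    observed = roc_auc(s_a, y) - roc_auc(s_b, y)
    n_perm = 10_000
    flips = rng.integers(0, 2, size=(n_perm, n)).astype(bool)
    count = 0
    for f in flips:
        pa = np.where(f, s_b, s_a)
        pb = np.where(f, s_a, s_b)
        if roc_auc(pa, y) - roc_auc(pb, y) >= observed:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    assert p_delong == pytest.approx(p_perm, abs=0.02)


# -- Clopper-Pearson --------------------------------------------------------


@pytest.mark.parametrize(
    "k,n,point,lo,hi",
    [
        (125, 130, 96.2, 91.3, 98.7),
        (137, 172, 79.7, 72.9, 85.4),
        (122, 172, 70.9, 63.5, 77.6),
        (108, 172, 62.8, 55.1, 70.0),
    ],
)
def test_clopper_pearson_reference_intervals(k, n, point, lo, hi):
    """Exact intervals recomputed from count fractions match the frozen
    reference values to one decimal in percent."""
    p, l, h = clopper_pearson(k, n)
    assert round(100 * p, 1) == point
    assert round(100 * l, 1) == lo
    assert round(100 * h, 1) == hi


def test_clopper_pearson_edges_and_monotonicity():
    p, lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0 and p == 0.0 and hi > 0
    p, lo, hi = clopper_pearson(10, 10)
    assert hi == 1.0
    prev = (-1.0, -1.0)
    for k in range(11):
        p, lo, hi = clopper_pearson(k, 10)
        assert lo <= p <= hi
        assert lo >= prev[0] and hi >= prev[1]
        prev = (lo, hi)
    with pytest.raises(ValueError):
        clopper_pearson(5, 4)


def test_clopper_pearson_against_statsmodels(rng):
    from statsmodels.stats.proportion import proportion_confint

    for _ in range(10):
        n = int(rng.integers(5, 200))
        k = int(rng.integers(0, n + 1))
        _, lo, hi = clopper_pearson(k, n)
        slo, shi = proportion_confint(k, n, method="beta")
        assert lo == pytest.approx(slo, abs=1e-12)
        assert hi == pytest.approx(shi, abs=1e-12)


# -- McNemar ----------------------------------------------------------------


def test_mcnemar_exact_tail():
    # all 10 discordant pairs favour one side: p = 2 * (1/2)^10
    assert mcnemar(10, 0) == pytest.approx(2 * 0.5**10, rel=1e-9)
    assert mcnemar(10, 0) == pytest.approx(0.00195, abs=5e-6)


def test_mcnemar_symmetry_and_degenerate(rng):
    for _ in range(5):
        b, c = int(rng.integers(0, 30)), int(rng.integers(0, 30))
        if b == c == 0:
            continue
        assert mcnemar(b, c) == pytest.approx(mcnemar(c, b), rel=1e-12)
    assert mcnemar(7, 7) == 1.0
    with pytest.warns(UserWarning, match="degenerate"):
        assert mcnemar(0, 0) == 1.0


# -- report assembly --------------------------------------------------------


def _fixture_predictions():
    """4 subjects / 8 ears with hand-readable probabilities."""
    mk = lambda *v: np.array(v)
    u = mk(1 / 3, 1 / 3, 1 / 3)
    preds = [
        BilateralPrediction(mk(0.8, 0.1, 0.1), mk(0.1, 0.7, 0.2), u),  # R correct 0, L correct 1
        BilateralPrediction(mk(0.1, 0.2, 0.7), mk(0.9, 0.05, 0.05), u),  # R correct 2, L correct 0
        BilateralPrediction(mk(0.6, 0.3, 0.1), mk(0.2, 0.3, 0.5), u),  # R wrong (true 1), L true 2 pred 2
        BilateralPrediction(mk(0.3, 0.6, 0.1), mk(0.5, 0.4, 0.1), u),  # R true 0 pred 1, L true 0 pred 0
    ]
    labels = [
        BilateralLabel("a", EarCategory(0), EarCategory(1)),
        BilateralLabel("b", EarCategory(2), EarCategory(0)),
        BilateralLabel("c", EarCategory(1), EarCategory(2)),
        BilateralLabel("d", EarCategory(0), EarCategory(0)),
    ]
    return preds, labels


def test_evaluate_hand_computed_fixture():
    preds, labels = _fixture_predictions()
    rep = evaluate(preds, labels)
    assert rep.n_ears == 8
    # positives: a-L(1), b-R(2), c-R(1), c-L(2) -> detected: a-L, b-R, c-L (c-R missed)
    assert (rep.sensitivity.k, rep.sensitivity.n) == (3, 4)
    # negatives: a-R, b-L, d-R, d-L -> d-R called positive
    assert (rep.specificity.k, rep.specificity.n) == (3, 4)
    # 3-class accuracy: correct = a-R, a-L, b-R, b-L, c-L, d-L = 6 of 8
    assert (rep.accuracy.k, rep.accuracy.n) == (6, 8)
    assert rep.accuracy.point == pytest.approx(np.trace(rep.confusion) / rep.confusion.sum())
    assert rep.confusion.sum() == 8


def test_evaluate_order_invariant():
    preds, labels = _fixture_predictions()
    rep1 = evaluate(preds, labels)
    order = [2, 0, 3, 1]
    rep2 = evaluate([preds[i] for i in order], [labels[i] for i in order])
    assert rep1.auc == rep2.auc
    np.testing.assert_array_equal(rep1.confusion, rep2.confusion)


def test_evaluate_perfect_predictions():
    mk = lambda c: np.eye(3)[c]
    labels = [
        BilateralLabel("a", EarCategory(0), EarCategory(2)),
        BilateralLabel("b", EarCategory(1), EarCategory(0)),
        BilateralLabel("c", EarCategory(2), EarCategory(1)),
    ]
    preds = [
        BilateralPrediction(mk(int(l.right)), mk(int(l.left)), np.full(3, 1 / 3))
        for l in labels
    ]
    rep = evaluate(preds, labels)
    assert rep.sensitivity.point == 1.0
    assert rep.specificity.point == 1.0
    assert rep.accuracy.point == 1.0
    assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))
    assert rep.auc == 1.0


def test_evaluate_with_comparator():
    preds, labels = _fixture_predictions()
    rep = evaluate(preds, labels, comparators={"other": preds})
    comp = rep.comparisons["other"]
    assert comp["delong_auc_greater"] == 0.5  # identical scores
    assert comp["mcnemar_sensitivity"] == 1.0
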