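"""Contingency-table agreement statistics against published values and
an independent brute-force oracle."""

import numpy as np
import pytest
from scipy import stats as sps

from hep2 import agreement as ag


@pytest.fixture(scope="module")
def t1():
    return ag.load_table1()


@pytest.fixture(scope="module")
def t2():
    return ag.load_table2()


COLLAPSE = {"positive": "positive", "weak_positive": "positive", "negative": "negative"}


@pytest.fixture(scope="module")
def pooled(t1, t2):
    return ag.pool([ag.collapse(t1, COLLAPSE), ag.collapse(t2, COLLAPSE)])


def test_fixture_tables_match_printed_marginals(t1, t2):
    assert t1.n == 924 and t2.n == 298
    assert list(t1.counts.sum(axis=1)) == [546, 140, 238]
    assert list(t1.counts.sum(axis=0)) == [140, 556, 228]
    assert list(t2.counts.sum(axis=1)) == [57, 16, 225]
    assert list(t2.counts.sum(axis=0)) == [44, 47, 207]


def test_collapse_to_two_classes(t1, t2):
    c1 = ag.collapse(t1, COLLAPSE)
    c2 = ag.collapse(t2, COLLAPSE)
    assert c1.counts.tolist() == [[657, 29], [39, 199]]
    assert c2.counts.tolist() == [[67, 6], [24, 201]]
    ident = {k: k for k in t1.row_labels}
    assert ag.collapse(t1, ident).counts.tolist() == t1.counts.tolist()


def test_pool_and_commutativity(t1, t2, pooled):
    assert pooled.counts.tolist() == [[724, 35], [63, 400]]
    assert pooled.n == 1222
    other = ag.collapse(ag.pool([t1, t2]), COLLAPSE)
    assert other.counts.tolist() == pooled.counts.tolist()
    zero_plus = ag.pool([t1, ag.ContingencyTable(np.eye(3, dtype=int),
                                                 t1.row_labels, t1.col_labels)])
    assert (zero_plus.counts - t1.counts - np.eye(3, dtype=int) == 0).all()


def test_contingency_coefficients_match_published(t1, t2):
    assert ag.contingency_coefficient(t1) == pytest.approx(0.646, abs=5e-4)
    assert ag.contingency_coefficient(t2) == pytest.approx(0.695, abs=5e-4)


def test_chi_square_independence_is_zero():
    t = ag.ContingencyTable(np.array([[10, 20], [30, 60]]), ("a", "b"), ("x", "y"))
    chi2, df, p = ag.chi_square_test(t)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert df == 1


def test_kappa_matches_published_with_ci(pooled):
    kappa, (lo, hi) = ag.cohen_kappa(pooled)
    assert kappa == pytest.approx(0.828, abs=5e-4)
    assert lo == pytest.approx(0.795, abs=1e-3)
    assert hi == pytest.approx(0.860, abs=1e-3)


def test_kappa_cross_checked_against_statsmodels(pooled):
    ir = pytest.importorskip("statsmodels.stats.inter_rater")
    res = ir.cohens_kappa(pooled.counts)
    kappa, (lo, hi) = ag.cohen_kappa(pooled)
    assert kappa == pytest.approx(res.kappa, abs=1e-10)
    assert lo == pytest.approx(res.kappa_low, abs=1e-6)
    assert hi == pytest.approx(res.kappa_upp, abs=1e-6)


def test_kappa_degenerate_and_boundary_cases():
    diag = ag.ContingencyTable(np.diag([5, 7]), ("a", "b"), ("a", "b"))
    assert ag.cohen_kappa(diag)[0] == pytest.approx(1.0)
    # exact product of marginals -> chance agreement only
    indep = ag.ContingencyTable(np.array([[16, 24], [24, 36]]), ("a", "b"), ("a", "b"))
    assert ag.cohen_kappa(indep)[0] == pytest.approx(0.0, abs=1e-12)


def test_kappa_invariant_under_simultaneous_permutation(pooled):
    perm = ag.ContingencyTable(pooled.counts[::-1, ::-1],
                               pooled.row_labels[::-1], pooled.col_labels[::-1])
    assert ag.cohen_kappa(perm)[0] == pytest.approx(ag.cohen_kappa(pooled)[0], abs=1e-12)


def test_percent_agreement_and_discordance(pooled):
    assert ag.percent_agreement(pooled) == pytest.approx(92.0, abs=0.05)
    discordant = int(pooled.counts[0, 1] + pooled.counts[1, 0])
    assert discordant == 98
    assert 100 * discordant / pooled.n == pytest.approx(8.0, abs=0.05)


def test_mcnemar_university_cohort(t1):
    m = ag.mcnemar(ag.collapse(t1, COLLAPSE))
    assert (m.b, m.c) == (29, 39)
    assert m.diff_percent == pytest.approx(1.08, abs=5e-3)
    assert m.p > 0.05  # not significant, as reported


def test_mcnemar_private_cohort(t2):
    m = ag.mcnemar(ag.collapse(t2, COLLAPSE))
    assert (m.b, m.c) == (6, 24)
    assert m.diff_percent == pytest.approx(6.04, abs=5e-3)
    assert m.p_cc == pytest.approx(0.0019, abs=1e-4)


def test_mcnemar_weak_excluded_difference(t2):
    # keep only strictly positive and negative calls on both axes
    sub = ag.ContingencyTable(
        t2.counts[np.ix_([0, 2], [0, 2])], ("positive", "negative"), ("positive", "negative")
    )
    m = ag.mcnemar(sub)
    assert abs(m.diff_percent) == pytest.approx(0.81, abs=5e-3)
    assert m.p > 0.05


def test_row_confirmation_rates(t1, t2):
    confirmed1 = t1.counts[0, 0] + t1.counts[0, 1]  # automated-positive confirmed
    assert confirmed1 == 543
    assert 100 * confirmed1 / t1.counts[0].sum() == pytest.approx(99.5, abs=0.05)
    confirmed2 = t2.counts[0, 0] + t2.counts[0, 1]
    assert confirmed2 == 55
    assert 100 * confirmed2 / t2.counts[0].sum() == pytest.approx(96.5, abs=0.05)


def test_mcnemar_symmetric_discordance_is_null():
    t = ag.ContingencyTable(np.array([[50, 7], [7, 50]]), ("p", "n"), ("p", "n"))
    m = ag.mcnemar(t)
    assert m.diff_percent == 0.0
    assert m.p == pytest.approx(1.0)


def test_statistics_match_brute_force_oracle_on_random_tables():
    """Direct formula evaluation must agree to 1e-10 on random tables."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        k = int(rng.integers(2, 5))
        counts = rng.integers(1, 80, size=(k, k))
        t = ag.ContingencyTable(counts, tuple("rc"[0] + str(i) for i in range(k)),
                                tuple("c" + str(i) for i in range(k)))
        n = counts.sum()
        # chi-square from first principles
        e = np.outer(counts.sum(1), counts.sum(0)) / n
        chi2_o = float(((counts - e) ** 2 / e).sum())
        chi2, df, p = ag.chi_square_test(t)
        assert abs(chi2 - chi2_o) < 1e-10
        assert abs(p - float(sps.chi2.sf(chi2_o, (k - 1) ** 2))) < 1e-10
        assert abs(ag.contingency_coefficient(t) - np.sqrt(chi2_o / (chi2_o + n))) < 1e-10
        # kappa from first principles
        pm = counts / n
        po = np.trace(pm)
        pe = float(pm.sum(1) @ pm.sum(0))
        assert abs(ag.cohen_kappa(t)[0] - (po - pe) / (1 - pe)) < 1e-10
        assert abs(ag.percent_agreement(t) - 100 * po) < 1e-10
        if k == 2:
            b, c = int(counts[0, 1]), int(counts[1, 0])
            m = ag.mcnemar(t)
            assert abs(m.diff_percent - 100 * (c - b) / n) < 1e-10
            assert abs(m.chi_square_cc - (abs(b - c) - 1) ** 2 / (b + c)) < 1e-10
            p_exact = min(1.0, 2 * sps.binom.cdf(min(b, c), b + c, 0.5))
            assert abs(m.p_exact - p_exact) < 1e-10


def test_contingency_coefficient_bound():
    rng = np.random.default_rng(9)
    for _ in range(20):
        k = int(rng.integers(2, 5))
        t = ag.ContingencyTable(rng.integers(1, 50, size=(k, k)),
                                tuple(map(str, range(k))), tuple(map(str, range(k))))
        c = ag.contingency_coefficient(t)
        assert 0 <= c < np.sqrt((k - 1) / k)


def test_invalid_tables_rejected():
    with pytest.raises(ValueError):
        ag.ContingencyTable(np.array([[1, -1], [0, 2]]), ("a", "b"), ("x", "y"))
    with pytest.raises(ValueError):
        ag.ContingencyTable(np.zeros((2, 2), dtype=int), ("a", "b"), ("x", "y"))
    t = ag.ContingencyTable(np.array([[1, 2, 3], [4, 5, 6]]), ("a", "b"), ("x", "y", "z"))
    with pytest.raises(ValueError):
        ag.cohen_kappa(t)
    with pytest.raises(KeyError):
        ag.collapse(t, {"a": "g"})
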