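"""Association-statistic primitives against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import epigrn as eg
from epigrn import UndefinedStatisticError


def brute_force_somers_d(score, label):
    """O(n^2) pairwise concordance over all cross-class pairs."""
    score = np.asarray(score, float)
    label = np.asarray(label, int)
    pos = score[label == 1]
    neg = score[label == 0]
    conc = disc = 0
    for a in pos:
        for b in neg:
            if a > b:
                conc += 1
            elif a < b:
                disc += 1
    return (conc - disc) / (len(pos) * len(neg))


def rank_then_pearson(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSomersD:
    def test_perfect_separation(self):
        res = eg.somers_d([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.d == 1.0 and res.auc == 1.0

    def test_zero_concordance_example(self):
        # brute force over the 4 cross pairs gives 2 concordant, 2 discordant
        res = eg.somers_d([3, 1, 2, 4], [0, 1, 0, 1])
        assert res.d == 0.0 and res.auc == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n = rng.integers(4, 51)
            score = rng.choice(np.arange(10), size=n).astype(float)  # ties
            label = rng.integers(0, 2, size=n)
            if label.min() == label.max():
                label[0] = 1 - label[0]
            res = eg.somers_d(score, label)
            assert res.d == pytest.approx(brute_force_somers_d(score, label),
                                          abs=1e-12)
            assert res.auc == pytest.approx((res.d + 1) / 2, abs=1e-12)

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            eg.somers_d([1.0, 2.0, 3.0], [1, 1, 1])


class TestSpearman:
    def test_monotone(self):
        assert eg.spearman_rho([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_known_permutation(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 6
        assert eg.spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_matches_rank_then_pearson_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = rng.integers(3, 40)
            x = rng.choice(np.arange(8), size=n).astype(float)
            y = rng.choice(np.arange(8), size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert eg.spearman_rho(x, y) == pytest.approx(
                rank_then_pearson(x, y), abs=1e-12
            )

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            eg.spearman_rho([1, 1, 1], [1, 2, 3])


class TestFisherZ:
    def test_null_center(self):
        res = eg.fisher_z_test(0.0, 50)
        assert res.z == 0.0 and res.p == 1.0

    def test_closed_form(self):
        # atanh(0.5) * sqrt(100)
        res = eg.fisher_z_test(0.5, 103)
        assert res.z == pytest.approx(np.arctanh(0.5) * 10, abs=1e-9)
        assert res.z == pytest.approx(5.493, abs=1e-3)

    def test_sign_symmetry(self):
        a = eg.fisher_z_test(0.5, 103)
        b = eg.fisher_z_test(-0.5, 103)
        assert b.z == -a.z and b.p == a.p

    def test_perfect_correlation_flagged(self):
        res = eg.fisher_z_test(1.0, 20)
        assert res.infinite and res.p == 0.0 and np.isinf(res.z)

    def test_p_monotone_in_abs_z(self):
        stats = [0.1, 0.3, 0.5, 0.7, 0.9]
        results = [eg.fisher_z_test(s, 30) for s in stats]
        zs = [abs(r.z) for r in results]
        ps = [r.p for r in results]
        assert zs == sorted(zs)
        assert ps == sorted(ps, reverse=True)


def step_up_oracle(p):
    """Literal BH: find largest k with p_(k) <= k/m * q by scanning q."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, p[order[i]] * m / (i + 1))
        adj[order[i]] = prev
    return adj


class TestBHAdjust:
    def test_stairstep_example(self):
        out = eg.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert eg.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = rng.integers(1, 21)
            p = rng.random(m)
            assert np.allclose(eg.bh_adjust(p), step_up_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(Exception):
            eg.bh_adjust([0.5, 1.5])


class TestProportionsZ:
    def test_known_value(self):
        # pooled p = 0.5, se = sqrt(0.25 * 0.05)
        z, p = eg.proportions_ztest(30, 40, 10, 40)
        assert z == pytest.approx(4.4721, abs=1e-3)

    def test_equal_proportions(self):
        z, p = eg.proportions_ztest(5, 20, 5, 20)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = eg.proportions_ztest(12, 30, 4, 25)
        z2, p2 = eg.proportions_ztest(4, 25, 12, 30)
        assert z2 == pytest.approx(-z1) and p2 == pytest.approx(p1)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest as sm_ztest
        rng = np.random.default_rng(5)
        for _ in range(50):
            na, nb = rng.integers(5, 60, size=2)
            ka, kb = rng.integers(1, na), rng.integers(1, nb)
            z, p = eg.proportions_ztest(int(ka), int(na), int(kb), int(nb))
            z_sm, p_sm = sm_ztest([ka, kb], [na, nb])
            assert z == pytest.approx(z_sm, abs=1e-9)
            assert p == pytest.approx(p_sm, abs=1e-9)

    def test_degenerate_pool(self):
        with pytest.raises(UndefinedStatisticError):
            eg.proportions_ztest(0, 10, 0, 10)


class TestStatProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 6), min_size=4, max_size=40),
           st.data())
    def test_somers_d_bounds_and_auc_relation(self, scores, data):
        labels = data.draw(st.lists(
            st.integers(0, 1), min_size=len(scores), max_size=len(scores)
        ))
        if min(labels) == max(labels):
            labels[0] = 1 - labels[0]
        res = eg.somers_d(np.array(scores, float), np.array(labels))
        assert -1.0 <= res.d <= 1.0
        assert res.auc == pytest.approx((res.d + 1) / 2, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=25))
    def test_bh_bounds_and_order_preservation(self, p):
        adj = eg.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        # adjustment preserves the significance ordering
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 9), min_size=3, max_size=30),
           st.data())
    def test_spearman_symmetry(self, x, data):
        y = data.draw(st.lists(st.integers(0, 9), min_size=len(x),
                               max_size=len(x)))
        x, y = np.array(x, float), np.array(y, float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert eg.spearman_rho(x, y) == pytest.approx(
            eg.spearman_rho(y, x), abs=1e-12
        )
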