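"""w-scores, change rates, t-tests, ANOVA and FDR control."""

import numpy as np
import pytest
from scipy import stats as sps

from murivol.stats import (anova_bonferroni, bh_fdr, change_rate, fit_wscore,
                           paired_test, unpaired_test, wscore)


class TestWScore:
    def test_reference_scores_standardized(self, rng):
        t = rng.uniform(400, 500, size=12)
        v = 0.05 * t + rng.normal(0, 0.4, size=12)
        model = fit_wscore(v, t)
        w = model.wscore(v, t)
        assert abs(w.mean()) < 1e-10
        assert w.std(ddof=1) == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        """Four hand-picked points against the closed-form OLS solution."""
        t = np.array([400.0, 430.0, 460.0, 500.0])
        v = np.array([20.0, 21.5, 21.9, 23.4])
        n = len(t)
        b1 = (n * (t * v).sum() - t.sum() * v.sum()) / (n * (t * t).sum() - t.sum() ** 2)
        b0 = v.mean() - b1 * t.mean()
        model = fit_wscore(v, t)
        assert model.beta1 == pytest.approx(b1, rel=1e-10)
        assert model.beta0 == pytest.approx(b0, rel=1e-10)

    def test_collinear_reference_raises(self):
        t = np.array([400.0, 450.0, 500.0, 520.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_wscore(0.1 * t, t)

    def test_unit_residual_displacement(self, rng):
        t = rng.uniform(400, 500, size=10)
        v = 0.05 * t + rng.normal(0, 0.5, size=10)
        model = fit_wscore(v, t)
        v_new = model.beta0 + model.beta1 * 450.0 + model.resid_mean + model.resid_sd
        assert wscore(model, v_new, 450.0) == pytest.approx(1.0)
        v_center = model.beta0 + model.beta1 * 450.0 + model.resid_mean
        assert wscore(model, v_center, 450.0) == pytest.approx(0.0)

    def test_too_few_reference_subjects(self):
        with pytest.raises(ValueError):
            fit_wscore([1.0, 2.0], [400.0, 500.0])


class TestChangeRate:
    def test_exact_line(self):
        t = np.array([4.5, 5.5, 7.5])
        fit = change_rate(t, 10.0 - 0.5 * t)
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-10)

    def test_two_point_slope(self):
        fit = change_rate([4.5, 7.5], [10.0, 8.5])
        assert fit.slope == pytest.approx(-0.5)
        assert fit.intercept == pytest.approx(10.0)

    def test_single_timepoint_raises(self):
        with pytest.raises(ValueError):
            change_rate([4.5, 4.5], [1.0, 2.0])

    def test_slope_standard_error_closed_form(self, rng):
        """Empirical slope SD over replicates matches sigma/sqrt(Sxx)."""
        t = np.array([4.5, 5.5, 7.5])
        sigma = 0.3
        slopes = []
        for _ in range(1000):
            v = 10.0 - 0.5 * t + rng.normal(0, sigma, size=3)
            slopes.append(change_rate(t, v).slope)
        expect = sigma / np.sqrt(((t - t.mean()) ** 2).sum())
        assert np.std(slopes, ddof=1) == pytest.approx(expect, rel=0.08)
        assert np.mean(slopes) == pytest.approx(-0.5, abs=4 * expect / np.sqrt(1000))


class TestTTests:
    def test_identical_pairs_flagged(self):
        r = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p == 1.0 and r.degenerate

    def test_constant_offset_pairs_flagged_zero_p(self):
        r = paired_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.p == 0.0 and r.degenerate

    def test_paired_matches_textbook_formula(self):
        a = np.array([5.1, 4.8, 6.0, 5.5, 5.9])
        b = np.array([4.6, 4.9, 5.2, 5.1, 5.3])
        d = a - b
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t_stat), len(d) - 1)
        r = paired_test(a, b)
        assert r.statistic == pytest.approx(t_stat, rel=1e-10)
        assert r.p == pytest.approx(p, rel=1e-10)

    def test_unpaired_matches_pooled_formula(self):
        a = np.array([3.2, 3.9, 4.1, 3.6])
        b = np.array([2.8, 3.0, 3.3, 2.5, 3.1])
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        r = unpaired_test(a, b)
        assert r.statistic == pytest.approx(t_stat, rel=1e-10)
        assert r.df == na + nb - 2

    def test_one_tailed_halves_p(self, rng):
        a = rng.normal(1.0, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        two = unpaired_test(a, b)
        one = unpaired_test(a, b, alternative="greater")
        assert one.p == pytest.approx(two.p / 2, rel=1e-10)


class TestAnovaBonferroni:
    def test_overwhelming_separation(self, rng):
        groups = [rng.normal(0, 0.1, 8), rng.normal(5, 0.1, 8), rng.normal(10, 0.1, 8)]
        res = anova_bonferroni(groups)
        assert res["anova"].p < 1e-10
        assert all(t.p_adjusted < 1e-3 for t in res["pairs"].values())

    def test_bonferroni_factor_is_pair_count(self, rng):
        groups = [rng.normal(0, 1, 6) for _ in range(3)]
        res = anova_bonferroni(groups)
        for t in res["pairs"].values():
            assert t.p_adjusted == pytest.approx(min(1.0, t.p * 3))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0], [1.0, 2.0]])


def bh_oracle(p, q):
    """Literal step-up: largest i with p_(i) <= i*q/m rejected, plus the
    standard monotone adjusted p."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(ranked <= thresh)[0]
    k = passing.max() + 1 if passing.size else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out, reject


class TestBHFDR:
    def test_stepup_enumeration(self):
        """All of [.01, .02, .03, .04] pass p_(i) <= i * 0.05 / 4."""
        adj, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_null_board(self):
        adj, reject = bh_fdr([1.0] * 6, q=0.05)
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_matches_bruteforce_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.random(m)
            adj, reject = bh_fdr(p, q=0.05)
            adj_o, reject_o = bh_oracle(p, 0.05)
            assert np.allclose(adj, adj_o)
            assert np.array_equal(reject, reject_o)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.random(25)
        adj, _ = bh_fdr(p, 0.05)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
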