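"""Mann-Whitney arm, empirical-Bayes moderated t, and BH adjustment."""

import numpy as np
import pytest
from scipy import optimize, special, stats

from lipidmets.diffabund import (
    bh_adjust,
    fit_moderated,
    mann_whitney_all,
    mann_whitney_test,
)
from conftest import make_matrix


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        # a fully below b: U = 0; 2 of the C(4,2)=6 equally likely labelings
        # are at least as extreme, so the exact two-sided p is 1/3
        u, p = mann_whitney_test([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1, 2])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=40), rng.normal(0.5, 1, 35)
        u1, p1 = mann_whitney_test(a, b)
        u2, p2 = mann_whitney_test(np.exp(a), np.exp(b))
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_null_rejection_rate_calibrated(self):
        """Large-sample null: rejection rate at alpha=0.05 stays inside the
        binomial 99% band over 1000 features."""
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(1000, 200)))
        res = mann_whitney_all(m)
        rate = (res.table["p"] < 0.05).mean()
        band = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < band


class TestBH:
    def test_hand_stepup_vectors(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_adjust([0.001, 0.5]), [0.002, 0.5])
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_monotone_in_rank_order_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1).all() and (q >= p).all()

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestModerated:
    def _matrix(self, x1, x2):
        vals = np.hstack([x1, x2])
        n1, n2 = x1.shape[1], x2.shape[1]
        return make_matrix(vals, group=[1] * n1 + [0] * n2, scale="log")

    def test_d0_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=(30, 12)), rng.normal(size=(30, 15))
        model = fit_moderated(self._matrix(x1, x2), d0_override=0)
        t_ref, p_ref = stats.ttest_ind(x1, x2, axis=1, equal_var=True)
        assert np.allclose(model.table["t"], t_ref, atol=1e-12)
        assert np.allclose(model.table["p"], p_ref, atol=1e-12)

    def test_equal_variances_moderation_is_noop(self):
        """When every feature has exactly the same sample variance the
        estimated prior makes shrinkage a no-op."""
        rng = np.random.default_rng(4)
        base = rng.normal(size=24)
        # same residuals for all features, different shifts
        vals = np.vstack([base + s for s in np.linspace(0, 3, 40)])
        model = fit_moderated(make_matrix(vals, group=[0, 1] * 12, scale="log"))
        assert np.allclose(model.table["s_tilde_sq"], model.table["s2"], atol=1e-6)

    def test_three_feature_toy_matches_formula_oracle(self):
        """s_tilde on a 3-feature toy equals an independent evaluation of
        (d0*s0^2 + d*s2)/(d0 + d) with (d0, s0^2) re-derived from scratch."""
        x1 = np.array([[0.0, 1.0, 2.0], [0.0, 2.0, 4.0], [0.0, 3.0, 6.0]])
        x2 = np.array([[5.0, 6.0, 7.0], [5.0, 7.0, 9.0], [5.0, 8.0, 11.0]])
        model = fit_moderated(self._matrix(x1, x2))
        d = 4
        s2 = model.table["s2"].to_numpy()
        assert np.allclose(s2, [1.0, 4.0, 9.0])
        # independent moment-matching oracle via brentq on the trigamma eq.
        e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
        target = e.var(ddof=1) - special.polygamma(1, d / 2)
        x0 = optimize.brentq(lambda x: special.polygamma(1, x) - target, 1e-6, 1e6)
        d0 = 2 * x0
        s0 = np.exp(e.mean() + special.digamma(x0) - np.log(x0))
        assert model.d0 == pytest.approx(d0, rel=1e-6)
        assert model.s0_sq == pytest.approx(s0, rel=1e-6)
        expected = (d0 * s0 + d * s2) / (d0 + d)
        assert np.allclose(model.table["s_tilde_sq"], expected, rtol=1e-6)

    def test_shrinkage_lies_between_s2_and_prior(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(60, 20)) * rng.uniform(0.2, 3, size=(60, 1))
        model = fit_moderated(make_matrix(vals, group=[0] * 10 + [1] * 10, scale="log"))
        lo = np.minimum(model.table["s2"], model.s0_sq)
        hi = np.maximum(model.table["s2"], model.s0_sq)
        assert ((model.table["s_tilde_sq"] >= lo - 1e-12)
                & (model.table["s_tilde_sq"] <= hi + 1e-12)).all()

    def test_small_group_errors_and_zero_variance_excluded(self):
        with pytest.raises(ValueError):
            fit_moderated(make_matrix(np.ones((3, 3)), group=[0, 0, 1], scale="log"))
        vals = np.vstack([np.ones(10), np.random.default_rng(6).normal(size=10)])
        model = fit_moderated(make_matrix(vals, group=[0] * 5 + [1] * 5, scale="log"))
        assert model.excluded == ["f0"]
        assert list(model.table.index) == ["f1"]


def test_power_both_arms_recover_planted_effects(small_cohort):
    """Planted log2fc=1 effects at n=40/group are recovered by both arms
    at FDR < 0.001 with high sensitivity."""
    from lipidmets.preprocess import impute_and_center, log_transform

    centered = impute_and_center(small_cohort.lipids)
    mw = mann_whitney_all(centered)
    mod = fit_moderated(log_transform(centered)).result()
    truth = small_cohort.truth & set(centered.feature_ids)
    assert len(mw.selected & truth) >= 0.9 * len(truth)
    assert len(mod.selected & truth) >= 0.9 * len(truth)
    for res in (mw, mod):
        assert (res.table.loc[list(res.selected), "q"] < 0.001).all()
        assert (res.table["q"] >= res.table["p"] - 1e-15).all()
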