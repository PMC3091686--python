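import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tc2tf import diffexp
from tests.conftest import make_dataset


def bh_oracle(p):
    """Brute-force step-up enumeration: q_(i) = min_{j>=i}(p_(j) * m / j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        best = min(p[order[j]] * m / (j + 1) for j in range(pos, m))
        q[i] = min(best, 1.0)
    return q


def _design(n_rep=3, times=(0.0, 6.0, 24.0)):
    rows = []
    for gt in ("wt", "ko"):
        for rep in range(1, n_rep + 1):
            for t in times:
                rows.append((f"{gt}_t{int(t)}_r{rep}", gt, t, rep))
    return rows


class TestFitCellMeans:
    def test_identical_replicates_give_zero_variance_exact_means(self):
        rows = _design()
        cell_value = {("wt", 0.0): 1.0, ("wt", 6.0): 4.0, ("wt", 24.0): 2.0,
                      ("ko", 0.0): 3.0, ("ko", 6.0): 5.0, ("ko", 24.0): 6.0}
        vals = {sid: [cell_value[(gt, t)]] for sid, gt, t, _ in rows}
        ds = make_dataset(vals, rows, ["p_a"])
        fit = diffexp.fit_cell_means(ds)
        assert fit.s2.iloc[0] == 0.0
        assert fit.df == 12  # 6 cells x (3 - 1)
        assert fit.means.loc["p_a", ("wt", 6.0)] == 4.0

    def test_singleton_cell_contributes_mean_but_no_df(self):
        rows = _design(n_rep=1, times=(0.0, 6.0))
        rows += [("wt_t0_r2", "wt", 0.0, 2), ("wt_t6_r2", "wt", 6.0, 2),
                 ("ko_t0_r2", "ko", 0.0, 2), ("ko_t6_r2", "ko", 6.0, 2)]
        vals = {sid: [1.0] for sid, _, _, _ in rows}
        ds = make_dataset(vals, rows, ["p_a"])
        fit = diffexp.fit_cell_means(ds)
        assert fit.df == 4  # 4 cells x (2 - 1)


class TestInteractionContrast:
    def _fit_from_means(self, means, n=3):
        cells = list(means)
        mf = pd.DataFrame([list(means.values())],
                          index=["g"],
                          columns=pd.MultiIndex.from_tuples(cells))
        return diffexp.LinearFit(means=mf, s2=pd.Series([1.0], index=["g"]),
                                 df=8, cell_counts={c: n for c in cells})

    def test_printed_formula_arithmetic(self):
        fit = self._fit_from_means({("ko", 6.0): 5.0, ("ko", 0.0): 3.0,
                                    ("wt", 6.0): 6.0, ("wt", 0.0): 2.0})
        c, v = diffexp.interaction_contrast(fit, 6.0)
        assert c.iloc[0] == pytest.approx(-2.0)

    def test_identical_response_cancels(self):
        fit = self._fit_from_means({("ko", 6.0): 9.0, ("ko", 0.0): 4.0,
                                    ("wt", 6.0): 8.0, ("wt", 0.0): 3.0})
        c, _ = diffexp.interaction_contrast(fit, 6.0)
        assert c.iloc[0] == pytest.approx(0.0)

    def test_scale_factor_is_sum_of_reciprocal_counts(self):
        fit = self._fit_from_means({("ko", 6.0): 0, ("ko", 0.0): 0,
                                    ("wt", 6.0): 0, ("wt", 0.0): 0}, n=3)
        _, v = diffexp.interaction_contrast(fit, 6.0)
        assert v == pytest.approx(4.0 / 3.0)

    def test_t0_rejected(self):
        fit = self._fit_from_means({("ko", 6.0): 0, ("ko", 0.0): 0,
                                    ("wt", 6.0): 0, ("wt", 0.0): 0})
        with pytest.raises(ValueError, match="t=0"):
            diffexp.interaction_contrast(fit, 0.0)


class TestVariancePrior:
    def test_underdispersed_ensemble_gives_infinite_d0(self):
        rng = np.random.default_rng(0)
        d = 16
        s2 = np.exp(rng.normal(0, 0.01, size=500))  # far less spread than chi2
        prior = diffexp.estimate_variance_prior(s2, d)
        assert math.isinf(prior.d0)

    def test_d0_zero_reproduces_ordinary_t(self):
        rows = _design()
        rng = np.random.default_rng(1)
        vals = {sid: rng.normal(size=60).tolist() for sid, _, _, _ in rows}
        ds = make_dataset(vals, rows, [f"p_{i}" for i in range(60)])
        fit = diffexp.fit_cell_means(ds)
        stats0 = diffexp.moderated_stats(
            fit, 6.0, prior=diffexp.VariancePrior(d0=0.0, s0_sq=123.0))
        c, v = diffexp.interaction_contrast(fit, 6.0)
        t_ord = c / np.sqrt(fit.s2 * v)
        np.testing.assert_allclose(stats0["t"], t_ord, rtol=1e-12)

    def test_infinite_d0_pins_variance_at_prior(self):
        rows = _design()
        rng = np.random.default_rng(2)
        vals = {sid: rng.normal(size=60).tolist() for sid, _, _, _ in rows}
        ds = make_dataset(vals, rows, [f"p_{i}" for i in range(60)])
        fit = diffexp.fit_cell_means(ds)
        prior = diffexp.VariancePrior(d0=math.inf, s0_sq=0.5)
        stats = diffexp.moderated_stats(fit, 6.0, prior=prior)
        c, v = diffexp.interaction_contrast(fit, 6.0)
        np.testing.assert_allclose(stats["t"], c / np.sqrt(0.5 * v),
                                   rtol=1e-12)

    def test_moderated_t_interpolates_between_limits(self):
        rows = _design()
        rng = np.random.default_rng(3)
        vals = {sid: rng.normal(size=80).tolist() for sid, _, _, _ in rows}
        ds = make_dataset(vals, rows, [f"p_{i}" for i in range(80)])
        fit = diffexp.fit_cell_means(ds)
        s0 = float(fit.s2.median())
        t_lo = diffexp.moderated_stats(
            fit, 6.0, prior=diffexp.VariancePrior(0.0, s0))["t"]
        t_hi = diffexp.moderated_stats(
            fit, 6.0, prior=diffexp.VariancePrior(math.inf, s0))["t"]
        t_mid = diffexp.moderated_stats(
            fit, 6.0, prior=diffexp.VariancePrior(8.0, s0))["t"]
        lo = np.minimum(np.abs(t_lo), np.abs(t_hi))
        hi = np.maximum(np.abs(t_lo), np.abs(t_hi))
        assert ((np.abs(t_mid) >= lo - 1e-9)
                & (np.abs(t_mid) <= hi + 1e-9)).all()

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            diffexp.estimate_variance_prior(np.zeros(100), 16)

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(4)
        s2 = rng.chisquare(8, size=200) / 8
        fit = diffexp.LinearFit(
            means=pd.DataFrame(index=range(200)), s2=pd.Series(s2),
            df=8, cell_counts={})
        prior = diffexp.estimate_variance_prior(s2, 8)
        post = diffexp.posterior_variances(fit, prior)
        lo = np.minimum(s2, prior.s0_sq)
        hi = np.maximum(s2, prior.s0_sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert diffexp.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            diffexp.bh_adjust([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(diffexp.bh_adjust([1.0] * 5),
                                      [1.0] * 5)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        q = diffexp.bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexp.bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=25))
    def test_matches_bruteforce_enumeration(self, p):
        np.testing.assert_allclose(diffexp.bh_adjust(p), bh_oracle(p),
                                   atol=1e-12)


class TestSelectSignificant:
    def test_null_data_selects_almost_nothing(self):
        rows = _design()
        rng = np.random.default_rng(6)
        n = 300
        vals = {sid: rng.normal(size=n).tolist() for sid, _, _, _ in rows}
        ds = make_dataset(vals, rows, [f"p_{i}" for i in range(n)])
        fit = diffexp.fit_cell_means(ds)
        out = diffexp.select_significant(fit, alpha=0.05)
        assert out["significant"].mean() < 0.02

    def test_stricter_alpha_selects_subset(self):
        rows = _design()
        rng = np.random.default_rng(7)
        n = 200
        base = rng.normal(size=n)
        vals = {}
        for sid, gt, t, _ in rows:
            v = base + rng.normal(0, 0.2, size=n)
            if gt == "ko" and t == 24.0:
                v = v + np.where(np.arange(n) < 30, 1.5, 0.0)
            vals[sid] = v.tolist()
        ds = make_dataset(vals, rows, [f"p_{i}" for i in range(n)])
        fit = diffexp.fit_cell_means(ds)
        loose = diffexp.select_significant(fit, alpha=0.05)
        strict = diffexp.select_significant(fit, alpha=0.01)
        sig_loose = set(loose[loose.significant].set_index(
            ["gene_id", "time_h"]).index)
        sig_strict = set(strict[strict.significant].set_index(
            ["gene_id", "time_h"]).index)
        assert sig_strict <= sig_loose
        assert len(sig_loose) >= 20
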