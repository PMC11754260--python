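"""Estimator tests: closed forms vs independent oracles, thresholds, ranking."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pvsignal.contingency import ContingencyTable
from pvsignal.signal_stats import (
    BcpnnPriors,
    DEFAULT_PRIORS,
    apply_thresholds,
    bcpnn,
    bcpnn_posterior_moments,
    compute_signals,
    prr,
    rank_by_ic,
    ror,
)

cells = st.integers(min_value=1, max_value=5000)


class TestRor:
    def test_proportional_table_is_one(self):
        assert ror(ContingencyTable(10, 90, 100, 900)).ror == pytest.approx(1.0)

    def test_ci_closed_form(self):
        # frozen from independent evaluation of exp(ln OR +/- 1.96*se),
        # se = sqrt(1/a+1/b+1/c+1/d)
        res = ror(ContingencyTable(10, 90, 100, 900))
        assert res.se == pytest.approx(0.3496029493900505, rel=1e-12)
        assert res.ci_low == pytest.approx(0.5039784444345278, rel=1e-12)
        assert res.ci_high == pytest.approx(1.9842118468420147, rel=1e-12)

    def test_bootstrap_agrees_with_analytic_se(self):
        # nonparametric bootstrap of the 2x2 multinomial: sd of ln ROR
        # should approximate the analytic Wald SE
        a, b, c, d = 10, 90, 100, 900
        n = a + b + c + d
        rng = np.random.default_rng(42)
        draws = rng.multinomial(n, np.array([a, b, c, d]) / n, size=50_000).astype(float)
        A, B, C, D = draws.T
        ok = (A > 0) & (B > 0) & (C > 0) & (D > 0)
        boot_sd = np.log((A * D)[ok] / (B * C)[ok]).std()
        assert boot_sd == pytest.approx(ror(ContingencyTable(a, b, c, d)).se, rel=0.15)

    def test_zero_cell_is_non_evaluable(self):
        res = ror(ContingencyTable(0, 100, 100, 900))
        assert math.isnan(res.ror) and math.isnan(res.ci_low)

    def test_haldane_correction_makes_zero_cell_evaluable(self):
        res = ror(ContingencyTable(0, 100, 100, 900), continuity=True)
        assert res.ror == pytest.approx((0.5 * 900.5) / (100.5 * 100.5))

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_ci_brackets_estimate(self, a, b, c, d):
        res = ror(ContingencyTable(a, b, c, d))
        assert res.ci_low <= res.ror <= res.ci_high

    def test_strictly_increasing_in_a(self):
        vals = [ror(ContingencyTable(a, 50, 60, 700)).ror for a in range(1, 30)]
        assert all(x < y for x, y in zip(vals, vals[1:]))


class TestPrr:
    def test_proportional_table_is_one(self):
        assert prr(ContingencyTable(10, 90, 100, 900)).prr == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # 0.2 / 0.05 = 4
        assert prr(ContingencyTable(20, 80, 100, 1900)).prr == pytest.approx(4.0)

    def test_chisq_matches_scipy_yates(self):
        got = prr(ContingencyTable(20, 80, 100, 1900), yates=True).chisq
        want = stats.chi2_contingency([[20, 80], [100, 1900]], correction=True)[0]
        assert got == pytest.approx(want, rel=1e-12)

    def test_chisq_matches_scipy_uncorrected(self):
        got = prr(ContingencyTable(20, 80, 100, 1900), yates=False).chisq
        want = stats.chi2_contingency([[20, 80], [100, 1900]], correction=False)[0]
        assert got == pytest.approx(want, rel=1e-12)

    def test_independence_table_chisq_zero(self):
        assert prr(ContingencyTable(10, 90, 100, 900), yates=False).chisq == pytest.approx(0.0)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_chisq_random_tables_match_scipy(self, a, b, c, d):
        got = prr(ContingencyTable(a, b, c, d), yates=True).chisq
        want = stats.chi2_contingency([[a, b], [c, d]], correction=True)[0]
        assert got == pytest.approx(want, rel=1e-9)

    def test_strictly_increasing_in_a(self):
        vals = [prr(ContingencyTable(a, 50, 60, 700)).prr for a in range(1, 30)]
        assert all(x < y for x, y in zip(vals, vals[1:]))


class TestBcpnn:
    def test_exact_independence_gives_ic_zero(self):
        # a*N = (a+b)(a+c): 10*1000 = 100*100
        assert bcpnn(ContingencyTable(10, 90, 90, 810)).ic == pytest.approx(0.0)

    def test_a_zero_gives_neg_inf_ic_but_finite_posterior(self):
        res = bcpnn(ContingencyTable(0, 100, 100, 900))
        assert res.ic == -math.inf
        assert math.isfinite(res.eic) and math.isfinite(res.vic)

    def test_closed_form_tracks_exact_moments(self):
        # the closed forms are first-order approximations of the exact
        # posterior moments; at N=1000 they agree to a few hundredths
        t = ContingencyTable(25, 75, 75, 825)
        res = bcpnn(t)
        mean, var = bcpnn_posterior_moments(t)
        assert res.eic == pytest.approx(mean, abs=0.05)
        assert res.vic == pytest.approx(var, rel=0.05)

    def test_exact_moments_match_monte_carlo(self):
        # Monte-Carlo oracle: sample the three independent Beta posteriors
        t = ContingencyTable(25, 75, 75, 825)
        p = DEFAULT_PRIORS
        a, b, c, d = t.as_tuple()
        n = t.n
        g = p.gamma(a, b, c, d)
        rng = np.random.default_rng(7)
        m = 200_000
        ic = (
            np.log2(rng.beta(a + p.gamma11, n - a + g - p.gamma11, m))
            - np.log2(rng.beta(a + b + p.alpha1, n - (a + b) + p.alpha - p.alpha1, m))
            - np.log2(rng.beta(a + c + p.beta1, n - (a + c) + p.beta - p.beta1, m))
        )
        mean, var = bcpnn_posterior_moments(t)
        assert ic.mean() == pytest.approx(mean, abs=3 * ic.std(ddof=1) / math.sqrt(m))
        assert ic.var(ddof=1) == pytest.approx(var, rel=0.02)

    def test_eic_converges_to_ic_at_large_n(self):
        # fixed proportions, N = 1e7: prior influence vanishes
        scale = 10_000_000 / 1000
        t = ContingencyTable(25 * scale, 75 * scale, 75 * scale, 825 * scale)
        res = bcpnn(t)
        assert abs(res.eic - res.ic) < 0.01

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=1000, deadline=None)
    def test_vic_nonnegative(self, a, b, c, d):
        res = bcpnn(ContingencyTable(a, b, c, d))
        assert res.vic >= 0.0
        assert res.ic025 <= res.eic

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            BcpnnPriors(alpha=0.0)

    def test_gamma_recomputed_per_table(self):
        p = DEFAULT_PRIORS
        assert p.gamma(10, 90, 100, 800) != p.gamma(50, 50, 100, 800)


class TestThresholds:
    def frame(self, **overrides):
        row = dict(
            event="x", level="PT", stratum="overall", a=50, b=50, c=100, d=800,
            ror=2.0, ror_ci_low=1.5, ror_ci_high=3.0, se_ln_ror=0.1,
            prr=2.0, prr_ci_low=1.5, prr_ci_high=3.0, se_ln_prr=0.1,
            chisq=10.0, ic=1.0, eic=0.9, vic=0.04, ic025=0.5,
        )
        row.update(overrides)
        return pd.DataFrame([row])

    def test_all_three_true(self):
        out = apply_thresholds(self.frame())
        assert bool(out.loc[0, "all_three"])

    def test_a_below_three_blocks_ror_and_prr(self):
        out = apply_thresholds(self.frame(a=2, ror=100.0, ror_ci_low=50.0))
        assert not out.loc[0, "ror_signal"] and not out.loc[0, "prr_signal"]
        # BCPNN has no a-threshold
        assert bool(out.loc[0, "bcpnn_signal"])

    def test_ic025_exactly_zero_is_not_a_signal(self):
        out = apply_thresholds(self.frame(ic025=0.0))
        assert not out.loc[0, "bcpnn_signal"]

    def test_chisq_at_four_is_not_a_signal(self):
        out = apply_thresholds(self.frame(chisq=4.0))
        assert not out.loc[0, "prr_signal"]

    def test_ci_low_at_one_is_not_a_signal(self):
        out = apply_thresholds(self.frame(ror_ci_low=1.0, prr_ci_low=1.0))
        assert not out.loc[0, "ror_signal"] and not out.loc[0, "prr_signal"]

    def test_nan_statistic_flags_false(self):
        out = apply_thresholds(self.frame(ror_ci_low=float("nan")))
        assert not out.loc[0, "ror_signal"]

    @given(a=st.integers(0, 10))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_a(self, a):
        lo = apply_thresholds(self.frame(a=a)).loc[0]
        hi = apply_thresholds(self.frame(a=a + 1)).loc[0]
        for flag in ("ror_signal", "prr_signal", "bcpnn_signal", "all_three"):
            assert (not lo[flag]) or hi[flag]


class TestRankByIc:
    def frame(self):
        return pd.DataFrame(
            {
                "event": ["P1", "P2", "P3", "Device use issue", "P4"],
                "a": [5, 3, 9, 100, 2],
                "ic": [2.0, 2.0, 1.0, 5.0, 0.5],
            }
        )

    def test_excluded_terms_removed_before_topk(self):
        top = rank_by_ic(self.frame(), 3)
        assert "Device use issue" not in set(top["event"])

    def test_tie_broken_by_a_then_name(self):
        top = rank_by_ic(self.frame(), 2)
        assert list(top["event"]) == ["P1", "P2"]

    def test_k_larger_than_list(self):
        top = rank_by_ic(self.frame(), 50)
        assert len(top) == 4

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            rank_by_ic(self.frame(), 0)

    def test_injected_strong_signal_ranks_first(self, default_data, default_pipeline):
        _, target_ids, events = default_pipeline
        from pvsignal import contingency as ct

        tables = ct.tabulate(events, target_ids)
        sig = compute_signals(tables)
        top = rank_by_ic(sig, 10)
        # RR=8 on a rare PT dominates the ranking
        assert top.loc[0, "event"] == "Body height decreased"


class TestComputeSignals:
    def test_vectorized_matches_scalar(self, default_pipeline):
        from pvsignal import contingency as ct

        _, target_ids, events = default_pipeline
        tables = ct.tabulate(events, target_ids)
        sig = compute_signals(tables).set_index("event")
        for event in list(tables)[:25]:
            t = tables[event]
            r, p_, b_ = ror(t), prr(t), bcpnn(t)
            row = sig.loc[event]
            for got, want in [
                (row["ror"], r.ror), (row["ror_ci_low"], r.ci_low),
                (row["prr"], p_.prr), (row["chisq"], p_.chisq),
                (row["ic"], b_.ic), (row["ic025"], b_.ic025),
            ]:
                if isinstance(want, float) and math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=1e-12)

    def test_empty_input(self):
        out = compute_signals({})
        assert out.empty
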