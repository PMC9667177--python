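"""LOSO window selection, success contrasts, repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats, special

from ctxdecode.decoder import CHANCE_PCT, DecodingTimecourse
from ctxdecode.loso import (
    circular_max_bin_select,
    contrast_table,
    loso_select,
    one_sample_t,
    rm_anova,
    success_contrast,
)
from ctxdecode.permstats import NullDistribution


N_BINS = 20
TIMES = np.round(np.arange(N_BINS) * 0.05, 10)


def _null(rng, n_subj=6, n_iter=80, sd=4.0):
    acc = rng.normal(CHANCE_PCT, sd, (n_iter, n_subj, N_BINS))
    t = np.zeros((n_iter, N_BINS))  # rebuilt per fold by loso_select
    return NullDistribution(t=t, acc=acc, n_iter=n_iter, times=TIMES)


class TestLosoSelect:
    def test_strong_common_effect_selected_in_every_fold(self):
        rng = np.random.default_rng(0)
        acc = rng.normal(CHANCE_PCT, 2.0, (6, N_BINS))
        acc[:, 8:11] += 25.0  # strong effect at bins 8-10 (0.40-0.50 s)
        loso = loso_select(acc, _null(rng), TIMES, (0.40, 0.50), margin=0.2)
        for bins, fb in zip(loso.bins, loso.fallback):
            assert not fb
            assert set(bins) & {8, 9, 10}
            assert all(0.40 - 0.2 - 1e-9 <= TIMES[b] <= 0.50 + 0.2 + 1e-9
                       for b in bins)

    def test_selection_never_uses_left_out_subject(self):
        """Making the left-out subject wildly deviant must not change its
        own fold's selection."""
        rng = np.random.default_rng(1)
        acc = rng.normal(CHANCE_PCT, 2.0, (6, N_BINS))
        acc[:, 8:11] += 25.0
        null = _null(np.random.default_rng(2))
        a = loso_select(acc, null, TIMES, (0.40, 0.50))
        acc2 = acc.copy()
        acc2[3, :] = 95.0  # absurd values for subject 3 everywhere
        b = loso_select(acc2, null, TIMES, (0.40, 0.50))
        np.testing.assert_array_equal(a.bins[3], b.bins[3])

    def test_zero_signal_engages_fallback(self):
        rng = np.random.default_rng(3)
        acc = rng.normal(CHANCE_PCT, 4.0, (6, N_BINS))
        loso = loso_select(acc, _null(np.random.default_rng(4)), TIMES,
                           (0.40, 0.50), margin=0.1)
        center = int(np.argmin(np.abs(TIMES - 0.45)))
        for bins, fb in zip(loso.bins, loso.fallback):
            if fb:
                np.testing.assert_array_equal(bins, [center])

    def test_zero_margin_keeps_selection_inside_reference(self):
        rng = np.random.default_rng(5)
        acc = rng.normal(CHANCE_PCT, 2.0, (6, N_BINS))
        acc[:, 6:14] += 25.0  # effect wider than the reference window
        loso = loso_select(acc, _null(rng), TIMES, (0.40, 0.50), margin=0.0)
        for bins in loso.bins:
            assert all(0.40 - 1e-9 <= TIMES[b] <= 0.50 + 1e-9 for b in bins)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            loso_select(rng.normal(CHANCE_PCT, 2, (2, N_BINS)),
                        _null(rng, n_subj=2), TIMES, (0.4, 0.5))


def _toy_tc(preds, tgt, success, subject="S01"):
    n_tr, n_bins = preds.shape
    ev = (preds == tgt[:, None]).mean(axis=0)
    return DecodingTimecourse(
        subject=subject, condition="DE", times=TIMES[:n_bins], accuracy=ev,
        evidence_target=ev, evidence_competitor=np.full(n_bins, np.nan),
        evidence_other=1 - ev, predictions=preds, target_idx=tgt,
        competitor_idx=np.full(n_tr, -1),
        metadata=pd.DataFrame({"success": success}),
    )


def _windows(bins, n_subj):
    from ctxdecode.loso import LosoWindows

    return LosoWindows(
        bins=[np.asarray(bins)] * n_subj,
        fallback=np.zeros(n_subj, bool),
        times=TIMES,
        reference_window=(TIMES[bins[0]], TIMES[bins[-1]]),
        margin=0.0,
    )


class TestSuccessContrast:
    def _cohort_tcs(self, rng, n_subj=5, n_tr=30, boost_success=0.0):
        tcs = []
        for s in range(n_subj):
            tgt = rng.integers(0, 3, n_tr)
            success = rng.random(n_tr) < 0.5
            preds = rng.integers(0, 3, (n_tr, N_BINS))
            if boost_success:
                hit = (rng.random((n_tr, N_BINS)) < boost_success) & success[:, None]
                preds[hit] = np.broadcast_to(tgt[:, None], preds.shape)[hit]
            tcs.append(_toy_tc(preds, tgt, success, subject=f"S{s:02d}"))
        return tcs

    def test_identical_outcome_series_give_t_zero(self):
        rng = np.random.default_rng(7)
        tcs = []
        for s in range(4):
            tgt = np.zeros(20, dtype=int)
            preds = np.zeros((20, N_BINS), dtype=int)  # always correct
            success = np.arange(20) < 10
            tcs.append(_toy_tc(preds, tgt, success, subject=f"S{s:02d}"))
        res = success_contrast(tcs, _windows([5, 6], 4), min_trials=5)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_gated_effect_detected(self):
        rng = np.random.default_rng(8)
        tcs = self._cohort_tcs(rng, boost_success=0.5)
        res = success_contrast(tcs, _windows([5, 6, 7], 5), min_trials=5)
        assert res.statistic > 0 and res.p < 0.05
        assert res.effect_size > 0

    def test_min_trials_exclusion_and_failure_when_too_few(self):
        rng = np.random.default_rng(9)
        tcs = self._cohort_tcs(rng, n_subj=4, n_tr=12)
        with pytest.raises(ValueError):
            success_contrast(tcs, _windows([5], 4), min_trials=11)

    def test_shuffled_outcomes_give_uniform_p(self):
        """Calibration: with outcome labels random, the contrast p-value is
        uniform on [0, 1] (KS test over replicates)."""
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(200):
            tcs = self._cohort_tcs(rng, n_subj=6, n_tr=24)
            res = success_contrast(tcs, _windows([5, 6], 6), min_trials=3)
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCircularVsLoso:
    def test_circular_selection_uses_all_subjects(self):
        rng = np.random.default_rng(11)
        acc = rng.normal(CHANCE_PCT, 3.0, (6, N_BINS))
        acc[:, 13] += 30.0
        win = circular_max_bin_select(acc, TIMES)
        for bins in win.bins:
            np.testing.assert_array_equal(bins, [13])


class TestOneSampleT:
    def test_values_at_mu_give_zero(self):
        res = one_sample_t(np.full(6, CHANCE_PCT))
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_two_point_closed_form(self):
        """Closed-form oracle for n=2: t = (mean-mu)/(sd/sqrt(2))."""
        vals = np.array([34.4, 38.4])
        res = one_sample_t(vals, mu=33.3)
        sd = np.std(vals, ddof=1)
        t_expect = (vals.mean() - 33.3) / (sd / np.sqrt(2))
        assert res.statistic == pytest.approx(t_expect)
        assert res.effect_size == pytest.approx((vals.mean() - 33.3) / sd)
        assert res.df == 1

    def test_mean_cohens_d_matches_noncentral_expectation(self):
        """E[d-hat] = d * sqrt((n-1)/2) * G((n-2)/2)/G((n-1)/2) for a normal
        sample (exact small-sample bias of mean/SD)."""
        rng = np.random.default_rng(12)
        n, d_true = 28, 0.85
        ds = []
        for _ in range(1000):
            x = rng.normal(35.0, 2.0, n)
            ds.append(one_sample_t(x, mu=33.3).effect_size)
        g = special.gammaln
        bias = np.sqrt((n - 1) / 2.0) * np.exp(g((n - 2) / 2) - g((n - 1) / 2))
        expect = d_true * bias
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - expect) < 3 * se

    def test_zero_variance_nonzero_difference_flagged_infinite(self):
        res = one_sample_t(np.full(5, 40.0), mu=33.3)
        assert np.isinf(res.statistic) and res.statistic > 0


class TestRmAnova:
    def test_pure_crossover_interaction(self):
        rng = np.random.default_rng(13)
        rows = []
        for s in range(8):
            off = rng.normal(0, 1)
            for a, b, v in [(0, 0, 1), (0, 1, -1), (1, 0, -1), (1, 1, 1)]:
                rows.append(
                    dict(subject=s, A=str(a), B=str(b),
                         y=off + v + rng.normal(0, 1e-4))
                )
        df = pd.DataFrame(rows)
        res = rm_anova(df, "y", within=["A", "B"])
        assert res.p < 1e-6  # interaction (highest-order term)
        main_a = res.table.loc["A", "F Value"]
        main_b = res.table.loc["B", "F Value"]
        assert main_a < 1.0 and main_b < 1.0
        assert res.table.loc["A:B", "eta_p2"] > 0.99

    def test_one_way_three_level_matches_ss_oracle(self):
        """Brute-force within-subject sums-of-squares oracle."""
        rng = np.random.default_rng(14)
        n_subj, levels = 10, 3
        y = rng.normal(0, 1, (n_subj, levels)) + np.array([0.0, 0.4, 0.9])
        rows = [
            dict(subject=s, A=str(a), y=y[s, a])
            for s in range(n_subj)
            for a in range(levels)
        ]
        res = rm_anova(pd.DataFrame(rows), "y", within=["A"])
        grand = y.mean()
        ss_a = n_subj * ((y.mean(0) - grand) ** 2).sum()
        ss_subj = levels * ((y.mean(1) - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_a - ss_subj
        f_expect = (ss_a / (levels - 1)) / (ss_err / ((levels - 1) * (n_subj - 1)))
        assert res.statistic == pytest.approx(f_expect, abs=1e-8)

    def test_single_two_level_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(15)
        n_subj = 12
        y = rng.normal(0, 1, (n_subj, 2)) + np.array([0.0, 0.5])
        rows = [
            dict(subject=s, A=str(a), y=y[s, a])
            for s in range(n_subj)
            for a in range(2)
        ]
        res = rm_anova(pd.DataFrame(rows), "y", within=["A"])
        t, _ = stats.ttest_rel(y[:, 1], y[:, 0])
        assert res.statistic == pytest.approx(t**2, abs=1e-8)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(16)
        n_rep = 300
        rejections = {"A": 0, "B": 0, "A:B": 0}
        for _ in range(n_rep):
            rows = [
                dict(subject=s, A=str(a), B=str(b), y=rng.normal())
                for s in range(8)
                for a in range(2)
                for b in range(2)
            ]
            res = rm_anova(pd.DataFrame(rows), "y", within=["A", "B"])
            for term in rejections:
                if res.table.loc[term, "Pr > F"] < 0.05:
                    rejections[term] += 1
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        for term, k in rejections.items():
            assert abs(k / n_rep - 0.05) < band + 0.01

    def test_missing_cells_rejected(self):
        df = pd.DataFrame(
            dict(subject=[0, 0, 1], A=["0", "1", "0"], y=[1.0, 2.0, 3.0])
        )
        with pytest.raises(ValueError):
            rm_anova(df, "y", within=["A"])


def test_contrast_table_layout():
    res = one_sample_t(np.array([34.0, 36.0, 35.0]), name="demo")
    tab = contrast_table([res])
    assert list(tab.columns) == ["effect", "stat", "df", "p", "effect_size", "n"]
    assert tab.loc[0, "effect"] == "demo"
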