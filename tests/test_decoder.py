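"""One-vs-all decoding: training, cross-validation, confusion handling,
searchlights, cross-phase timecourses and smoothing."""

import numpy as np
import pandas as pd
import pytest

import ctxdecode as cx
from ctxdecode.decoder import (
    CHANCE_PCT,
    ConfusionMatrix,
    DecodingTimecourse,
    accuracy,
    conditional_accuracy,
    cross_validate_10fold,
    decode_timecourse,
    frequency_groups,
    moving_average,
    normalize_confusion,
    predict_stack,
    searchlight_channels,
    searchlight_frequencies,
    smooth_timecourse,
    train_ova_linear,
)
from ctxdecode.tfr import FeatureMatrix


def _clouds(rng, n_per_class=12, n_feat=30, sep=8.0):
    """Three well-separated Gaussian clouds with labelled trials."""
    centers = rng.standard_normal((3, n_feat)) * sep
    X, y = [], []
    for ci, ctx in enumerate(cx.CONTEXTS):
        X.append(centers[ci] + rng.standard_normal((n_per_class, n_feat)))
        y += [ctx] * n_per_class
    X = np.vstack(X)
    fm = FeatureMatrix(X, [("CH01", float(f)) for f in range(n_feat)])
    return fm, np.array(y)


class TestTraining:
    def test_separable_clouds_reach_perfect_training_accuracy(self):
        fm, y = _clouds(np.random.default_rng(0))
        dec = train_ova_linear(fm, y)
        assert dec.coef.shape == (3, fm.n_features)
        pred = dec.predict(fm)
        assert (np.array(dec.classes)[pred] == y).all()

    def test_single_class_rejected(self):
        fm, _ = _clouds(np.random.default_rng(1))
        with pytest.raises(ValueError):
            train_ova_linear(fm, np.array(["city"] * fm.n_trials))

    def test_non_finite_features_rejected(self):
        fm, y = _clouds(np.random.default_rng(2))
        fm.values[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_ova_linear(fm, y)

    def test_duplicated_feature_columns_do_not_change_predictions(self):
        rng = np.random.default_rng(3)
        fm, y = _clouds(rng, sep=2.0)
        dup = FeatureMatrix(
            np.hstack([fm.values, fm.values]),
            fm.feature_index + [(c, f + 100) for c, f in fm.feature_index],
        )
        p1 = train_ova_linear(fm, y).predict(fm)
        p2 = train_ova_linear(dup, y).predict(dup)
        np.testing.assert_array_equal(p1, p2)

    def test_tie_breaks_to_lowest_class_index(self):
        dec = cx.TrainedDecoder(
            classes=list(cx.CONTEXTS),
            coef=np.zeros((3, 4)),
            intercept=np.zeros(3),
            norm_mean=np.zeros(4),
            norm_sd=np.ones(4),
            C=1.0,
        )
        fm = FeatureMatrix(np.ones((5, 4)), [("CH01", f) for f in range(4)])
        assert (dec.predict(fm) == 0).all()

    def test_prediction_invariant_to_consistent_feature_permutation(self):
        rng = np.random.default_rng(4)
        fm, y = _clouds(rng, sep=2.0)
        dec = train_ova_linear(fm, y)
        perm = rng.permutation(fm.n_features)
        fm_p = FeatureMatrix(fm.values[:, perm],
                             [fm.feature_index[i] for i in perm])
        dec_p = cx.TrainedDecoder(
            classes=dec.classes,
            coef=dec.coef[:, perm],
            intercept=dec.intercept,
            norm_mean=dec.norm_mean[perm],
            norm_sd=dec.norm_sd[perm],
            C=dec.C,
        )
        np.testing.assert_array_equal(dec.predict(fm), dec_p.predict(fm_p))


def test_decoder_roundtrip(tmp_path):
    fm, y = _clouds(np.random.default_rng(30))
    dec = train_ova_linear(fm, y)
    dec.save(tmp_path, "dec")
    back = cx.TrainedDecoder.load(tmp_path, "dec")
    np.testing.assert_array_equal(back.predict(fm), dec.predict(fm))
    assert back.classes == dec.classes
    assert back.feature_index == dec.feature_index


class TestCrossValidation:
    def test_separable_data_gives_diagonal_confusion(self):
        fm, y = _clouds(np.random.default_rng(5), n_per_class=10)
        conf = cross_validate_10fold(fm, y, seed=0)
        np.testing.assert_array_equal(
            conf.matrix, np.diag([10, 10, 10]).astype(float)
        )

    def test_fold_sizes_differ_by_at_most_one_for_n64(self):
        folds = np.array_split(np.random.default_rng(0).permutation(64), 10)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [6] * 6 + [7] * 4

    def test_each_trial_predicted_exactly_once(self):
        fm, y = _clouds(np.random.default_rng(6), n_per_class=7)
        conf = cross_validate_10fold(fm, y, seed=1)
        assert conf.matrix.sum() == fm.n_trials

    def test_fewer_trials_than_folds_rejected(self):
        fm, y = _clouds(np.random.default_rng(7), n_per_class=3)
        with pytest.raises(ValueError):
            cross_validate_10fold(fm, y.copy()[:9], n_folds=10)

    @pytest.mark.parametrize("C", [0.1, 1.0, 10.0])
    def test_regularization_insensitive_on_separable_data(self, C):
        """The decoding properties must not hinge on the (unreported)
        regularization constant: separable contexts decode perfectly for
        C in {0.1, 1, 10}."""
        fm, y = _clouds(np.random.default_rng(20), n_per_class=10)
        conf = cross_validate_10fold(fm, y, seed=2, C=C)
        assert accuracy(normalize_confusion(conf)) == 100.0

    def test_shuffled_labels_decode_at_chance(self):
        """Exchangeability: label-shuffled CV accuracy averages 1/3."""
        rng = np.random.default_rng(8)
        accs = []
        for s in range(30):
            fm, y = _clouds(rng, n_per_class=8, n_feat=10, sep=3.0)
            y = y[rng.permutation(len(y))]
            conf = cross_validate_10fold(fm, y, seed=s)
            accs.append(accuracy(normalize_confusion(conf)))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - CHANCE_PCT) < 3 * se + 1e-9


class TestConfusion:
    def test_worked_example(self):
        conf = ConfusionMatrix(
            np.array([[2.0, 1, 1], [0, 4, 0], [1, 1, 2]]), list(cx.CONTEXTS)
        )
        norm = normalize_confusion(conf)
        np.testing.assert_allclose(
            norm.matrix,
            [[0.5, 0.25, 0.25], [0, 1, 0], [0.25, 0.25, 0.5]],
        )
        assert accuracy(norm) == pytest.approx(100 * 2 / 3, abs=1e-9)

    def test_identity_counts(self):
        conf = ConfusionMatrix(np.eye(3) * 5, list(cx.CONTEXTS))
        norm = normalize_confusion(conf)
        np.testing.assert_allclose(norm.matrix, np.eye(3))
        assert accuracy(norm) == 100.0

    def test_uniform_matrix_is_chance(self):
        conf = ConfusionMatrix(np.full((3, 3), 1.0), list(cx.CONTEXTS))
        assert accuracy(normalize_confusion(conf)) == pytest.approx(CHANCE_PCT)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        conf = ConfusionMatrix(rng.integers(1, 10, (3, 3)).astype(float),
                               list(cx.CONTEXTS))
        norm = normalize_confusion(conf)
        np.testing.assert_allclose(norm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_row_rejected(self):
        conf = ConfusionMatrix(np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 1]]),
                               list(cx.CONTEXTS))
        with pytest.raises(ValueError):
            normalize_confusion(conf)

    def test_accuracy_requires_normalized_input(self):
        conf = ConfusionMatrix(np.eye(3), list(cx.CONTEXTS))
        with pytest.raises(ValueError):
            accuracy(conf)


class TestSearchlights:
    def test_self_only_adjacency_equals_per_channel_decoding(self):
        rng = np.random.default_rng(10)
        n_ch, n_f = 3, 4
        idx = [(f"CH{c + 1:02d}", float(f)) for c in range(n_ch)
               for f in range(n_f)]
        fm = FeatureMatrix(rng.standard_normal((30, n_ch * n_f)), idx)
        y = np.array(list(cx.CONTEXTS) * 10)
        adj = {f"CH{c + 1:02d}": set() for c in range(n_ch)}
        sl = searchlight_channels(fm, y, adj, seed=4)
        # manual per-channel decoding replaying the same rng stream
        rng2 = np.random.default_rng(4)
        for c in range(n_ch):
            keep = np.flatnonzero(
                [ch == f"CH{c + 1:02d}" for ch, _ in idx]
            )
            conf = cross_validate_10fold(fm.subset(keep), y, rng2)
            assert sl[f"CH{c + 1:02d}"] == pytest.approx(
                accuracy(normalize_confusion(conf))
            )

    def test_channel_searchlight_peaks_at_informative_channels(self):
        rng = np.random.default_rng(11)
        n_ch, n_f, n_per = 5, 3, 10
        y = np.array(list(cx.CONTEXTS) * n_per)
        X = rng.standard_normal((len(y), n_ch * n_f))
        # inject class separation into channels CH01 and CH02 only
        for ci, ctx in enumerate(cx.CONTEXTS):
            X[np.array(y) == ctx, : 2 * n_f] += 6.0 * (ci + 1)
        idx = [(f"CH{c + 1:02d}", float(f)) for c in range(n_ch)
               for f in range(n_f)]
        fm = FeatureMatrix(X, idx)
        adj = {f"CH{c + 1:02d}": set() for c in range(n_ch)}
        sl = searchlight_channels(fm, y, adj, seed=0)
        assert min(sl["CH01"], sl["CH02"]) > max(sl["CH04"], sl["CH05"])

    def test_frequency_groups_truncate_at_grid_ends(self):
        groups = frequency_groups([4.0, 5.0, 6.0, 7.0])
        assert groups[4.0] == [4.0, 5.0]
        assert groups[7.0] == [6.0, 7.0]
        assert groups[5.0] == [4.0, 5.0, 6.0]

    def test_frequency_searchlight_tracks_informative_band(self):
        rng = np.random.default_rng(12)
        freqs = [4.0, 5.0, 6.0, 20.0, 21.0]
        y = np.array(list(cx.CONTEXTS) * 10)
        X = rng.standard_normal((len(y), len(freqs)))
        for ci, ctx in enumerate(cx.CONTEXTS):
            X[np.array(y) == ctx, :2] += 6.0 * (ci + 1)  # 4-5 Hz informative
        fm = FeatureMatrix(X, [("CH01", f) for f in freqs])
        sl = searchlight_frequencies(fm, y, seed=0)
        assert sl[4.0] > sl[21.0]
        assert sl[4.0] > 80.0


def _toy_timecourse(preds, tgt, comp=None, success=None, times=None):
    n_tr, n_bins = preds.shape
    times = times if times is not None else np.arange(n_bins) * 0.05
    md = pd.DataFrame(
        {"success": success if success is not None else [True] * n_tr}
    )
    comp = comp if comp is not None else np.full(n_tr, -1)
    ev_t = (preds == tgt[:, None]).mean(axis=0)
    has = comp >= 0
    ev_c = (
        (preds[has] == comp[has, None]).mean(axis=0)
        if has.any()
        else np.full(n_bins, np.nan)
    )
    other = 1 - ev_t - np.nan_to_num(ev_c) if has.any() else 1 - ev_t
    return DecodingTimecourse(
        subject="S01", condition="AC", times=times, accuracy=ev_t,
        evidence_target=ev_t, evidence_competitor=ev_c, evidence_other=other,
        predictions=preds, target_idx=tgt, competitor_idx=comp, metadata=md,
    )


class TestTimecourse:
    def test_evidence_proportions_sum_to_one(self, cohort_hi_snr,
                                             encoding_features):
        from conftest import SMALL_FREQS

        feats, labels = encoding_features
        dec = train_ova_linear(feats[0], labels[0],
                               classes=sorted(set(labels[0])))
        ret = cohort_hi_snr.subjects["S01"]["retrieval"]
        rtfr = cx.morlet_tfr(ret, freqs=SMALL_FREQS)
        md = ret.metadata
        ac = (md["condition"] == "AC").to_numpy()
        from ctxdecode.tfr import TFRStack

        sub = TFRStack(rtfr.power[ac], rtfr.freqs, rtfr.times,
                       rtfr.channel_names, md[ac], rtfr.valid)
        tc = decode_timecourse(
            dec, sub, md.loc[ac, "context"].to_numpy(),
            md.loc[ac, "competitor"].to_numpy(),
        )
        s = tc.evidence_target + tc.evidence_competitor + tc.evidence_other
        np.testing.assert_allclose(s, 1.0, atol=1e-9)
        np.testing.assert_allclose(tc.accuracy, tc.evidence_target)

    def test_feature_space_mismatch_rejected(self):
        dec = cx.TrainedDecoder(
            classes=list(cx.CONTEXTS), coef=np.zeros((3, 5)),
            intercept=np.zeros(3), norm_mean=np.zeros(5),
            norm_sd=np.ones(5), C=1.0,
        )
        stack = np.zeros((4, 10, 7))
        with pytest.raises(ValueError):
            decode_timecourse(dec, None, np.array(["city"] * 4),
                              feature_stack=stack,
                              bin_times=np.arange(10) * 0.05)

    def test_conditional_accuracy_splits_by_mask(self):
        preds = np.array([[0, 0], [1, 1], [0, 1], [2, 2]])
        tgt = np.array([0, 1, 0, 0])
        tc = _toy_timecourse(preds, tgt,
                             success=[True, True, False, False])
        succ = conditional_accuracy(tc, np.array([1, 1, 0, 0], bool))
        np.testing.assert_allclose(succ, [100.0, 100.0])
        fail = conditional_accuracy(tc, np.array([0, 0, 1, 1], bool))
        np.testing.assert_allclose(fail, [50.0, 0.0])


class TestSmoothing:
    def test_constant_series_unchanged(self):
        preds = np.zeros((4, 9), dtype=int)
        tc = _toy_timecourse(preds, np.zeros(4, dtype=int))
        sm = smooth_timecourse(tc, window=0.1)
        np.testing.assert_allclose(sm.accuracy, tc.accuracy)
        assert sm.smoothed

    def test_impulse_spread_over_three_bins(self):
        x = np.zeros(9)
        x[4] = 1.0
        times = np.arange(9) * 0.05
        out = moving_average(x, times, window=0.1)
        np.testing.assert_allclose(out[3:6], [1 / 3] * 3)
        assert out[2] == 0 and out[6] == 0

    def test_matches_bruteforce_moving_average(self):
        rng = np.random.default_rng(13)
        x = rng.random(20)
        times = np.arange(20) * 0.05
        out = moving_average(x, times, window=0.1)
        for i in range(20):
            sel = [j for j in range(20) if abs(times[j] - times[i]) <= 0.05 + 1e-9]
            assert out[i] == pytest.approx(np.mean(x[sel]))

    def test_window_smaller_than_step_rejected(self):
        preds = np.zeros((2, 5), dtype=int)
        tc = _toy_timecourse(preds, np.zeros(2, dtype=int))
        with pytest.raises(ValueError):
            smooth_timecourse(tc, window=0.01)
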