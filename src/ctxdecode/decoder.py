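"""One-vs-all linear-margin context classification.

A linear SVM with a one-against-all strategy is trained on across-trial
normalized encoding features (one max-margin separator per context;
prediction is the argmax of the three decision values, ties broken by the
lowest class index).  The module provides 10-fold cross-validation with
row-normalized confusion matrices, channel/frequency searchlights, and
cross-phase application of the frozen encoding decoder to every bin of the
85-bin retrieval grid to produce per-subject reinstatement timecourses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .tfr import (
    RETRIEVAL_BIN_TIMES,
    FeatureMatrix,
    TFRStack,
    bin_features,
    normalize_across_trials,
)

logger = logging.getLogger(__name__)

CHANCE_PCT = 100.0 / 3.0


@dataclass
class TrainedDecoder:
    """Frozen one-vs-all linear decoder plus its normalization statistics."""

    classes: list[str]
    coef: np.ndarray  # (n_classes, n_features)
    intercept: np.ndarray  # (n_classes,)
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    C: float
    feature_index: list[tuple[str, float]] = field(default_factory=list)

    def decision_values(self, raw: FeatureMatrix) -> np.ndarray:
        """Per-class decision values on raw features (frozen z-score applied)."""
        if raw.n_features != self.coef.shape[1]:
            raise ValueError(
                f"feature-space mismatch: decoder has {self.coef.shape[1]}, "
                f"input has {raw.n_features}"
            )
        sd = np.where(self.norm_sd < 1e-12, 1.0, self.norm_sd)
        x = (raw.values - self.norm_mean) / sd
        x[:, self.norm_sd < 1e-12] = 0.0
        return x @ self.coef.T + self.intercept

    def predict(self, raw: FeatureMatrix) -> np.ndarray:
        """Predicted class indices; ties resolve to the lowest class index."""
        return np.argmax(self.decision_values(raw), axis=1)

    # ------------------------------------------------------------------ I/O
    def save(self, directory, stem: str) -> None:
        """JSON (classes, C, feature index) + array bundle (weights, stats)."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / f"{stem}.npz",
            coef=self.coef,
            intercept=self.intercept,
            norm_mean=self.norm_mean,
            norm_sd=self.norm_sd,
        )
        meta = {
            "classes": list(self.classes),
            "C": self.C,
            "feature_index": [[c, f] for c, f in self.feature_index],
        }
        (directory / f"{stem}.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory, stem: str) -> "TrainedDecoder":
        import json
        from pathlib import Path

        directory = Path(directory)
        arr = np.load(directory / f"{stem}.npz")
        meta = json.loads((directory / f"{stem}.json").read_text())
        return cls(
            classes=meta["classes"],
            coef=arr["coef"],
            intercept=arr["intercept"],
            norm_mean=arr["norm_mean"],
            norm_sd=arr["norm_sd"],
            C=meta["C"],
            feature_index=[(c, float(f)) for c, f in meta["feature_index"]],
        )


@dataclass
class ConfusionMatrix:
    """True-context x predicted-context counts or row proportions."""

    matrix: np.ndarray
    classes: list[str]
    normalized: bool = False

    @property
    def row_n(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def train_ova_linear(
    features: FeatureMatrix,
    labels: np.ndarray,
    C: float = 1.0,
    classes: list[str] | None = None,
) -> TrainedDecoder:
    """Train the one-vs-all linear SVM on raw features.

    Normalization statistics are computed here, on the training trials only,
    and frozen into the decoder.
    """
    labels = np.asarray(labels)
    if not np.all(np.isfinite(features.values)):
        raise ValueError("non-finite feature values")
    classes = list(classes) if classes is not None else sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to train")
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 trials per class, got {counts}")
    norm, _, (mean, sd) = normalize_across_trials(features)
    y = np.array([classes.index(l) for l in labels])
    svm = LinearSVC(C=C, dual="auto", max_iter=5000, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm.fit(norm.values, y)
    coef, intercept = svm.coef_, svm.intercept_
    if len(classes) == 2:  # liblinear collapses binary to a single scorer
        coef = np.vstack([-coef, coef])
        intercept = np.concatenate([-intercept, intercept])
    return TrainedDecoder(
        classes=classes,
        coef=coef,
        intercept=intercept,
        norm_mean=mean,
        norm_sd=sd,
        C=C,
        feature_index=list(features.feature_index),
    )


def cross_validate_10fold(
    features: FeatureMatrix,
    labels: np.ndarray,
    seed: int | np.random.Generator = 0,
    n_folds: int = 10,
    C: float = 1.0,
    classes: list[str] | None = None,
    pooled_normalization: bool = False,
) -> ConfusionMatrix:
    """Randomized 10-fold cross-validation, counts accumulated over folds.

    Trials are randomly permuted and split into ``n_folds`` subsets whose
    sizes differ by at most one; each fold is predicted exactly once by a
    decoder trained on the rest.  By default the feature normalization is
    recomputed within each training fold; ``pooled_normalization=True``
    computes it once on all trials instead.
    """
    labels = np.asarray(labels)
    n = features.n_trials
    if n < n_folds:
        raise ValueError(f"fewer trials ({n}) than folds ({n_folds})")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    classes = list(classes) if classes is not None else sorted(set(labels))
    folds = np.array_split(rng.permutation(n), n_folds)
    if pooled_normalization:
        pooled, _, _ = normalize_across_trials(features)
    conf = np.zeros((len(classes), len(classes)))
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        base = pooled if pooled_normalization else features
        train_fm = FeatureMatrix(
            base.values[train_mask], list(base.feature_index)
        )
        test_fm = FeatureMatrix(base.values[test_idx], list(base.feature_index))
        if pooled_normalization:
            # statistics already applied once on the pooled matrix
            dec = _fit_on_normalized(train_fm, labels[train_mask], C, classes)
        else:
            dec = train_ova_linear(train_fm, labels[train_mask], C, classes)
        pred = dec.predict(test_fm)
        for yi, pi in zip(labels[test_idx], pred):
            conf[classes.index(yi), pi] += 1
    return ConfusionMatrix(conf, classes, normalized=False)


def _fit_on_normalized(features, labels, C, classes):
    """Fit the OvA SVM on already-normalized features (identity statistics)."""
    y = np.array([classes.index(l) for l in labels])
    svm = LinearSVC(C=C, dual="auto", max_iter=5000, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm.fit(features.values, y)
    coef, intercept = svm.coef_, svm.intercept_
    if len(classes) == 2:
        coef = np.vstack([-coef, coef])
        intercept = np.concatenate([-intercept, intercept])
    nf = features.n_features
    return TrainedDecoder(
        classes, coef, intercept, np.zeros(nf), np.ones(nf), C,
        list(features.feature_index),
    )


def normalize_confusion(conf: ConfusionMatrix) -> ConfusionMatrix:
    """Divide every row by its sum so each row sums to one."""
    sums = conf.matrix.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("confusion matrix has an empty row")
    return ConfusionMatrix(conf.matrix / sums, list(conf.classes), normalized=True)


def accuracy(conf: ConfusionMatrix) -> float:
    """Mean of the diagonal of the row-normalized matrix, in percent."""
    if not conf.normalized:
        raise ValueError("accuracy requires a row-normalized confusion matrix")
    return 100.0 * float(np.mean(np.diag(conf.matrix)))


# --------------------------------------------------------------------------
# searchlights


def searchlight_channels(
    features: FeatureMatrix,
    labels: np.ndarray,
    adjacency: dict[str, set[str]],
    seed: int = 0,
    C: float = 1.0,
) -> pd.Series:
    """Per-channel decoding accuracy using the channel and its neighbors.

    For each center channel the cross-validated accuracy of a decoder
    restricted to {channel union neighbors} x all frequencies is allocated
    to the center.
    """
    channels = list(dict.fromkeys(ch for ch, _ in features.feature_index))
    missing = [c for c in channels if c not in adjacency]
    if missing:
        raise KeyError(f"adjacency missing channels: {missing}")
    ch_of_feature = np.array([ch for ch, _ in features.feature_index])
    out = {}
    rng = np.random.default_rng(seed)
    for center in channels:
        group = {center} | set(adjacency.get(center, ()))
        if len(group) == 1:
            logger.warning("channel %s has no neighbors; running alone", center)
        keep = np.flatnonzero(np.isin(ch_of_feature, list(group)))
        sub = features.subset(keep)
        conf = cross_validate_10fold(sub, labels, rng, C=C)
        out[center] = accuracy(normalize_confusion(conf))
    return pd.Series(out, name="accuracy_pct")


def frequency_groups(freqs: list[float]) -> dict[float, list[float]]:
    """Frequency neighborhoods for the searchlight: {f-1, f, f+1} on the
    grid, truncated to two frequencies at the grid ends."""
    out = {}
    for i, f in enumerate(freqs):
        out[f] = [freqs[j] for j in (i - 1, i, i + 1) if 0 <= j < len(freqs)]
    return out


def searchlight_frequencies(
    features: FeatureMatrix,
    labels: np.ndarray,
    seed: int = 0,
    C: float = 1.0,
) -> pd.Series:
    """Per-frequency accuracy using {f-1, f, f+1} (2 freqs at grid ends)."""
    freqs = sorted(set(f for _, f in features.feature_index))
    if len(freqs) < 2:
        raise ValueError("need >= 2 frequencies for the frequency searchlight")
    f_of_feature = np.array([f for _, f in features.feature_index])
    groups = frequency_groups(freqs)
    out = {}
    rng = np.random.default_rng(seed)
    for f in freqs:
        group = groups[f]
        keep = np.flatnonzero(np.isin(f_of_feature, group))
        sub = features.subset(keep)
        conf = cross_validate_10fold(sub, labels, rng, C=C)
        out[f] = accuracy(normalize_confusion(conf))
    return pd.Series(out, name="accuracy_pct")


# --------------------------------------------------------------------------
# cross-phase timecourses


@dataclass
class DecodingTimecourse:
    """Per-bin decoding of one subject x condition retrieval set.

    ``accuracy`` is the proportion of trials whose predicted context equals
    the target context (thus identical to ``evidence_target``);
    ``evidence_competitor`` is defined only when competitor labels exist
    (AB/AC trials), in which case target + competitor + other sums to 1 at
    every bin.  ``predictions`` keeps the trial-level predicted class
    indices so success/failure splits can be recomputed downstream.
    """

    subject: str
    condition: str
    times: np.ndarray
    accuracy: np.ndarray  # (n_bins,) proportion in [0, 1]
    evidence_target: np.ndarray
    evidence_competitor: np.ndarray  # nan where undefined
    evidence_other: np.ndarray
    predictions: np.ndarray  # (n_trials, n_bins) class indices
    target_idx: np.ndarray  # (n_trials,) class index of the target context
    competitor_idx: np.ndarray  # (n_trials,) class index or -1
    metadata: pd.DataFrame
    smoothed: bool = False

    @property
    def n_trials(self) -> int:
        return self.predictions.shape[0]


def bin_feature_stack(
    tfr: TFRStack, bin_times: np.ndarray = RETRIEVAL_BIN_TIMES
) -> np.ndarray:
    """Raw per-bin feature values, shape ``(n_trials, n_bins, n_features)``.

    Precomputing this once lets permutation nulls re-apply many decoders to
    the same retrieval data without re-slicing the TFR.
    """
    cols = [bin_features(tfr, t).values for t in bin_times]
    return np.stack(cols, axis=1)


def predict_stack(decoder: TrainedDecoder, stack: np.ndarray) -> np.ndarray:
    """Predicted class indices for a (n_trials, n_bins, n_features) stack."""
    n_tr, n_bins, n_feat = stack.shape
    sd = np.where(decoder.norm_sd < 1e-12, 1.0, decoder.norm_sd)
    x = (stack.reshape(-1, n_feat) - decoder.norm_mean) / sd
    x[:, decoder.norm_sd < 1e-12] = 0.0
    scores = x @ decoder.coef.T + decoder.intercept
    return np.argmax(scores, axis=1).reshape(n_tr, n_bins)


def decode_timecourse(
    decoder: TrainedDecoder,
    retrieval_tfr: TFRStack | None,
    target_context: np.ndarray,
    competitor_context: np.ndarray | None = None,
    bin_times: np.ndarray = RETRIEVAL_BIN_TIMES,
    subject: str = "",
    condition: str = "",
    feature_stack: np.ndarray | None = None,
    metadata: pd.DataFrame | None = None,
) -> DecodingTimecourse:
    """Apply the frozen encoding decoder at every retrieval time bin.

    Each bin's single-slice feature matrix is normalized with the decoder's
    frozen statistics and classified; per-bin accuracy and per-context
    evidence proportions are recorded.  A precomputed ``feature_stack`` (see
    :func:`bin_feature_stack`) may replace the TFR input.
    """
    target_context = np.asarray(target_context)
    if feature_stack is None:
        if retrieval_tfr is None:
            raise ValueError("either retrieval_tfr or feature_stack is required")
        feature_stack = bin_feature_stack(retrieval_tfr, bin_times)
        if metadata is None:
            metadata = retrieval_tfr.metadata.copy()
    if metadata is None:
        metadata = pd.DataFrame(index=range(feature_stack.shape[0]))
    n_trials = feature_stack.shape[0]
    if len(target_context) != n_trials:
        raise ValueError("one target context per trial required")
    if feature_stack.shape[2] != decoder.coef.shape[1]:
        raise ValueError("feature-space mismatch between decoder and retrieval data")
    cls_index = {c: i for i, c in enumerate(decoder.classes)}
    tgt = np.array([cls_index[c] for c in target_context])
    if competitor_context is not None:
        comp = np.array(
            [cls_index.get(c, -1) if c is not None else -1 for c in competitor_context]
        )
    else:
        comp = np.full(n_trials, -1)

    preds = predict_stack(decoder, feature_stack)

    ev_t = (preds == tgt[:, None]).mean(axis=0)
    has_comp = comp >= 0
    if has_comp.any():
        ev_c = (preds[has_comp] == comp[has_comp, None]).mean(axis=0)
        other = 1.0 - (preds[has_comp] == tgt[has_comp, None]).mean(axis=0) - ev_c
        acc = (preds == tgt[:, None]).mean(axis=0)
    else:
        ev_c = np.full(len(bin_times), np.nan)
        other = 1.0 - ev_t
        acc = ev_t
    return DecodingTimecourse(
        subject=subject,
        condition=condition,
        times=np.asarray(bin_times, dtype=float),
        accuracy=acc,
        evidence_target=ev_t,
        evidence_competitor=ev_c,
        evidence_other=other,
        predictions=preds,
        target_idx=tgt,
        competitor_idx=comp,
        metadata=metadata,
    )


def moving_average(x: np.ndarray, times: np.ndarray, window: float) -> np.ndarray:
    """Centered moving average with shrinking edge windows (nan-tolerant)."""
    half = window / 2.0 + 1e-9
    out = np.empty_like(x, dtype=float)
    for i, t in enumerate(times):
        sel = np.abs(times - t) <= half
        out[i] = np.nanmean(x[sel]) if np.any(~np.isnan(x[sel])) else np.nan
    return out


def smooth_timecourse(tc: DecodingTimecourse, window: float = 0.1) -> DecodingTimecourse:
    """Moving-average smoothing of the accuracy/evidence series (0.1 s default)."""
    step = float(np.min(np.diff(tc.times)))
    if window < step:
        raise ValueError("smoothing window smaller than the bin step")
    return DecodingTimecourse(
        subject=tc.subject,
        condition=tc.condition,
        times=tc.times,
        accuracy=moving_average(tc.accuracy, tc.times, window),
        evidence_target=moving_average(tc.evidence_target, tc.times, window),
        evidence_competitor=moving_average(tc.evidence_competitor, tc.times, window),
        evidence_other=moving_average(tc.evidence_other, tc.times, window),
        predictions=tc.predictions,
        target_idx=tc.target_idx,
        competitor_idx=tc.competitor_idx,
        metadata=tc.metadata,
        smoothed=True,
    )


def conditional_accuracy(
    tc: DecodingTimecourse, trial_mask: np.ndarray
) -> np.ndarray:
    """Per-bin percent-correct over a trial subset (e.g. successful trials).

    The headline reinstatement timecourses are computed over successfully
    recalled trials only; the success/failure contrast then compares both
    outcomes inside the windows identified that way.
    """
    trial_mask = np.asarray(trial_mask, dtype=bool)
    if trial_mask.sum() == 0:
        return np.full(tc.predictions.shape[1], np.nan)
    correct = tc.predictions[trial_mask] == tc.target_idx[trial_mask, None]
    return 100.0 * correct.mean(axis=0)


def timecourse_table(tcs: list[DecodingTimecourse]) -> pd.DataFrame:
    """Tidy export: one row per subject x condition x time bin."""
    rows = []
    for tc in tcs:
        for i, t in enumerate(tc.times):
            rows.append(
                dict(
                    subject=tc.subject,
                    condition=tc.condition,
                    bin_time=t,
                    accuracy=tc.accuracy[i],
                    evidence_target=tc.evidence_target[i],
                    evidence_competitor=tc.evidence_competitor[i],
                    evidence_other=tc.evidence_other[i],
                    smoothed=tc.smoothed,
                )
            )
    return pd.DataFrame(rows)
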