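"""Label-shuffle permutation machinery for the decoding analyses.

Statistical reliability of decoding is assessed against empirical null
distributions built by shuffling context labels within subject and re-running
the full pipeline: for encoding, the 10-fold cross-validation (100 iterations
by default); for retrieval, retraining the encoding decoder on shuffled
labels and re-decoding every time bin (1000 iterations by default, matching
the larger number of retrieval data points).  Each iteration yields a group
one-sample t-statistic against the 33.3% chance level (per bin for
retrieval); the 2.5th and 97.5th percentiles of the resulting t distribution
form a two-tailed 0.05 threshold.  A Monte-Carlo FDR test on the same nulls
(per-bin permutation p-values, Benjamini-Hochberg step-up) corroborates the
percentile rule; only bins significant under both are reported as "joint".
Channel/frequency searchlight maps use Bonferroni-corrected parametric
one-sample t-tests instead (0.05/60 and 0.05/42).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoder import (
    CHANCE_PCT,
    FeatureMatrix,
    accuracy,
    cross_validate_10fold,
    normalize_confusion,
    predict_stack,
    train_ova_linear,
)
from .tfr import RETRIEVAL_BIN_TIMES


def group_t(values: np.ndarray, mu: float = CHANCE_PCT, axis: int = 0) -> np.ndarray:
    """One-sample t vs ``mu`` along ``axis`` (ddof=1)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[axis]
    mean = values.mean(axis=axis)
    sd = values.std(axis=axis, ddof=1)
    sd = np.where(sd == 0, np.finfo(float).tiny, sd)
    with np.errstate(over="ignore", divide="ignore"):
        return (mean - mu) / (sd / np.sqrt(n))


def smoothing_matrix(times: np.ndarray, window: float) -> np.ndarray:
    """Row-stochastic centered moving-average operator (shrinking edges)."""
    half = window / 2.0 + 1e-9
    sel = np.abs(times[:, None] - times[None, :]) <= half
    return sel / sel.sum(axis=1, keepdims=True)


@dataclass
class NullDistribution:
    """Sampled group t-statistics under within-subject label shuffling.

    ``t`` has shape ``(n_iter,)`` for the encoding null or ``(n_iter,
    n_bins)`` for the retrieval null; ``acc`` keeps the underlying
    per-subject accuracies (percent) so leave-one-subject-out folds can
    rebuild their own null t-statistics.
    """

    t: np.ndarray
    acc: np.ndarray  # (n_iter, n_subj[, n_bins]) percent
    n_iter: int
    chance: float = CHANCE_PCT
    times: np.ndarray | None = None

    def fold_t(self, exclude_subject: int) -> np.ndarray:
        """Null t recomputed without one subject (for LOSO thresholds)."""
        keep = [i for i in range(self.acc.shape[1]) if i != exclude_subject]
        return group_t(self.acc[:, keep, ...], self.chance, axis=1)


@dataclass
class SignificanceMask:
    """Per-bin decisions under the percentile rule and the FDR test."""

    times: np.ndarray
    t_obs: np.ndarray
    threshold_lo: np.ndarray
    threshold_hi: np.ndarray
    percentile_sig: np.ndarray
    p_perm: np.ndarray
    p_fdr: np.ndarray
    fdr_sig: np.ndarray
    joint_sig: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.joint_sig is None:
            self.joint_sig = self.percentile_sig & self.fdr_sig


# --------------------------------------------------------------------------
# null construction


def encoding_shuffle_null(
    features_per_subject: list[FeatureMatrix],
    labels_per_subject: list[np.ndarray],
    n_iter: int = 100,
    seed: int = 0,
    C: float = 1.0,
    n_folds: int = 10,
) -> NullDistribution:
    """Encoding null: per iteration, shuffle each subject's context labels,
    re-run the 10-fold CV, and take the group t of accuracies vs chance."""
    n_subj = len(features_per_subject)
    if n_subj < 2:
        raise ValueError("need >= 2 subjects")
    if n_iter < 50:
        raise ValueError("n_iter must be >= 50")
    rng = np.random.default_rng(seed)
    classes = sorted(set(np.concatenate(labels_per_subject)))
    acc = np.empty((n_iter, n_subj))
    for it in range(n_iter):
        for si, (fm, labels) in enumerate(
            zip(features_per_subject, labels_per_subject)
        ):
            shuffled = np.asarray(labels)[rng.permutation(len(labels))]
            try:
                conf = cross_validate_10fold(
                    fm, shuffled, rng, n_folds=n_folds, C=C, classes=classes
                )
            except Exception as e:  # pragma: no cover - diagnostic path
                raise RuntimeError(
                    f"encoding null failed at iteration {it}, subject {si}"
                ) from e
            acc[it, si] = accuracy(normalize_confusion(conf))
    return NullDistribution(t=group_t(acc, axis=1), acc=acc, n_iter=n_iter)


@dataclass
class RetrievalSubject:
    """Everything the retrieval null needs for one subject."""

    enc_features: FeatureMatrix  # raw encoding features
    enc_labels: np.ndarray
    feature_stack: np.ndarray  # (n_trials, n_bins, n_features)
    target_idx: np.ndarray  # class index per retrieval trial


def retrieval_shuffle_null(
    subjects: list[RetrievalSubject],
    classes: list[str],
    n_iter: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    mode: str = "retrain",
    smooth_window: float | None = 0.1,
    bin_times: np.ndarray = RETRIEVAL_BIN_TIMES,
) -> NullDistribution:
    """Retrieval null: per-bin group t under within-subject label shuffling.

    ``mode='retrain'`` (default, the stricter reading) re-trains the
    encoding decoder on shuffled encoding labels each iteration and
    re-decodes every bin; ``mode='permute_test'`` keeps the decoder fixed
    and permutes the retrieval target labels instead.  Accuracy series are
    smoothed with the same moving average applied to the observed series
    before the t-statistics are formed.
    """
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    if n_iter < 50:
        raise ValueError("n_iter must be >= 50")
    if mode not in ("retrain", "permute_test"):
        raise ValueError("mode must be 'retrain' or 'permute_test'")
    rng = np.random.default_rng(seed)
    n_bins = len(bin_times)
    smooth = (
        smoothing_matrix(np.asarray(bin_times, float), smooth_window)
        if smooth_window
        else None
    )
    acc = np.empty((n_iter, len(subjects), n_bins))
    fixed_preds = None
    if mode == "permute_test":
        fixed_preds = []
        for s in subjects:
            dec = train_ova_linear(s.enc_features, s.enc_labels, C, classes)
            fixed_preds.append(predict_stack(dec, s.feature_stack))
    for it in range(n_iter):
        for si, s in enumerate(subjects):
            try:
                if mode == "retrain":
                    shuffled = np.asarray(s.enc_labels)[
                        rng.permutation(len(s.enc_labels))
                    ]
                    dec = train_ova_linear(s.enc_features, shuffled, C, classes)
                    preds = predict_stack(dec, s.feature_stack)
                    a = (preds == s.target_idx[:, None]).mean(axis=0)
                else:
                    perm = rng.permutation(len(s.target_idx))
                    a = (fixed_preds[si] == s.target_idx[perm, None]).mean(axis=0)
            except Exception as e:  # pragma: no cover - diagnostic path
                raise RuntimeError(
                    f"retrieval null failed at iteration {it}, subject {si}"
                ) from e
            acc[it, si] = 100.0 * (a @ smooth.T if smooth is not None else a)
    return NullDistribution(
        t=group_t(acc, axis=1),
        acc=acc,
        n_iter=n_iter,
        times=np.asarray(bin_times, float),
    )


# --------------------------------------------------------------------------
# thresholds and masks


def percentile_threshold(
    null: NullDistribution | np.ndarray, alpha: float = 0.05
):
    """Empirical two-tailed thresholds: 100*(alpha/2) and 100*(1-alpha/2)
    percentiles (linear interpolation)."""
    t = null.t if isinstance(null, NullDistribution) else np.asarray(null)
    if t.shape[0] < 40:
        raise ValueError("need >= 40 null samples for percentile thresholds")
    # degenerate null iterations (zero across-subject variance) give +-inf t;
    # cap them so interpolation stays defined without changing the ordering
    t = np.clip(t, -1e12, 1e12)
    lo = np.percentile(t, 100.0 * alpha / 2.0, axis=0)
    hi = np.percentile(t, 100.0 * (1.0 - alpha / 2.0), axis=0)
    return lo, hi


def fdr_monte_carlo(
    observed_t: np.ndarray,
    null_t: np.ndarray,
    q: float = 0.05,
):
    """Two-tailed per-bin permutation p-values with BH step-up correction.

    p = (1 + #{|t_null| >= |t_obs|}) / (1 + n_iter) per bin, then
    Benjamini-Hochberg across bins at level ``q``.
    Returns ``(p_perm, p_adjusted, reject)``.
    """
    observed_t = np.atleast_1d(np.asarray(observed_t, float))
    null_t = np.atleast_2d(np.asarray(null_t, float))
    if null_t.shape[1] != observed_t.shape[0]:
        raise ValueError("null and observed bin grids differ")
    n_iter = null_t.shape[0]
    exceed = (np.abs(null_t) >= np.abs(observed_t)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_iter)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p, p_adj, reject


def significant_bins(
    observed_t: np.ndarray,
    null: NullDistribution,
    alpha: float = 0.05,
    q: float = 0.05,
) -> SignificanceMask:
    """Joint percentile-of-t and Monte-Carlo-FDR significance per bin."""
    observed_t = np.asarray(observed_t, float)
    null_t = np.atleast_2d(null.t)
    if null_t.shape[1] == 1 and observed_t.shape[0] > 1:
        null_t = np.repeat(null_t, observed_t.shape[0], axis=1)
    if null_t.shape[1] != observed_t.shape[0]:
        raise ValueError("observed series and null do not share the bin grid")
    lo, hi = percentile_threshold(NullDistribution(null_t, null.acc, null.n_iter), alpha)
    perc = (observed_t > hi) | (observed_t < lo)
    p, p_adj, fdr = fdr_monte_carlo(observed_t, null_t, q)
    times = null.times if null.times is not None else np.arange(len(observed_t))
    return SignificanceMask(
        times=np.asarray(times, float),
        t_obs=observed_t,
        threshold_lo=np.broadcast_to(lo, observed_t.shape).copy(),
        threshold_hi=np.broadcast_to(hi, observed_t.shape).copy(),
        percentile_sig=perc,
        p_perm=p,
        p_fdr=p_adj,
        fdr_sig=fdr,
    )


def bonferroni_searchlight(
    accuracy_maps: np.ndarray,
    m: int | None = None,
    alpha: float = 0.05,
    chance: float = CHANCE_PCT,
):
    """Bonferroni-corrected one-sample t-test per searchlight cell.

    ``accuracy_maps`` is ``(n_subjects, n_cells)`` in percent.  Each cell is
    tested against chance; a cell is significant iff p < alpha/m (m = 42 for
    the frequency map, 60 for the channel map).
    Returns dict with ``t``, ``p``, ``sig`` and the corrected threshold.
    """
    maps = np.atleast_2d(np.asarray(accuracy_maps, float))
    n_cells = maps.shape[1]
    if m is None:
        m = n_cells
    if m != n_cells:
        raise ValueError(f"m={m} does not match map size {n_cells}")
    t, p = stats.ttest_1samp(maps, popmean=chance, axis=0)
    threshold = alpha / m
    return {"t": t, "p": p, "sig": p < threshold, "threshold": threshold}
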