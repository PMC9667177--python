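"""Leave-one-subject-out window selection and within-window contrasts.

Contrasting decoding accuracy between successful and unsuccessful trials
inside time windows that were themselves selected for showing reliable
decoding is circular if the tested subject contributed to the selection.
The selection here is therefore leave-one-subject-out (LOSO): for each
subject, the significant time bins are identified from the remaining
subjects' timecourses (thresholded by that fold's own permutation null) and
restricted to a margin of +-0.2 s around the group reference window.  The
selected bins then feed paired success/failure contrasts, one-sample tests
against chance, and repeated-measures ANOVAs over within-subject factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .decoder import CHANCE_PCT, DecodingTimecourse
from .permstats import NullDistribution, group_t, percentile_threshold

logger = logging.getLogger(__name__)


@dataclass
class LosoWindows:
    """Per left-out subject: selected bin indices on the retrieval grid."""

    bins: list[np.ndarray]  # one index array per subject
    fallback: np.ndarray  # bool per subject: empty selection, center used
    times: np.ndarray
    reference_window: tuple[float, float]
    margin: float


@dataclass
class ContrastResult:
    """A single reported statistic with its effect size."""

    name: str
    statistic: float
    df: float | tuple
    p: float
    effect_size: float
    n: int
    per_subject: pd.DataFrame | None = None
    table: pd.DataFrame | None = None

    def row(self) -> dict:
        return dict(
            effect=self.name,
            stat=self.statistic,
            df=str(self.df),
            p=self.p,
            effect_size=self.effect_size,
            n=self.n,
        )


def loso_select(
    accuracy_per_subject: np.ndarray,
    null: NullDistribution,
    times: np.ndarray,
    reference_window: tuple[float, float],
    margin: float = 0.2,
    alpha: float = 0.05,
) -> LosoWindows:
    """Select analysis bins for each subject from the other subjects only.

    ``accuracy_per_subject`` is ``(n_subjects, n_bins)`` in percent
    (smoothed, as entered into the group t-test).  For each left-out
    subject, the remaining subjects' group t-series is thresholded by the
    percentile rule of that fold's null (rebuilt from the stored
    per-subject null accuracies without the left-out subject), and
    significant bins within ``reference_window`` extended by ``margin`` on
    both sides are selected.  An empty selection falls back to the bin
    nearest the window center, flagged in ``fallback``.
    """
    acc = np.asarray(accuracy_per_subject, float)
    n_subj, n_bins = acc.shape
    if n_subj < 3:
        raise ValueError("LOSO selection needs >= 3 subjects")
    times = np.asarray(times, float)
    w0, w1 = reference_window
    in_window = (times >= w0 - margin - 1e-9) & (times <= w1 + margin + 1e-9)
    if not in_window.any():
        raise ValueError("reference window (with margin) off the bin grid")
    center = 0.5 * (w0 + w1)
    center_bin = int(np.argmin(np.abs(times - center)))
    bins, fallback = [], np.zeros(n_subj, dtype=bool)
    for s in range(n_subj):
        keep = [i for i in range(n_subj) if i != s]
        t_obs = group_t(acc[keep], axis=0)
        lo, hi = percentile_threshold(null.fold_t(s), alpha)
        sig = ((t_obs > hi) | (t_obs < lo)) & in_window
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            logger.warning(
                "LOSO fold %d: no significant bins; falling back to window center",
                s,
            )
            idx = np.array([center_bin])
            fallback[s] = True
        bins.append(idx)
    return LosoWindows(bins, fallback, times, (w0, w1), margin)


def circular_max_bin_select(
    accuracy_per_subject: np.ndarray, times: np.ndarray
) -> LosoWindows:
    """Deliberately circular selection: the max-|t| bin across ALL subjects.

    Every subject gets the same bin, chosen with the tested subjects
    included.  Exists to demonstrate the selection bias LOSO avoids; never
    used by the pipeline proper.
    """
    acc = np.asarray(accuracy_per_subject, float)
    t = group_t(acc, axis=0)
    best = int(np.argmax(np.abs(t)))
    n_subj = acc.shape[0]
    return LosoWindows(
        bins=[np.array([best])] * n_subj,
        fallback=np.zeros(n_subj, dtype=bool),
        times=np.asarray(times, float),
        reference_window=(times[best], times[best]),
        margin=0.0,
    )


def _window_accuracy(tc: DecodingTimecourse, bins: np.ndarray, mask: np.ndarray):
    """Mean percent-correct over selected bins for a trial subset."""
    if mask.sum() == 0:
        return np.nan, 0
    correct = tc.predictions[mask][:, bins] == tc.target_idx[mask, None]
    return 100.0 * float(correct.mean()), int(mask.sum())


def success_contrast(
    timecourses: list[DecodingTimecourse],
    loso: LosoWindows,
    min_trials: int = 10,
) -> ContrastResult:
    """Paired success vs failure accuracy contrast inside the LOSO windows.

    Subjects without more than ``min_trials`` trials in both outcomes are
    excluded (and counted in the log).  Cohen's d uses the paired
    convention: mean difference / SD of differences.
    """
    rows = []
    excluded = 0
    for si, tc in enumerate(timecourses):
        success = tc.metadata["success"].to_numpy(dtype=bool)
        a_s, n_s = _window_accuracy(tc, loso.bins[si], success)
        a_u, n_u = _window_accuracy(tc, loso.bins[si], ~success)
        if n_s <= min_trials or n_u <= min_trials:
            excluded += 1
            continue
        rows.append(
            dict(subject=tc.subject, acc_success=a_s, acc_failure=a_u,
                 n_success=n_s, n_failure=n_u)
        )
    if excluded:
        logger.info(
            "success_contrast: %d subjects excluded (<= %d trials per outcome)",
            excluded,
            min_trials,
        )
    per_subject = pd.DataFrame(rows)
    if len(per_subject) < 3:
        raise ValueError(
            f"only {len(per_subject)} eligible subjects (need >= 3)"
        )
    diff = per_subject["acc_success"] - per_subject["acc_failure"]
    sd = diff.std(ddof=1)
    if sd == 0:
        t, p = (0.0, 1.0) if np.isclose(diff.mean(), 0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(
            per_subject["acc_success"], per_subject["acc_failure"]
        )
    d = float(diff.mean() / sd) if sd > 0 else 0.0
    return ContrastResult(
        name="successful_vs_unsuccessful",
        statistic=float(t),
        df=len(per_subject) - 1,
        p=float(p),
        effect_size=d,
        n=len(per_subject),
        per_subject=per_subject,
    )


def one_sample_t(values: np.ndarray, mu: float = CHANCE_PCT,
                 name: str = "vs_chance") -> ContrastResult:
    """Two-tailed one-sample t vs ``mu`` with Cohen's d = mean diff / SD."""
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("need >= 2 subjects")
    sd = values.std(ddof=1)
    if sd == 0:
        if np.isclose(values.mean(), mu):
            return ContrastResult(name, 0.0, len(values) - 1, 1.0, 0.0, len(values))
        logger.warning("one_sample_t: zero variance with nonzero mean difference")
        sign = np.sign(values.mean() - mu)
        return ContrastResult(
            name, float(sign * np.inf), len(values) - 1, 0.0,
            float(sign * np.inf), len(values)
        )
    t, p = stats.ttest_1samp(values, popmean=mu)
    d = float((values.mean() - mu) / sd)
    return ContrastResult(name, float(t), len(values) - 1, float(p), d, len(values))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    within: list[str] | None = None,
) -> ContrastResult:
    """Repeated-measures ANOVA over up to three within-subject factors.

    ``data`` is long-format with one row per subject x cell; cells must be
    complete and balanced.  The returned ``table`` holds F, dfs, p and
    partial eta squared for every main effect and interaction (all factors
    here have 2-3 levels, and the headline factors are 2-level, so no
    sphericity correction is applied).  ``statistic`` etc. report the
    highest-order term.
    """
    if within is None or not within:
        raise ValueError("at least one within-subject factor required")
    counts = data.groupby([subject] + within, observed=True).size()
    if counts.min() < 1 or counts.nunique() != 1:
        raise ValueError("missing or unbalanced within-subject cells")
    n_subj = data[subject].nunique()
    if n_subj < 3:
        raise ValueError("need >= 3 subjects")
    res = AnovaRM(data, depvar=dv, subject=subject, within=within).fit()
    tab = res.anova_table.copy()
    tab["eta_p2"] = (tab["F Value"] * tab["Num DF"]) / (
        tab["F Value"] * tab["Num DF"] + tab["Den DF"]
    )
    top = tab.iloc[-1]
    return ContrastResult(
        name=" x ".join(within),
        statistic=float(top["F Value"]),
        df=(float(top["Num DF"]), float(top["Den DF"])),
        p=float(top["Pr > F"]),
        effect_size=float(top["eta_p2"]),
        n=n_subj,
        table=tab,
    )


def contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    """Tidy stats table (effect, stat, df, p, effect_size, n)."""
    return pd.DataFrame([r.row() for r in results])
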