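"""Pipeline orchestration: simulate -> preprocess -> TFR -> train -> decode
-> permutation stats -> LOSO contrasts -> cluster tests -> report.

Every stage reads its inputs from and persists its outputs to a run
directory, so stages can be run individually from the CLI or all at once
with :func:`run_pipeline`.  Stage outputs are cached: a stage whose relevant
configuration hash matches the one stored in the run directory is loaded
instead of recomputed.  Every stochastic stage derives its seed
deterministically from the master seed and the stage name.

The default configuration is a desk-scale run (8 subjects, 60 encoding
trials per context, 32 channels at 200 Hz, 100/200 permutation iterations,
499 cluster draws) that completes on one CPU in minutes; the experiment-
scale constants (62 channels, 500 Hz, 100/1000/10000 iterations) are plain
config switches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoder import (
    CHANCE_PCT,
    accuracy,
    bin_feature_stack,
    conditional_accuracy,
    cross_validate_10fold,
    decode_timecourse,
    normalize_confusion,
    searchlight_channels,
    searchlight_frequencies,
    timecourse_table,
    train_ova_linear,
)
from .loso import (
    contrast_table,
    loso_select,
    one_sample_t,
    success_contrast,
)
from .montage import channel_adjacency
from .permstats import (
    RetrievalSubject,
    bonferroni_searchlight,
    encoding_shuffle_null,
    group_t,
    retrieval_shuffle_null,
    significant_bins,
    smoothing_matrix,
)
from .preprocess import baseline_epoch_mean
from .synth import (
    CONDITIONS,
    SimConfig,
    SyntheticCohort,
    generate_cohort,
    save_cohort,
)
from .tfr import (
    log_baseline_tfr,
    morlet_tfr,
    window_average_features,
)
from .cluster import cluster_permutation_p

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "tfr",
    "train",
    "decode",
    "stats",
    "cluster",
    "report",
)


@dataclass
class RunConfig:
    """Full pipeline configuration (see module docstring for the defaults)."""

    sim: dict = field(default_factory=dict)
    freq_start: float = 4.0
    freq_stop: float = 45.0
    freq_step: float = 1.0
    time_step: float = 0.05
    wavelet_width: float = 5.0
    encoding_feature_window: tuple[float, float] = (0.0, 6.0)
    retrieval_bin_window: tuple[float, float] = (-0.2, 4.0)
    svm_C: float = 1.0
    n_iter_encoding: int = 100
    n_iter_retrieval: int = 200
    cluster_draws: int = 499
    alpha: float = 0.05
    fdr_q: float = 0.05
    smooth_window: float = 0.1
    loso_margin: float = 0.2
    min_trials: int = 10
    reference_windows: dict = field(
        default_factory=lambda: {"DE": (0.9, 1.0), "AC": (2.5, 2.8), "AB": (2.5, 2.8)}
    )
    cluster_condition: str = "DE"
    cluster_window: tuple[float, float] = (0.3, 1.5)
    cluster_freq_range: tuple[float, float] = (4.0, 45.0)
    run_searchlights: bool = False
    seed: int = 0

    def __post_init__(self):
        defaults = dict(
            n_subjects=8, n_channels=32, fs=200.0, n_blocks=15,
            pairs_per_condition_per_block=4,
        )
        defaults.update(self.sim)
        self.sim = defaults

    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_start, self.freq_stop + 1e-9, self.freq_step)

    def bin_times(self) -> np.ndarray:
        t0, t1 = self.retrieval_bin_window
        return np.round(np.arange(t0, t1 + 1e-9, self.time_step), 10)

    def sim_config(self) -> SimConfig:
        kw = dict(self.sim)
        kw.setdefault("seed", stage_seed(self.seed, "simulate"))
        fields = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(kw) - fields
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        return SimConfig(**kw)

    # -------------------------------------------------------------- serde
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in (
            "encoding_feature_window",
            "retrieval_bin_window",
            "cluster_window",
            "cluster_freq_range",
        ):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        if "reference_windows" in d:
            d["reference_windows"] = {
                c: tuple(w) for c, w in d["reference_windows"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


# --------------------------------------------------------------------------
# caching helpers


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _cache_valid(stage_dir: Path, key: str) -> bool:
    f = stage_dir / "stage_hash.json"
    if not f.exists():
        return False
    try:
        return json.loads(f.read_text())["hash"] == key
    except Exception:
        return False


def _write_cache_key(stage_dir: Path, key: str) -> None:
    (stage_dir / "stage_hash.json").write_text(json.dumps({"hash": key}))


def _log_event(outdir: Path, **event) -> None:
    event.setdefault("time", time.strftime("%Y-%m-%dT%H:%M:%S"))
    with open(Path(outdir) / "run_log.jsonl", "a") as f:
        f.write(json.dumps(event) + "\n")


# --------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, outdir: Path) -> SyntheticCohort:
    d = _stage_dir(outdir, "simulate")
    key = config.config_hash() + ":sim"
    cohort = generate_cohort(config.sim_config())
    if not _cache_valid(d, key):
        save_cohort(cohort, d)
        _write_cache_key(d, key)
    _log_event(outdir, stage="simulate", subjects=len(cohort.subjects))
    return cohort


def stage_preprocess(config: RunConfig, outdir: Path, cohort: SyntheticCohort):
    """Whole-epoch mean baseline (synthetic data has no mastoid channels)."""
    d = _stage_dir(outdir, "preprocess")
    out = {}
    for sid, phases in cohort.subjects.items():
        out[sid] = {ph: baseline_epoch_mean(ep) for ph, ep in phases.items()}
    key = config.config_hash() + ":pre"
    if not _cache_valid(d, key):
        (d / "preprocess.json").write_text(
            json.dumps({"steps": ["baseline_epoch_mean"]})
        )
        _write_cache_key(d, key)
    _log_event(outdir, stage="preprocess", subjects=len(out))
    return out


def stage_tfr(config: RunConfig, outdir: Path, epochs_by_subject) -> dict:
    d = _stage_dir(outdir, "tfr")
    freqs = config.freqs()
    out = {}
    for sid, phases in epochs_by_subject.items():
        out[sid] = {}
        for ph, ep in phases.items():
            out[sid][ph] = morlet_tfr(
                ep, freqs=freqs, time_step=config.time_step,
                width=config.wavelet_width,
            )
    _write_cache_key(d, config.config_hash() + ":tfr")
    _log_event(outdir, stage="tfr", n_freqs=len(freqs))
    return out


def stage_train(config: RunConfig, outdir: Path, tfrs: dict) -> dict:
    """Per-subject encoding features, 10-fold CV confusion, frozen decoder."""
    d = _stage_dir(outdir, "train")
    t0, t1 = config.encoding_feature_window
    rng_seed = stage_seed(config.seed, "train")
    result = {"features": {}, "labels": {}, "decoders": {}, "confusions": {},
              "accuracy": {}, "per_class_accuracy": {}}
    classes = None
    rows = []
    for si, (sid, phases) in enumerate(sorted(tfrs.items())):
        fm = window_average_features(phases["encoding"], t0, t1)
        labels = fm.metadata["context"].to_numpy()
        if classes is None:
            classes = sorted(set(labels))
        conf = cross_validate_10fold(
            fm, labels, seed=rng_seed + si, C=config.svm_C, classes=classes
        )
        norm = normalize_confusion(conf)
        result["features"][sid] = fm
        result["labels"][sid] = labels
        result["decoders"][sid] = train_ova_linear(fm, labels, config.svm_C, classes)
        result["confusions"][sid] = norm
        result["accuracy"][sid] = accuracy(norm)
        result["per_class_accuracy"][sid] = {
            c: 100.0 * norm.matrix[i, i] for i, c in enumerate(classes)
        }
        rows.append(dict(subject=sid, accuracy_pct=result["accuracy"][sid],
                         **result["per_class_accuracy"][sid]))
    result["classes"] = classes
    pd.DataFrame(rows).to_csv(d / "encoding_accuracy.csv", index=False)

    if config.run_searchlights:
        ch_names = next(iter(tfrs.values()))["encoding"].channel_names
        adj = channel_adjacency(ch_names)
        ch_maps, fr_maps = [], []
        for si, (sid, _) in enumerate(sorted(tfrs.items())):
            fm = result["features"][sid]
            labels = result["labels"][sid]
            ch_maps.append(
                searchlight_channels(fm, labels, adj, seed=rng_seed + si,
                                     C=config.svm_C)
            )
            fr_maps.append(
                searchlight_frequencies(fm, labels, seed=rng_seed + si,
                                        C=config.svm_C)
            )
        ch_df = pd.DataFrame(ch_maps)
        fr_df = pd.DataFrame(fr_maps)
        result["searchlight_channels"] = ch_df
        result["searchlight_freqs"] = fr_df
        result["searchlight_channels_test"] = bonferroni_searchlight(
            ch_df.to_numpy(), m=ch_df.shape[1], alpha=config.alpha
        )
        result["searchlight_freqs_test"] = bonferroni_searchlight(
            fr_df.to_numpy(), m=fr_df.shape[1], alpha=config.alpha
        )
        ch_df.to_csv(d / "searchlight_channels.csv", index=False)
        fr_df.to_csv(d / "searchlight_frequencies.csv", index=False)
    _write_cache_key(d, config.config_hash() + ":train")
    _log_event(outdir, stage="train",
               mean_accuracy=float(np.mean(list(result["accuracy"].values()))))
    return result


def stage_decode(config: RunConfig, outdir: Path, tfrs: dict, train: dict) -> dict:
    """Cross-phase decoding of every retrieval bin, per subject x condition."""
    d = _stage_dir(outdir, "decode")
    bin_times = config.bin_times()
    out = {"timecourses": {}, "stacks": {}, "bin_times": bin_times,
           "_metadata": {}}
    for sid, phases in sorted(tfrs.items()):
        rtfr = phases["retrieval"]
        stack = bin_feature_stack(rtfr, bin_times)
        out["stacks"][sid] = stack
        md = rtfr.metadata
        out["_metadata"][sid] = md
        dec = train["decoders"][sid]
        for cond in CONDITIONS:
            mask = (md["condition"] == cond).to_numpy()
            if mask.sum() == 0:
                continue
            comp = md.loc[mask, "competitor"].to_numpy() if "competitor" in md else None
            tc = decode_timecourse(
                dec,
                None,
                md.loc[mask, "context"].to_numpy(),
                comp,
                bin_times=bin_times,
                subject=sid,
                condition=cond,
                feature_stack=stack[mask],
                metadata=md.loc[mask].reset_index(drop=True),
            )
            out["timecourses"].setdefault(cond, []).append(tc)
    table = timecourse_table(
        [tc for tcs in out["timecourses"].values() for tc in tcs]
    )
    table.to_csv(d / "timecourses.csv", index=False)
    _write_cache_key(d, config.config_hash() + ":decode")
    _log_event(outdir, stage="decode", n_bins=len(bin_times))
    return out


def stage_stats(config: RunConfig, outdir: Path, train: dict, decode: dict) -> dict:
    """Permutation nulls, significance masks, LOSO windows and contrasts."""
    d = _stage_dir(outdir, "stats")
    bin_times = decode["bin_times"]
    smooth = smoothing_matrix(bin_times, config.smooth_window)
    subjects = sorted(train["decoders"])
    classes = train["classes"]

    # group-level encoding accuracy vs its shuffle null
    enc_null = encoding_shuffle_null(
        [train["features"][s] for s in subjects],
        [train["labels"][s] for s in subjects],
        n_iter=config.n_iter_encoding,
        seed=stage_seed(config.seed, "stats.encoding_null"),
        C=config.svm_C,
    )
    enc_acc = np.array([train["accuracy"][s] for s in subjects])
    enc_t = float(group_t(enc_acc))
    enc_thresh = np.percentile(enc_null.t, [2.5, 97.5])

    results = {
        "encoding": {
            "mean_accuracy_pct": float(enc_acc.mean()),
            "t_vs_chance": enc_t,
            "null_thresholds_t": [float(x) for x in enc_thresh],
            "significant": bool(enc_t > enc_thresh[1] or enc_t < enc_thresh[0]),
        },
        "conditions": {},
    }
    np.savez_compressed(d / "encoding_null.npz", t=enc_null.t, acc=enc_null.acc)

    contrasts = []
    masks_rows = []
    for cond, tcs_all in decode["timecourses"].items():
        # the reinstatement timecourse analysis is computed over successful
        # trials; subjects without at least 2 successes drop out of it
        succ = [tc.metadata["success"].to_numpy(dtype=bool) for tc in tcs_all]
        keep = [i for i, m in enumerate(succ) if m.sum() >= 2]
        if len(keep) < 2:
            logger.warning("condition %s: too few subjects with successes", cond)
            continue
        tcs = [tcs_all[i] for i in keep]
        succ = [succ[i] for i in keep]
        acc = np.stack(
            [
                conditional_accuracy(tc, m) @ smooth.T
                for tc, m in zip(tcs, succ)
            ]
        )
        t_obs = group_t(acc, axis=0)
        null = retrieval_shuffle_null(
            [
                RetrievalSubject(
                    train["features"][tc.subject],
                    train["labels"][tc.subject],
                    _condition_stack(decode, tc)[m],
                    tc.target_idx[m],
                )
                for tc, m in zip(tcs, succ)
            ],
            classes,
            n_iter=config.n_iter_retrieval,
            seed=stage_seed(config.seed, f"stats.retrieval_null.{cond}"),
            C=config.svm_C,
            smooth_window=config.smooth_window,
            bin_times=bin_times,
        )
        mask = significant_bins(t_obs, null, alpha=config.alpha, q=config.fdr_q)
        np.savez_compressed(d / f"retrieval_null_{cond}.npz", t=null.t)
        for bi, t in enumerate(bin_times):
            masks_rows.append(
                dict(
                    condition=cond,
                    bin_time=t,
                    t_obs=mask.t_obs[bi],
                    percentile_sig=bool(mask.percentile_sig[bi]),
                    p_fdr=mask.p_fdr[bi],
                    joint_sig=bool(mask.joint_sig[bi]),
                )
            )
        results["conditions"][cond] = {
            "joint_significant_times": [
                float(t) for t, s in zip(bin_times, mask.joint_sig) if s
            ],
        }
        # LOSO windows + success contrast
        ref = config.reference_windows.get(cond)
        if ref is not None and len(tcs) >= 3:
            loso = loso_select(
                acc, null, bin_times, tuple(ref), margin=config.loso_margin,
                alpha=config.alpha,
            )
            try:
                sc = success_contrast(tcs, loso, min_trials=config.min_trials)
                sc.name = f"{cond}_successful_vs_unsuccessful"
                contrasts.append(sc)
                results["conditions"][cond]["success_contrast"] = sc.row()
            except ValueError as e:
                logger.warning("success contrast skipped for %s: %s", cond, e)
            sel_acc = np.array(
                [
                    conditional_accuracy(tc, m)[loso.bins[i]].mean()
                    for i, (tc, m) in enumerate(zip(tcs, succ))
                ]
            )
            ot = one_sample_t(sel_acc, name=f"{cond}_success_window_vs_chance")
            contrasts.append(ot)
            results["conditions"][cond]["window_vs_chance"] = ot.row()
    pd.DataFrame(masks_rows).to_csv(d / "significance_masks.csv", index=False)
    ct = contrast_table(contrasts)
    ct.to_csv(d / "contrasts.csv", index=False)
    results["contrast_table"] = ct.to_dict(orient="records")
    _write_cache_key(d, config.config_hash() + ":stats")
    _log_event(outdir, stage="stats", n_contrasts=len(contrasts))
    return results


def _condition_stack(decode: dict, tc) -> np.ndarray:
    """Condition-filtered per-bin feature stack for one timecourse."""
    stack = decode["stacks"][tc.subject]
    md = decode["_metadata"][tc.subject]
    mask = (md["condition"] == tc.condition).to_numpy()
    return stack[mask]


def stage_cluster(config: RunConfig, outdir: Path, tfrs: dict) -> dict:
    """Univariate success-vs-failure cluster test in the configured window."""
    d = _stage_dir(outdir, "cluster")
    cond = config.cluster_condition
    w0, w1 = config.cluster_window
    f0, f1 = config.cluster_freq_range
    per_subj_a, per_subj_b = [], []
    ch_names = freqs_sel = times_sel = None
    for sid, phases in sorted(tfrs.items()):
        rtfr = phases["retrieval"]
        lb = log_baseline_tfr(rtfr, base_window=(rtfr.times[0], 0.0))
        md = rtfr.metadata
        mask_c = (md["condition"] == cond).to_numpy()
        succ = mask_c & md["success"].to_numpy(dtype=bool)
        fail = mask_c & ~md["success"].to_numpy(dtype=bool)
        if succ.sum() == 0 or fail.sum() == 0:
            logger.warning("cluster: subject %s lacks one outcome; skipped", sid)
            continue
        fsel = (lb.freqs >= f0) & (lb.freqs <= f1)
        tsel = (lb.times >= w0 - 1e-9) & (lb.times <= w1 + 1e-9)
        ch_names = lb.channel_names
        freqs_sel = lb.freqs[fsel]
        times_sel = lb.times[tsel]
        sub = lb.power[:, :, fsel][:, :, :, tsel]
        per_subj_a.append(sub[succ].mean(axis=0))
        per_subj_b.append(sub[fail].mean(axis=0))
    if len(per_subj_a) < 2:
        logger.warning("cluster stage skipped: insufficient subjects")
        return {"skipped": True}
    adj = channel_adjacency(ch_names)
    res = cluster_permutation_p(
        np.stack(per_subj_a),
        np.stack(per_subj_b),
        ch_names,
        freqs_sel,
        times_sel,
        adj,
        n_draws=config.cluster_draws,
        seed=stage_seed(config.seed, "cluster"),
        alpha=config.alpha,
    )
    tab = res.table()
    tab.to_csv(d / "clusters.csv", index=False)
    np.savez_compressed(d / "cluster_null.npz", null_max_mass=res.null_max_mass)
    _write_cache_key(d, config.config_hash() + ":cluster")
    _log_event(outdir, stage="cluster", n_clusters=len(res.clusters))
    return {"result": res, "table": tab.to_dict(orient="records")}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and assemble the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    cohort = stage_simulate(config, outdir)
    pre = stage_preprocess(config, outdir, cohort)
    tfrs = stage_tfr(config, outdir, pre)
    train = stage_train(config, outdir, tfrs)
    decode = stage_decode(config, outdir, tfrs, train)
    stats = stage_stats(config, outdir, train, decode)
    cluster = stage_cluster(config, outdir, tfrs)
    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "chance_pct": CHANCE_PCT,
        "n_subjects": len(cohort.subjects),
        "encoding": stats["encoding"],
        "conditions": stats["conditions"],
        "contrasts": stats["contrast_table"],
        "clusters": cluster.get("table", []),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    _log_event(outdir, stage="report", done=True)
    return report


def summarize(outdir: str | Path, make_plots: bool = True) -> str:
    """Human-readable summary (and simple report plots) of a finished run."""
    outdir = Path(outdir)
    report = json.loads((outdir / "report.json").read_text())
    lines = [
        f"ctxdecode run {report['config_hash']} (seed {report['seed']})",
        f"subjects: {report['n_subjects']}",
        "encoding: mean accuracy "
        f"{report['encoding']['mean_accuracy_pct']:.1f}% "
        f"(chance {report['chance_pct']:.1f}%), "
        f"t = {report['encoding']['t_vs_chance']:.2f}, "
        f"significant: {report['encoding']['significant']}",
    ]
    for cond, info in report["conditions"].items():
        times = info.get("joint_significant_times", [])
        lines.append(
            f"{cond}: {len(times)} jointly significant bins"
            + (f" at {times}" if times else "")
        )
        if "success_contrast" in info:
            sc = info["success_contrast"]
            lines.append(
                f"  success vs failure: t({sc['df']}) = {sc['stat']:.2f}, "
                f"p = {sc['p']:.3f}, d = {sc['effect_size']:.2f}, n = {sc['n']}"
            )
    if make_plots:
        _plot_run(outdir, report)
    text = "\n".join(lines)
    (outdir / "summary.txt").write_text(text + "\n")
    return text


def _plot_run(outdir: Path, report: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = outdir / "plots"
    plots.mkdir(exist_ok=True)
    tc_file = outdir / "decode" / "timecourses.csv"
    if tc_file.exists():
        df = pd.read_csv(tc_file)
        fig, ax = plt.subplots(figsize=(8, 4))
        for cond, sub in df.groupby("condition"):
            mean = sub.groupby("bin_time")["accuracy"].mean() * 100
            ax.plot(mean.index, mean.values, label=cond)
            times = report["conditions"].get(cond, {}).get(
                "joint_significant_times", []
            )
            if times:
                ax.plot(times, [mean.reindex(times).mean()] * len(times), "*")
        ax.axhline(CHANCE_PCT, ls="--", c="k", lw=0.8)
        ax.set_xlabel("time from cue onset (s)")
        ax.set_ylabel("target accuracy (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plots / "timecourses.png", dpi=100)
        plt.close(fig)
    acc_file = outdir / "train" / "encoding_accuracy.csv"
    if acc_file.exists():
        df = pd.read_csv(acc_file)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(df["subject"], df["accuracy_pct"])
        ax.axhline(CHANCE_PCT, ls="--", c="k", lw=0.8)
        ax.set_ylabel("encoding accuracy (%)")
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        fig.savefig(plots / "encoding_accuracy.png", dpi=100)
        plt.close(fig)
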