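"""Synthetic multi-subject EEG cohorts for the AB/AC interference paradigm.

The experiment this package analyzes presents cue-associate word pairs inside
one of three immersive movie contexts (underwater, forest, city).  Competitive
pairs share a cue (AB then AC); DE pairs are a noncompetitive control.  Each
block assigns the three movies to the three conditions in rotation, and at
retrieval a word cue (0 s) is followed by a first-letter probe (2 s).

The generator emulates that design end to end: every context carries a
distinct channel x frequency oscillatory signature concentrated in posterior
channels within a 4-20 Hz band, riding on 1/f background noise.  Encoding
epochs express the signature of the trial's movie context throughout the
movie; retrieval epochs are signal-free except for programmable
"reinstatement" events that re-inject the target or competitor context
signature inside a chosen time window, optionally only on successfully
recalled trials.  Ground truth (signatures, events, labels) is recorded so
every downstream stage of the pipeline can be validated by recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Epochs

CONTEXTS = ("underwater", "forest", "city")
CONDITIONS = ("AB", "AC", "DE")


@dataclass(frozen=True)
class ReinstatementEvent:
    """A time-localized re-emergence of a context signature at retrieval.

    ``which_context`` selects whose signature is injected: the trial's target
    context (the movie of the to-be-retrieved pair) or its competitor context
    (the movie of the overlapping pair; undefined for DE trials).  Events
    with ``gated_by_success=True`` occur only on successfully recalled
    trials; ``gated_by_failure=True`` restricts them to failed trials
    instead (used to program outcome-dependent band-power differences for
    the univariate contrasts).
    """

    condition: str
    which_context: str  # "target" | "competitor"
    window: tuple[float, float]
    amplitude: float = 1.0
    gated_by_success: bool = True
    gated_by_failure: bool = False

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.which_context not in ("target", "competitor"):
            raise ValueError("which_context must be 'target' or 'competitor'")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.window[1] <= self.window[0]:
            raise ValueError("event window must have positive length")
        if self.gated_by_success and self.gated_by_failure:
            raise ValueError("an event cannot be gated by both outcomes")


def default_schedule() -> list[ReinstatementEvent]:
    """Reinstatement events matching the effects the analysis should recover.

    Noncompetitive (DE) retrieval reinstates the target context late in the
    cue window (0.9-1.0 s, success-gated).  Competitive AC retrieval first
    reinstates the competitor context early after the probe (2.35-2.45 s,
    regardless of outcome) and then, on resolved trials, the target context
    (2.5-2.8 s).  AB retrieval reinstates its target context in the same late
    probe window on successful trials.
    """
    return [
        ReinstatementEvent("DE", "target", (0.9, 1.0), 1.0, True),
        ReinstatementEvent("AC", "competitor", (2.35, 2.45), 1.0, False),
        ReinstatementEvent("AC", "target", (2.5, 2.8), 1.0, True),
        ReinstatementEvent("AB", "target", (2.5, 2.8), 1.0, True),
    ]


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    The defaults reproduce the experiment's structure: 62 channels at 500 Hz,
    encoding epochs -1..7 s around movie onset, retrieval epochs -2..6 s
    around cue onset with the probe at 2 s, 18 blocks of 4 word pairs per
    condition, and per-block analyzed retrieval sets of 4 DE + 2 AB + 2 AC
    trials (each cue tested once).  ``snr`` is the amplitude ratio of an
    injected context oscillation (at its largest signature weight) to the
    broadband background noise, per frequency component.
    """

    n_subjects: int = 8
    n_channels: int = 62
    fs: float = 500.0
    n_blocks: int = 18
    pairs_per_condition_per_block: int = 4
    analyzed_per_block: dict = field(
        default_factory=lambda: {"DE": 4, "AB": 2, "AC": 2}
    )
    encoding_window: tuple[float, float] = (-1.0, 7.0)
    retrieval_window: tuple[float, float] = (-2.0, 6.0)
    movie_duration: float = 6.0
    cue_onset: float = 0.0
    probe_onset: float = 2.0
    signature_band: tuple[float, float] = (4.0, 20.0)
    posterior_channel_fraction: float = 0.4
    snr: float = 1.0
    reinstatement_schedule: list[ReinstatementEvent] = field(
        default_factory=default_schedule
    )
    success_rates: dict = field(
        default_factory=lambda: {"AB": 0.70, "AC": 0.62, "DE": 0.74}
    )
    drift_timescale: float | None = None
    shared_noise_mix: float = 0.0
    white_noise_ratio: float = 0.5
    signature_correlation_bound: float = 0.5
    channel_names: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.probe_onset <= self.cue_onset:
            raise ValueError("probe_onset must follow cue_onset")
        if not (4.0 <= self.signature_band[0] < self.signature_band[1] <= 45.0):
            raise ValueError("signature_band must lie within 4-45 Hz")
        if not 0 < self.posterior_channel_fraction <= 1:
            raise ValueError("posterior_channel_fraction must be in (0, 1]")
        for cond, p in self.success_rates.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in success_rates")
            if not 0 < p <= 1:
                raise ValueError("success_rates must be in (0, 1]")
        for ev in self.reinstatement_schedule:
            w0, w1 = ev.window
            if w0 < self.retrieval_window[0] or w1 > self.retrieval_window[1]:
                raise ValueError(f"event window {ev.window} outside retrieval epoch")
            if self.analyzed_per_block.get(ev.condition, 0) == 0:
                raise ValueError(
                    f"schedule references condition {ev.condition!r} with no trials"
                )
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length mismatch")

    def resolved_channel_names(self) -> list[str]:
        if self.channel_names is not None:
            return list(self.channel_names)
        if self.n_channels == 62:
            from .montage import standard_montage_62

            return list(standard_montage_62()["name"])
        return [f"CH{i + 1:02d}" for i in range(self.n_channels)]

    def posterior_channels(self) -> np.ndarray:
        """Indices of signature-carrying channels (the posterior fraction).

        Channel order is anterior-to-posterior, so the carrying subset is the
        trailing fraction of the channel list.
        """
        k = max(1, int(round(self.posterior_channel_fraction * self.n_channels)))
        return np.arange(self.n_channels - k, self.n_channels)

    def band_freqs(self) -> np.ndarray:
        lo, hi = self.signature_band
        return np.arange(np.ceil(lo), np.floor(hi) + 1.0)


@dataclass
class SignatureMap:
    """Per-context relative power increments over (channel, frequency)."""

    context: str
    weights: np.ndarray  # (n_channels, n_band_freqs), >= 0
    freqs: np.ndarray  # Hz of the weight columns


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    subjects: dict[str, dict[str, Epochs]]  # subject -> {"encoding", "retrieval"}
    signatures: list[SignatureMap]
    schedule: list[ReinstatementEvent]
    config: SimConfig
    usable_for_success_contrast: bool = True

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    def behavior_table(self) -> pd.DataFrame:
        rows = []
        for sid, phases in self.subjects.items():
            md = phases["retrieval"].metadata
            for _, r in md.iterrows():
                rows.append(
                    dict(
                        subject=sid,
                        block=r["block"],
                        condition=r["condition"],
                        success=int(r["success"]),
                    )
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# signatures


def make_signatures(config: SimConfig, rng: np.random.Generator) -> list[SignatureMap]:
    """Draw three mutually distinguishable context signatures.

    Each context gets a smooth spectral profile peaking at a different
    frequency inside the signature band, multiplied by a random posterior
    channel profile, plus weak unstructured variability.  Candidate triples
    are rejection-resampled until all pairwise weight correlations fall below
    ``config.signature_correlation_bound``.
    """
    config.validate()
    post = config.posterior_channels()
    freqs = config.band_freqs()
    if len(post) * len(freqs) < 6:
        raise ValueError(
            "channel subset too small to build 3 distinguishable signatures"
        )
    lo, hi = freqs[0], freqs[-1]
    centers = lo + (np.arange(3) + 0.5) * (hi - lo) / 3.0
    sigma = max((hi - lo) / 10.0, 1.0)
    for _ in range(200):
        maps = []
        for ci, ctx in enumerate(CONTEXTS):
            chan_profile = rng.uniform(0.2, 1.0, size=len(post))
            freq_profile = np.exp(-0.5 * ((freqs - centers[ci]) / sigma) ** 2)
            w = np.outer(chan_profile, freq_profile)
            w += 0.05 * rng.uniform(0.0, 1.0, size=w.shape)
            full = np.zeros((config.n_channels, len(freqs)))
            full[post] = w / w.max()
            maps.append(SignatureMap(ctx, full, freqs.copy()))
        if _max_pairwise_correlation(maps) < config.signature_correlation_bound:
            return maps
    raise ValueError(
        "could not draw 3 signatures with pairwise correlation below "
        f"{config.signature_correlation_bound}"
    )


def _max_pairwise_correlation(maps: list[SignatureMap]) -> float:
    vecs = [m.weights.ravel() for m in maps]
    out = 0.0
    for i in range(3):
        for j in range(i + 1, 3):
            out = max(out, abs(np.corrcoef(vecs[i], vecs[j])[0, 1]))
    return out


# --------------------------------------------------------------------------
# single-trial synthesis


def _pink_noise(n_ch: int, n_samples: int, fs: float, rng: np.random.Generator):
    """1/f^1-power background noise, unit SD per channel."""
    white = rng.standard_normal((n_ch, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5  # PSD ~ 1/f  =>  amplitude ~ f^-1/2
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _envelope(times: np.ndarray, w0: float, w1: float, ramp: float = 0.05):
    """Boxcar on [w0, w1] with raised-cosine edges of width ``ramp``."""
    env = np.zeros_like(times)
    inside = (times >= w0) & (times <= w1)
    env[inside] = 1.0
    if ramp > 0:
        up = (times >= w0 - ramp) & (times < w0)
        env[up] = 0.5 * (1 + np.cos(np.pi * (times[up] - w0) / ramp))
        down = (times > w1) & (times <= w1 + ramp)
        env[down] = 0.5 * (1 + np.cos(np.pi * (times[down] - w1) / ramp))
    return env


def synth_trial(
    signature: SignatureMap | None,
    events: list[tuple[SignatureMap, tuple[float, float], float]],
    window: tuple[float, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one trial as ``channels x samples``.

    ``events`` is a list of realized injections ``(signature, (t0, t1),
    amplitude)``; ``signature`` is accepted as a convenience for a single
    whole-epoch injection and is ignored when ``events`` is given.  The
    oscillatory component of each event is a sum of fixed-frequency sinusoids
    with random phases whose (channel, frequency) amplitude envelope follows
    ``snr * amplitude * weights``.
    """
    t0, t1 = window
    n = int(round((t1 - t0) * config.fs)) + 1
    times = t0 + np.arange(n) / config.fs
    noise = _pink_noise(config.n_channels, n, config.fs, rng)
    if config.white_noise_ratio > 0:
        w = config.white_noise_ratio
        noise = (noise + w * rng.standard_normal(noise.shape)) / np.sqrt(1 + w**2)
    if config.shared_noise_mix > 0:
        shared = _pink_noise(1, n, config.fs, rng)[0]
        mix = config.shared_noise_mix * rng.uniform(0.5, 1.0, config.n_channels)
        noise = noise + mix[:, None] * shared

    if signature is not None and not events:
        events = [(signature, window, 1.0)]
    out = noise
    for sig, (w0, w1), amp in events:
        if w0 < t0 - 1e-9 or w1 > t1 + 1e-9:
            raise ValueError(f"event window ({w0}, {w1}) outside epoch {window}")
        if config.snr * amp == 0:
            continue
        env = _envelope(times, w0, w1)
        phases = rng.uniform(0, 2 * np.pi, size=sig.weights.shape)
        carrier = np.exp(2j * np.pi * sig.freqs[:, None] * times[None, :])
        coef = sig.weights * np.exp(1j * phases)  # (n_ch, n_f)
        osc = np.real(coef @ carrier)  # (n_ch, n_samples)
        out = out + config.snr * amp * env[None, :] * osc
    return out


# --------------------------------------------------------------------------
# cohort generation


def _block_context_assignment(block: int) -> dict[str, str]:
    """Rotate the three movies over conditions across blocks (counterbalanced)."""
    return {
        cond: CONTEXTS[(block + i) % 3] for i, cond in enumerate(CONDITIONS)
    }


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full encode/retrieve cohort with recorded ground truth.

    Per block, each condition's word pairs are encoded inside that block's
    movie for that condition; the analyzed retrieval set mirrors the
    first-tested pairs of each block (4 DE + 2 AB + 2 AC by default) so each
    cue appears once.  Identical configs (including seed) give bit-identical
    cohorts.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    sig_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    signatures = make_signatures(config, sig_rng)
    sig_by_ctx = {s.context: s for s in signatures}
    ch_names = config.resolved_channel_names()

    subj_seeds = ss.spawn(config.n_subjects + 1)[1:]
    subjects: dict[str, dict[str, Epochs]] = {}
    any_failure = False
    for si in range(config.n_subjects):
        sid = f"S{si + 1:02d}"
        rng = np.random.Generator(np.random.PCG64(subj_seeds[si]))
        enc_rows, enc_trials = [], []
        ret_rows, ret_trials = [], []
        drift = _drift_series(config, rng)
        trial_counter = 0
        for b in range(config.n_blocks):
            ctx_of = _block_context_assignment(b)
            comp_of = {"AB": ctx_of["AC"], "AC": ctx_of["AB"], "DE": None}
            for cond in CONDITIONS:
                for _ in range(config.pairs_per_condition_per_block):
                    ctx = ctx_of[cond]
                    d = drift[trial_counter] if drift is not None else 1.0
                    trial_counter += 1
                    data = synth_trial(
                        None,
                        [(sig_by_ctx[ctx], (0.0, config.movie_duration), d)],
                        config.encoding_window,
                        config,
                        rng,
                    )
                    enc_trials.append(data.astype(np.float32))
                    enc_rows.append(
                        dict(
                            subject=sid,
                            phase="encoding",
                            context=ctx,
                            condition=cond,
                            success=True,
                            block=b,
                        )
                    )
            for cond in CONDITIONS:
                for _ in range(config.analyzed_per_block.get(cond, 0)):
                    target = ctx_of[cond]
                    competitor = comp_of[cond]
                    success = bool(rng.random() < config.success_rates[cond])
                    any_failure |= not success
                    events = []
                    for ev in config.reinstatement_schedule:
                        if ev.condition != cond:
                            continue
                        if ev.gated_by_success and not success:
                            continue
                        if ev.gated_by_failure and success:
                            continue
                        ctx_used = target if ev.which_context == "target" else competitor
                        if ctx_used is None:
                            continue
                        events.append((sig_by_ctx[ctx_used], ev.window, ev.amplitude))
                    data = synth_trial(
                        None, events, config.retrieval_window, config, rng
                    )
                    ret_trials.append(data.astype(np.float32))
                    ret_rows.append(
                        dict(
                            subject=sid,
                            phase="retrieval",
                            context=target,
                            condition=cond,
                            success=success,
                            block=b,
                            competitor=competitor,
                        )
                    )
        subjects[sid] = {
            "encoding": Epochs(
                np.stack(enc_trials),
                config.fs,
                config.encoding_window[0],
                ch_names,
                pd.DataFrame(enc_rows),
            ),
            "retrieval": Epochs(
                np.stack(ret_trials),
                config.fs,
                config.retrieval_window[0],
                ch_names,
                pd.DataFrame(ret_rows),
            ),
        }

    usable = any_failure
    if not usable:
        warnings.warn(
            "all retrieval trials succeeded; cohort unusable for "
            "success/failure contrasts",
            UserWarning,
            stacklevel=2,
        )
    return SyntheticCohort(
        subjects=subjects,
        signatures=signatures,
        schedule=list(config.reinstatement_schedule),
        config=replace(config),
        usable_for_success_contrast=usable,
    )


def _drift_series(config: SimConfig, rng: np.random.Generator):
    """Slow random-walk modulation of signature amplitude across trials.

    Emulates gradual context drift within a session; off by default because
    it is cosmetic for every implemented statistic.
    """
    if config.drift_timescale is None:
        return None
    n = config.n_blocks * config.pairs_per_condition_per_block * len(CONDITIONS)
    # step SD chosen so amplitude wanders ~10% over one drift timescale
    trial_spacing = 10.0  # nominal seconds between encoding trials
    step = 0.1 * np.sqrt(trial_spacing / max(config.drift_timescale, trial_spacing))
    walk = np.cumsum(rng.standard_normal(n) * step)
    return np.clip(1.0 + walk - walk.mean(), 0.2, 2.0)


# --------------------------------------------------------------------------
# persistence


def save_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write each subject/phase as the array container and the behavior table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, phases in cohort.subjects.items():
        for phase, ep in phases.items():
            ep.save(directory, f"{sid}_{phase}")
    cohort.behavior_table().to_csv(directory / "behavior.tsv", sep="\t", index=False)


def load_cohort_epochs(directory: str | Path) -> dict[str, dict[str, Epochs]]:
    """Read back every ``<subject>_<phase>`` pair found in ``directory``."""
    directory = Path(directory)
    out: dict[str, dict[str, Epochs]] = {}
    for f in sorted(directory.glob("*_*.json")):
        stem = f.stem
        sid, phase = stem.rsplit("_", 1)
        out.setdefault(sid, {})[phase] = Epochs.load(directory, stem)
    return out
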