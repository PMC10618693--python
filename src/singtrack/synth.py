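"""Synthetic mother–infant dyads with known ground truth.

Three generators emulate the data the analysis consumes:

- :func:`make_song_audio` — verse-structured infant-directed song as a train
  of pitched tone bursts (sharp attack, exponential decay) at the metronome
  inter-onset interval 60/tempo, with per-note tempo/pitch/amplitude jitter.
  Condition defaults follow the study prompts (playsong 170 BPM, lullaby
  100 BPM) and the observed direction of every acoustic contrast: playsongs
  louder, faster, higher pitched, and more variable.
- :func:`make_synthetic_eeg` — each channel is the envelope convolved with a
  known TRF kernel plus 1/f noise (band-limited 0.3–100 Hz, the typical
  infant-EEG spectral shape) at a requested signal-to-noise variance ratio,
  plus optional high-amplitude square-pulse artifacts that trip the epoch
  rejection rule.
- :func:`make_dyad_table` — per-dyad behavioral rows: beta-distributed
  rhythmic-movement proportions per condition and a negative-binomial
  expressive-vocabulary count optionally coupled to tracking or movement.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.special import expit, logit

from .audio import AudioTrack, BroadbandEnvelope
from .preprocess import DEFAULT_CHANNELS, RawEEG
from .trf import LagConfig

__all__ = [
    "SongSpec",
    "GroundTruthKernel",
    "BehaviorSpec",
    "make_song_audio",
    "make_synthetic_eeg",
    "make_dyad_table",
    "make_cohort_accuracy",
    "default_kernel",
    "verses_for_duration",
]

NOTES_PER_VERSE = 16
#: semitone offsets of the fixed verse melody (relative to the song pitch)
_MELODY = (0, 2, 4, 5, 4, 2, 0, -1, 0, 2, 4, 7, 4, 2, 0, 0)

_CONDITION_DEFAULTS: dict[str, dict] = {
    # tempo: metronome prompts; pitch/loudness: observed song means;
    # per-note jitter SDs: playsong more variable than lullaby throughout.
    "playsong": dict(
        tempo_bpm=170.0,
        pitch_hz=268.6,
        loudness_rms=0.056,
        tempo_jitter_frac=0.020,
        pitch_jitter_semitones=0.8,
        amp_jitter_frac=0.25,
        verse_tempo_sd=0.05,
        verse_pitch_semitones=1.5,
        verse_amp_sd=0.30,
    ),
    "lullaby": dict(
        tempo_bpm=100.0,
        pitch_hz=260.5,
        loudness_rms=0.045,
        tempo_jitter_frac=0.012,
        pitch_jitter_semitones=0.45,
        amp_jitter_frac=0.12,
        verse_tempo_sd=0.03,
        verse_pitch_semitones=1.0,
        verse_amp_sd=0.15,
    ),
}


@dataclass(frozen=True)
class SongSpec:
    """Parameters of one synthetic infant-directed song."""

    condition: str
    tempo_bpm: float
    pitch_hz: float
    loudness_rms: float
    variability: float | Mapping[str, float] = 1.0
    n_verses: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in _CONDITION_DEFAULTS:
            raise ValueError("condition must be 'playsong' or 'lullaby'")
        if self.tempo_bpm <= 0:
            raise ValueError("tempo_bpm must be positive")
        if self.pitch_hz <= 0:
            raise ValueError("pitch_hz must be positive")
        if self.n_verses < 1:
            raise ValueError("n_verses must be at least 1")

    @classmethod
    def for_condition(cls, condition: str, seed: int = 0, **overrides) -> "SongSpec":
        base = _CONDITION_DEFAULTS[condition]
        kwargs = dict(
            condition=condition,
            tempo_bpm=base["tempo_bpm"],
            pitch_hz=base["pitch_hz"],
            loudness_rms=base["loudness_rms"],
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def _jitter_sds(self) -> dict[str, float]:
        keys = ("tempo", "pitch", "amplitude", "verse_tempo", "verse_pitch", "verse_amplitude")
        base = _CONDITION_DEFAULTS[self.condition]
        if isinstance(self.variability, Mapping):
            mult = {k: float(self.variability.get(k, 1.0)) for k in keys}
        else:
            mult = {k: float(self.variability) for k in keys}
        return {
            "tempo": base["tempo_jitter_frac"] * mult["tempo"],
            "pitch": base["pitch_jitter_semitones"] * mult["pitch"],
            "amplitude": base["amp_jitter_frac"] * mult["amplitude"],
            "verse_tempo": base["verse_tempo_sd"] * mult["verse_tempo"],
            "verse_pitch": base["verse_pitch_semitones"] * mult["verse_pitch"],
            "verse_amplitude": base["verse_amp_sd"] * mult["verse_amplitude"],
        }


def verses_for_duration(tempo_bpm: float, duration_s: float) -> int:
    """Verse count whose note train covers at least ``duration_s`` seconds."""
    ioi = 60.0 / tempo_bpm
    return int(np.ceil(duration_s / (ioi * NOTES_PER_VERSE)))


def make_song_audio(
    spec: SongSpec,
    duration_s: float | None = None,
    sample_rate: int = 44100,
    min_duration_s: float = 30.0,
) -> AudioTrack:
    """Synthesize a verse-structured note train for one song.

    Notes are harmonic tone bursts (5 ms attack, exponential decay) at the
    nominal inter-onset interval 60/tempo with independent per-note Gaussian
    timing jitter plus a per-verse tempo deviation (singing drifts between
    verses rather than holding a metronomic grid); pitch follows a fixed
    verse melody around ``pitch_hz`` with per-note jitter and a per-verse
    transposition; per-verse and per-note loudness vary likewise. Ground-
    truth onset times and note f0 are stored in ``AudioTrack.meta``.
    Output is padded with silence to ``min_duration_s``.
    """
    n_verses = spec.n_verses
    if duration_s is not None:
        n_verses = max(n_verses, verses_for_duration(spec.tempo_bpm, duration_s))
    rng = np.random.default_rng(spec.seed)
    sds = spec._jitter_sds()
    ioi = 60.0 / spec.tempo_bpm
    n_notes = n_verses * NOTES_PER_VERSE
    verse_of = np.repeat(np.arange(n_verses), NOTES_PER_VERSE)

    verse_tempo = np.ones(n_verses)
    if sds["verse_tempo"] > 0:
        verse_tempo = np.clip(1.0 + rng.normal(0.0, sds["verse_tempo"], n_verses), 0.7, 1.3)
    iois = ioi * verse_tempo[verse_of]
    onsets = np.concatenate([[0.0], np.cumsum(iois[:-1])])
    if sds["tempo"] > 0:
        jitter = rng.normal(0.0, sds["tempo"] * ioi, size=n_notes)
        jitter[0] = abs(jitter[0])  # keep the first onset nonnegative
        onsets = onsets + jitter
    semis = np.tile(_MELODY, n_verses).astype(float)
    if sds["verse_pitch"] > 0:
        semis = semis + rng.normal(0.0, sds["verse_pitch"], n_verses)[verse_of]
    if sds["pitch"] > 0:
        semis = semis + rng.normal(0.0, sds["pitch"], size=n_notes)
    f0 = spec.pitch_hz * 2.0 ** (semis / 12.0)
    amps = np.ones(n_notes)
    if sds["verse_amplitude"] > 0:
        amps *= np.clip(1.0 + rng.normal(0.0, sds["verse_amplitude"], n_verses), 0.2, None)[verse_of]
    if sds["amplitude"] > 0:
        amps *= np.clip(1.0 + rng.normal(0.0, sds["amplitude"], size=n_notes), 0.1, None)

    note_len = min(0.28, 0.9 * ioi)
    n_note = int(round(note_len * sample_rate))
    t_note = np.arange(n_note) / sample_rate
    attack = int(round(0.005 * sample_rate))
    env = np.exp(-t_note / (note_len / 4.0))
    env[:attack] *= np.linspace(0.0, 1.0, attack)

    total = int(np.ceil((onsets[-1] + note_len) * sample_rate)) + 1
    out = np.zeros(total)
    harmonics = (1.0, 0.5, 0.25, 0.12)
    for i in range(n_notes):
        tone = np.zeros(n_note)
        for h, a in enumerate(harmonics, start=1):
            tone += a * np.sin(2.0 * np.pi * h * f0[i] * t_note)
        start = int(round(onsets[i] * sample_rate))
        out[start : start + n_note] += amps[i] * env * tone

    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out *= spec.loudness_rms / rms
    target = int(round(min_duration_s * sample_rate))
    if duration_s is not None:
        target = max(target, int(round(duration_s * sample_rate)))
    if out.size < target:
        out = np.pad(out, (0, target - out.size))
    return AudioTrack(
        out,
        sample_rate,
        meta={
            "condition": spec.condition,
            "onsets_s": onsets,
            "note_f0_hz": f0,
            "tempo_bpm": spec.tempo_bpm,
            "seed": spec.seed,
        },
    )


# ---------------------------------------------------------------------------
# EEG forward model


@dataclass
class GroundTruthKernel:
    """Known channel × lag TRF used to couple envelope and synthetic EEG."""

    lag_axis_ms: np.ndarray
    weights: np.ndarray  # (n_channels, n_lags)
    snr: float

    def __post_init__(self) -> None:
        self.lag_axis_ms = np.asarray(self.lag_axis_ms, dtype=float)
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.weights.shape[1] != self.lag_axis_ms.size:
            raise ValueError("kernel weights and lag axis disagree")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative (0 = no coupling)")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def default_kernel(
    n_channels: int = len(DEFAULT_CHANNELS),
    lags: LagConfig = LagConfig(),
    snr: float = 1.0,
) -> GroundTruthKernel:
    """Smooth biphasic kernel (positivity near 80 ms, negativity near
    200 ms) with a deterministic dipolar-like topography.

    The topography is zero-mean across channels, as for a tangential source,
    so the coupled signal survives average re-referencing.
    """
    lag_ms = lags.lags_ms
    shape = np.exp(-0.5 * ((lag_ms - 80.0) / 30.0) ** 2) - 0.8 * np.exp(
        -0.5 * ((lag_ms - 200.0) / 50.0) ** 2
    )
    shape[lag_ms < 0] = 0.0
    topo = np.cos(2.0 * np.pi * (np.arange(n_channels) + 0.25) / n_channels)
    return GroundTruthKernel(lag_ms, np.outer(topo, shape), snr)


def _one_over_f_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sfreq: float,
    fmin: float = 0.3,
    fmax: float = 100.0,
) -> np.ndarray:
    """Unit-variance noise with power ∝ 1/f, band-limited to fmin–fmax."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    amp = np.zeros_like(freqs)
    band = (freqs >= fmin) & (freqs <= fmax)
    amp[band] = 1.0 / np.sqrt(freqs[band])
    spec = amp * (rng.standard_normal((n_channels, freqs.size)) +
                  1j * rng.standard_normal((n_channels, freqs.size)))
    x = np.fft.irfft(spec, n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def make_synthetic_eeg(
    envelope: BroadbandEnvelope,
    kernel: GroundTruthKernel,
    n_channels: int | None = None,
    artifact_rate: float = 2.0,
    seed: int = 0,
    lags: LagConfig = LagConfig(),
    total_rms_uv: float = 20.0,
    ch_names: Sequence[str] | None = None,
) -> RawEEG:
    """Forward model: EEG = kernel ⊛ envelope + 1/f noise + artifacts.

    The z-scored envelope is convolved with each channel's kernel row; the
    coupled part and the noise are scaled so their variance ratio equals the
    kernel's ``snr`` exactly (``snr = inf`` → no noise, ``snr = 0`` → no
    coupling) and the clean channel RMS is ``total_rms_uv``. Square-pulse
    artifacts (150–300 μV, 200–600 ms) hit a Poisson number of epochs per
    minute on a random quarter of the channels.
    """
    if envelope.sample_rate != 500.0:
        raise ValueError("envelope must be sampled at 500 Hz")
    if not np.array_equal(kernel.lag_axis_ms, lags.lags_ms):
        raise ValueError("kernel lag grid does not match the encoder lag grid")
    n_ch = n_channels if n_channels is not None else kernel.n_channels
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if n_ch > kernel.n_channels:
        raise ValueError("kernel has fewer channels than requested")
    names = list(ch_names) if ch_names is not None else list(DEFAULT_CHANNELS[:n_ch])
    if len(names) != n_ch:
        raise ValueError("one channel name per channel is required")

    sfreq = envelope.sample_rate
    env = envelope.values
    env_sd = env.std()
    env_z = (env - env.mean()) / (env_sd if env_sd > 0 else 1.0)
    T = env.size
    lag_samp = lags.lags_samples(sfreq)
    offset = -int(lag_samp[0])  # number of negative-lag samples

    # y[t] = sum_j w_j * env[t - lag_j]
    conv = sp_signal.fftconvolve(kernel.weights[:n_ch], env_z[None, :], axes=1)
    coupled = conv[:, offset : offset + T]
    if coupled.shape[1] < T:
        coupled = np.pad(coupled, [(0, 0), (0, T - coupled.shape[1])])

    rng = np.random.default_rng(seed)
    noise = _one_over_f_noise(rng, n_ch, T, sfreq)

    snr = kernel.snr
    if np.isinf(snr):
        sig_rms = np.full(n_ch, total_rms_uv)
        noise_rms = 0.0
    else:
        sig_rms = np.full(n_ch, total_rms_uv * np.sqrt(snr / (1.0 + snr)))
        noise_rms = total_rms_uv * np.sqrt(1.0 / (1.0 + snr))
    coupled_sd = coupled.std(axis=1)
    gain = np.where(coupled_sd > 0, sig_rms / np.where(coupled_sd > 0, coupled_sd, 1.0), 0.0)
    coupled_scaled = coupled * gain[:, None]
    data = coupled_scaled + noise_rms * noise

    n_artifacts = rng.poisson(artifact_rate * T / sfreq / 60.0)
    artifact_spans = []
    for _ in range(n_artifacts):
        dur = int(rng.uniform(0.2, 0.6) * sfreq)
        start = int(rng.integers(0, max(T - dur, 1)))
        amp = rng.uniform(150.0, 300.0) * rng.choice([-1.0, 1.0])
        chans = rng.choice(n_ch, size=max(1, n_ch // 4), replace=False)
        data[np.ix_(chans, np.arange(start, min(start + dur, T)))] += amp
        artifact_spans.append((start, min(start + dur, T)))

    return RawEEG(
        data=data,
        sfreq=sfreq,
        ch_names=names,
        meta={
            "ground_truth": {
                "kernel_weights": kernel.weights[:n_ch],
                "effective_kernel": kernel.weights[:n_ch] * gain[:, None],
                "gain": gain,
                "snr": snr,
                "coupled_variance": float(np.mean(coupled_scaled.var(axis=1))),
                "noise_variance": float(noise_rms**2) if not np.isinf(snr) else 0.0,
                "coupled_signal": coupled_scaled,
                "artifact_spans": artifact_spans,
                "seed": seed,
            }
        },
    )


# ---------------------------------------------------------------------------
# behavior


@dataclass(frozen=True)
class BehaviorSpec:
    """Movement and vocabulary generating parameters.

    Movement proportions follow a beta distribution (logit-scale dyad random
    intercept, SD ``movement_dyad_sd``); vocabulary is an over-dispersed
    (negative-binomial) count with log-mean ``log(vocab_base) +
    vocab_slope * driver`` where the driver is the dyad's standardized
    playsong tracking (if accuracies are supplied) or playsong movement.
    """

    movement_mean: Mapping[str, float] = field(
        default_factory=lambda: {"playsong": 0.3, "lullaby": 0.1}
    )
    movement_precision: float = 50.0
    movement_dyad_sd: float = 0.3
    vocab_base: float = 150.0
    vocab_slope: float = 0.2
    vocab_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, mu in self.movement_mean.items():
            if not 0.0 < mu < 1.0:
                raise ValueError(f"movement_mean[{cond!r}] must lie strictly in (0,1)")
        if self.movement_precision <= 0:
            raise ValueError("movement_precision must be positive")
        if self.vocab_base < 0:
            raise ValueError("vocab_base must be nonnegative")


def make_dyad_table(
    n_dyads: int,
    behavior: BehaviorSpec,
    accuracy: pd.DataFrame | None = None,
    seed: int = 0,
    study: int = 2,
) -> pd.DataFrame:
    """One row per dyad × condition with movement, vocabulary and (optionally
    joined) tracking accuracy.

    ``accuracy`` is a tidy table with columns dyad_id, condition, data_type,
    channel, z (as written by the TRF stage); the channel-mean true-pairing
    z joins as ``z_accuracy``.
    """
    if n_dyads < 2:
        raise ValueError("need at least 2 dyads")
    conditions = list(behavior.movement_mean)
    rng = np.random.default_rng(seed)
    dyads = [f"D{i + 1:03d}" for i in range(n_dyads)]
    u = rng.normal(0.0, behavior.movement_dyad_sd, size=n_dyads)
    rows = []
    for d, dyad in enumerate(dyads):
        for cond in conditions:
            mu = float(expit(logit(behavior.movement_mean[cond]) + u[d]))
            phi = behavior.movement_precision
            y = float(rng.beta(mu * phi, (1.0 - mu) * phi))
            rows.append({"dyad_id": dyad, "condition": cond, "movement_prop": y, "study": study})
    table = pd.DataFrame(rows)

    acc_mean = None
    if accuracy is not None and len(accuracy):
        true_acc = accuracy[accuracy["data_type"] == "true"]
        zcol = "z" if "z" in true_acc.columns else "z_accuracy"
        acc_mean = (
            true_acc.groupby(["dyad_id", "condition"])[zcol].mean().rename("z_accuracy")
        )
        table = table.merge(acc_mean, on=["dyad_id", "condition"], how="left")

    # vocabulary driver: playsong tracking if available, else playsong movement
    play = table[table["condition"] == "playsong"].set_index("dyad_id")
    if acc_mean is not None and "z_accuracy" in table.columns and play["z_accuracy"].notna().all():
        driver = play["z_accuracy"]
    else:
        driver = play["movement_prop"]
    z = (driver - driver.mean()) / (driver.std(ddof=0) or 1.0)
    log_mu = np.log(max(behavior.vocab_base, 1e-9)) + behavior.vocab_slope * z
    mu = np.exp(log_mu)
    k = behavior.vocab_dispersion
    vocab = rng.negative_binomial(k, k / (k + mu.to_numpy()))
    vocab_map = dict(zip(play.index, vocab))
    table["vocabulary"] = table["dyad_id"].map(vocab_map)
    return table


def make_cohort_accuracy(
    n_dyads: int,
    channels: Sequence[str] | int = 8,
    true_mean: Mapping[str, float] | None = None,
    shifted_mean: float = 0.001,
    dyad_sd: float = 0.010,
    dyad_slope_sd: float = 0.004,
    channel_sd: float = 0.020,
    acoustic_effects: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy Fisher-z accuracy table with known group-level structure.

    Defaults mirror the study-scale effects: true-pairing accuracy higher
    for lullabies (0.074) than playsongs (0.057) and a shifted-pairing mean
    near zero. Acoustic feature columns are drawn around the observed song
    descriptives; ``acoustic_effects[(feature, condition)]`` adds a linear
    effect of the standardized feature on the true-pairing accuracy.
    """
    if true_mean is None:
        true_mean = {"lullaby": 0.074, "playsong": 0.057}
    if isinstance(channels, int):
        channels = list(DEFAULT_CHANNELS[:channels])
    rng = np.random.default_rng(seed)
    dyads = [f"D{i + 1:03d}" for i in range(n_dyads)]
    feat_params = {
        "rms_mean": {"lullaby": (0.045, 0.035), "playsong": (0.056, 0.033)},
        "rms_sd": {"lullaby": (0.028, 0.020), "playsong": (0.037, 0.021)},
        "tempo_bpm": {"lullaby": (119.0, 8.35), "playsong": (128.1, 14.3)},
        "tempo_sd": {"lullaby": (33.1, 6.2), "playsong": (35.8, 6.8)},
        "pitch_hz": {"lullaby": (260.5, 36.3), "playsong": (268.6, 32.7)},
        "pitch_sd": {"lullaby": (34.1, 6.4), "playsong": (42.2, 6.2)},
        "pulse_clarity": {"lullaby": (0.059, 0.030), "playsong": (0.065, 0.026)},
        "pulse_clarity_sd": {"lullaby": (0.064, 0.011), "playsong": (0.061, 0.009)},
    }
    rows = []
    intercepts = rng.normal(0.0, dyad_sd, size=n_dyads)
    slopes = rng.normal(0.0, dyad_slope_sd, size=(n_dyads, 2))
    for d, dyad in enumerate(dyads):
        for ci, cond in enumerate(("lullaby", "playsong")):
            feats = {
                name: rng.normal(*params[cond]) for name, params in feat_params.items()
            }
            feat_term = 0.0
            if acoustic_effects:
                for (fname, fcond), beta in acoustic_effects.items():
                    if fcond == cond:
                        mu_f, sd_f = feat_params[fname][cond]
                        feat_term += beta * (feats[fname] - mu_f) / sd_f
            for data_type in ("true", "shifted"):
                base = true_mean[cond] if data_type == "true" else shifted_mean
                level = base + intercepts[d] + (slopes[d, ci] if data_type == "true" else 0.0)
                if data_type == "true":
                    level += feat_term
                for ch in channels:
                    rows.append(
                        {
                            "dyad_id": dyad,
                            "condition": cond,
                            "data_type": data_type,
                            "channel": ch,
                            "z_accuracy": level + rng.normal(0.0, channel_sd),
                            **feats,
                        }
                    )
    return pd.DataFrame(rows)
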