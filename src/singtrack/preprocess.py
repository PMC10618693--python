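"""Infant-EEG cleaning chain and envelope-aligned epoching.

The chain mirrors standard developmental-EEG practice for naturalistic
recordings: zero-phase FIR band-pass (0.3–100 Hz, −6 dB at 0.15/100.15 Hz),
line-noise suppression at 50/100 Hz, iterative bad-channel detection on the
average log band-power, wavelet thresholding of transient artifacts
(coif4, hard, level-dependent universal threshold), spherical-spline
interpolation of bad channels, average reference over the scalp set,
segmentation into non-overlapping 1-s epochs, and rejection of any epoch in
which a 200-ms sliding window on any electrode exceeds 100 μV SD. Subjects
retaining fewer than 90 artifact-free epochs are flagged excluded.

Every step appends its name and parameters to a log, so a cleaning run is
replayable from the log alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pywt
from scipy import signal

from .audio import BroadbandEnvelope

__all__ = [
    "RawEEG",
    "CleanEEG",
    "AlignedDataset",
    "DEFAULT_CHANNELS",
    "bandpass_raw",
    "remove_line_noise",
    "detect_bad_channels",
    "wavelet_denoise",
    "interpolate_channels",
    "rereference_average",
    "epoch_and_reject",
    "bandpass_final",
    "preprocess_pipeline",
    "montage_positions",
]

#: Scalp electrodes used for the average reference (10–20 extended names).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "F7", "F8", "F9", "F3", "Fz", "F4", "FT7", "FC3", "FCz", "FC4", "FT8",
    "T8", "C4", "Cz", "C3", "T7", "CP3", "CP4", "TP10", "P8", "P4", "Pz",
    "P3", "P7", "PO9", "PO10", "O1", "Oz", "O2",
)

MIN_EPOCHS_FOR_INCLUSION = 90
EPOCH_LENGTH_S = 1.0
REJECT_SD_UV = 100.0
REJECT_WINDOW_S = 0.2


@dataclass
class RawEEG:
    """Continuous EEG in μV, channels × samples."""

    data: np.ndarray
    sfreq: float = 500.0
    ch_names: Sequence[str] = ()
    bads: set = field(default_factory=set)
    log: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.ch_names:
            self.ch_names = [f"CH{i:02d}" for i in range(self.data.shape[0])]
        self.ch_names = list(self.ch_names)
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("one label per channel is required")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] < 2:
            raise ValueError("at least two channels are required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def _with(self, data: np.ndarray, step: str, **params) -> "RawEEG":
        return RawEEG(
            data=data,
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            bads=set(self.bads),
            log=self.log + [{"step": step, **params}],
            meta=dict(self.meta),
        )


@dataclass
class CleanEEG:
    """Artifact-cleaned, average-referenced continuous EEG."""

    data: np.ndarray
    sfreq: float
    ch_names: Sequence[str]
    interpolated: set = field(default_factory=set)
    reference: str = "average"
    log: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class AlignedDataset:
    """Epoch-screened EEG paired sample-by-sample with its envelope."""

    epochs: np.ndarray  # (n, channels, samples_per_epoch)
    envelope_segments: np.ndarray  # (n, samples_per_epoch)
    condition: str
    sfreq: float = 500.0
    ch_names: Sequence[str] = ()
    retained_epoch_count: int = 0
    total_epoch_count: int = 0
    excluded: bool = False
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs.shape[0] != self.envelope_segments.shape[0]:
            raise ValueError("epochs and envelope segments must share their index")
        if self.epochs.shape[2] != self.envelope_segments.shape[1]:
            raise ValueError("epochs and envelope segments must share their length")
        self.retained_epoch_count = self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


# ---------------------------------------------------------------------------
# filtering


def _fir_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with reflection padding; zero net delay."""
    ntaps = taps.size
    pad = ntaps // 2
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.fftconvolve(padded, taps[np.newaxis, :] if data.ndim == 2 else taps, mode="same", axes=-1)
    return out[..., pad:-pad]


def bandpass_raw(
    eeg: RawEEG, l_freq: float = 0.3, h_freq: float = 100.0, trans_bw: float = 0.3
) -> RawEEG:
    """Zero-phase FIR band-pass; −6 dB points at l_freq∓trans_bw/2 and
    h_freq±trans_bw/2 (defaults: 0.15 and 100.15 Hz)."""
    ntaps = int(np.ceil(3.3 / (trans_bw / eeg.sfreq)))
    ntaps += 1 - ntaps % 2  # odd length => exactly linear phase, integer delay
    if eeg.n_samples < 3 * ntaps:
        raise ValueError(
            f"recording ({eeg.n_samples} samples) shorter than 3x filter length ({3 * ntaps})"
        )
    taps = signal.firwin(ntaps, [l_freq, h_freq], pass_zero=False, fs=eeg.sfreq)
    out = _fir_zero_phase(eeg.data, taps)
    return eeg._with(out, "bandpass_raw", l_freq=l_freq, h_freq=h_freq, ntaps=ntaps)


def remove_line_noise(
    eeg: RawEEG, freqs: Iterable[float] = (50.0, 100.0), halfwidth: float = 0.6
) -> RawEEG:
    """Suppress line components by clamping FFT-bin magnitudes around each
    target frequency to the flanking noise floor.

    Only bins exceeding twice the flank-mean magnitude are touched and their
    phases are kept, so a signal without a line component passes through
    nearly unchanged; bands beyond ±2 Hz are untouched exactly.
    """
    n = eeg.n_samples
    spec = np.fft.rfft(eeg.data, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / eeg.sfreq)
    for f0 in freqs:
        if f0 >= eeg.sfreq / 2:
            raise ValueError(f"line frequency {f0} Hz is not below Nyquist")
        notch = np.abs(f - f0) <= halfwidth
        flank = (np.abs(f - f0) > halfwidth) & (np.abs(f - f0) <= 2.0)
        if not notch.any() or not flank.any():
            continue
        floor = np.mean(np.abs(spec[:, flank]), axis=1, keepdims=True)
        mag = np.abs(spec[:, notch])
        thresh = 2.0 * floor
        excess = mag > thresh
        scale = np.where(excess, thresh / np.maximum(mag, 1e-300), 1.0)
        spec[:, notch] *= scale
    out = np.fft.irfft(spec, n, axis=1)
    return eeg._with(out, "remove_line_noise", freqs=list(freqs), halfwidth=halfwidth)


# ---------------------------------------------------------------------------
# bad channels and artifacts


def _log_band_power(data: np.ndarray, sfreq: float, fmin: float, fmax: float) -> np.ndarray:
    nper = min(int(4 * sfreq), data.shape[1])
    f, pxx = signal.welch(data, fs=sfreq, nperseg=nper, axis=1)
    band = (f >= fmin) & (f <= fmax)
    return np.mean(np.log(pxx[:, band] + 1e-30), axis=1)


def detect_bad_channels(
    eeg: RawEEG, z_thresh: float = 3.0, passes: int = 2, fmin: float = 1.0, fmax: float = 100.0
) -> set:
    """Flag channels whose average log band-power (1–100 Hz) deviates more
    than ``z_thresh`` SD from the channel mean; repeated on the remainder.

    Returns the union over passes. Raises if every channel ends up flagged.
    """
    if eeg.n_channels < 4:
        raise ValueError("bad-channel detection needs at least 4 channels")
    power = _log_band_power(eeg.data, eeg.sfreq, fmin, fmax)
    remaining = list(range(eeg.n_channels))
    flagged: set = set()
    for _ in range(passes):
        vals = power[remaining]
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            break
        z = (vals - mu) / sd
        new = [remaining[i] for i in np.flatnonzero(np.abs(z) > z_thresh)]
        if not new:
            break
        flagged.update(new)
        remaining = [i for i in remaining if i not in flagged]
        if not remaining:
            raise RuntimeError(
                "all channels flagged as bad; recording unusable "
                f"(log band-power range {power.min():.2f}..{power.max():.2f})"
            )
    return {eeg.ch_names[i] for i in flagged}


def wavelet_denoise(
    eeg: RawEEG, wavelet: str = "coif4", level: int = 9
) -> RawEEG:
    """Remove transient artifacts by hard, level-dependent wavelet
    thresholding: per level, σ = MAD/0.6745 and threshold σ·√(2 ln N); the
    reconstruction of supra-threshold coefficients (the artifact estimate)
    is subtracted from each channel."""
    out = np.empty_like(eeg.data)
    n = eeg.n_samples
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    lev = min(level, max_level)
    thr_factor = np.sqrt(2.0 * np.log(max(n, 2)))
    for c in range(eeg.n_channels):
        x = eeg.data[c]
        coeffs = pywt.wavedec(x, wavelet, level=lev)
        artifact_coeffs = []
        for arr in coeffs:
            sigma = np.median(np.abs(arr - np.median(arr))) / 0.6745
            thr = sigma * thr_factor
            artifact_coeffs.append(np.where(np.abs(arr) > thr, arr, 0.0))
        artifact = pywt.waverec(artifact_coeffs, wavelet)[:n]
        out[c] = x - artifact
    return eeg._with(out, "wavelet_denoise", wavelet=wavelet, level=lev)


# ---------------------------------------------------------------------------
# interpolation and reference


def _standard_montage():
    import mne

    for name in ("colin27_1005", "standard_1005", "standard_1020"):
        try:
            return mne.channels.make_standard_montage(name)
        except Exception:
            continue
    raise RuntimeError("no standard 10-20 montage available")


def montage_positions(ch_names: Sequence[str]) -> np.ndarray:
    """3-D positions (meters) of 10–20 electrode labels."""
    montage = _standard_montage()
    pos = montage.get_positions()["ch_pos"]
    out = []
    for name in ch_names:
        if name not in pos:
            raise KeyError(f"no template position for electrode {name!r}")
        out.append(pos[name])
    return np.asarray(out)


def interpolate_channels(eeg: RawEEG, bads: Iterable[str] | None = None) -> RawEEG:
    """Replace bad channels by spherical-spline estimates from the good ones."""
    import mne

    bads = set(bads) if bads is not None else set(eeg.bads)
    unknown = bads - set(eeg.ch_names)
    if unknown:
        raise ValueError(f"bad labels not in recording: {sorted(unknown)}")
    if not bads:
        return eeg._with(eeg.data.copy(), "interpolate_channels", bads=[])
    if eeg.n_channels - len(bads) < 4:
        raise ValueError("need at least 4 good channels for interpolation")
    info = mne.create_info(list(eeg.ch_names), eeg.sfreq, ch_types="eeg")
    raw = mne.io.RawArray(eeg.data * 1e-6, info, verbose="error")
    raw.set_montage(_standard_montage(), on_missing="raise", verbose="error")
    raw.info["bads"] = sorted(bads)
    raw.interpolate_bads(reset_bads=True, mode="accurate", verbose="error")
    out = eeg._with(raw.get_data() * 1e6, "interpolate_channels", bads=sorted(bads))
    out.bads = set()
    out.meta = {**eeg.meta, "interpolated": sorted(bads)}
    return out


def rereference_average(eeg: RawEEG, reference_channels: Sequence[str] | None = None) -> CleanEEG:
    """Re-reference to the average of the scalp set (idempotent)."""
    ref = list(reference_channels) if reference_channels else [
        ch for ch in eeg.ch_names if ch in DEFAULT_CHANNELS
    ] or list(eeg.ch_names)
    idx = [eeg.ch_names.index(ch) for ch in ref]
    mean = eeg.data[idx].mean(axis=0, keepdims=True)
    data = eeg.data - mean
    return CleanEEG(
        data=data,
        sfreq=eeg.sfreq,
        ch_names=list(eeg.ch_names),
        interpolated=set(eeg.meta.get("interpolated", [])),
        reference="average",
        log=eeg.log + [{"step": "rereference_average", "channels": ref}],
        meta=dict(eeg.meta),
    )


# ---------------------------------------------------------------------------
# epoching


def _max_sliding_sd(epoch: np.ndarray, window: int) -> float:
    """Max over channels and 1-sample-step windows of the windowed SD."""
    x = epoch
    c1 = np.cumsum(np.concatenate([np.zeros((x.shape[0], 1)), x], axis=1), axis=1)
    c2 = np.cumsum(np.concatenate([np.zeros((x.shape[0], 1)), x**2], axis=1), axis=1)
    s1 = c1[:, window:] - c1[:, :-window]
    s2 = c2[:, window:] - c2[:, :-window]
    var = np.clip(s2 / window - (s1 / window) ** 2, 0.0, None)
    # ddof=1 to match the conventional sample SD used in rejection rules
    var = var * window / (window - 1)
    return float(np.sqrt(var.max())) if var.size else 0.0


def epoch_rejection_mask(
    epochs: np.ndarray,
    sfreq: float,
    sd_thresh: float = REJECT_SD_UV,
    window_s: float = REJECT_WINDOW_S,
) -> np.ndarray:
    """Boolean keep-mask: an epoch is dropped iff any 200-ms sliding window
    (step 1 sample) on any electrode exceeds the SD threshold."""
    window = int(round(window_s * sfreq))
    return np.array(
        [_max_sliding_sd(ep, window) <= sd_thresh for ep in epochs], dtype=bool
    )


def epoch_and_reject(
    eeg: CleanEEG,
    envelope: BroadbandEnvelope,
    condition: str,
    sd_thresh: float = REJECT_SD_UV,
    window_s: float = REJECT_WINDOW_S,
    min_epochs: int = MIN_EPOCHS_FOR_INCLUSION,
) -> AlignedDataset:
    """Cut non-overlapping 1-s epochs, drop artifact epochs, segment the
    envelope identically, and flag subjects below the epoch-count floor."""
    n_eeg = eeg.data.shape[1]
    n_env = envelope.values.size
    if abs(n_eeg - n_env) > 1:
        raise ValueError(
            f"EEG ({n_eeg} samples) and envelope ({n_env}) do not cover the same span"
        )
    n = min(n_eeg, n_env)
    per = int(round(EPOCH_LENGTH_S * eeg.sfreq))
    n_ep = n // per
    if n_ep == 0:
        raise ValueError("recording shorter than one epoch")
    eeg_ep = eeg.data[:, : n_ep * per].reshape(eeg.data.shape[0], n_ep, per).transpose(1, 0, 2)
    env_ep = envelope.values[: n_ep * per].reshape(n_ep, per)
    keep = epoch_rejection_mask(eeg_ep, eeg.sfreq, sd_thresh, window_s)
    ds = AlignedDataset(
        epochs=eeg_ep[keep],
        envelope_segments=env_ep[keep],
        condition=condition,
        sfreq=eeg.sfreq,
        ch_names=list(eeg.ch_names),
        total_epoch_count=n_ep,
        excluded=bool(keep.sum() < min_epochs),
        log=eeg.log
        + [{
            "step": "epoch_and_reject",
            "sd_thresh": sd_thresh,
            "window_s": window_s,
            "retained": int(keep.sum()),
            "total": n_ep,
        }],
    )
    return ds


def bandpass_final(
    ds: AlignedDataset, l_freq: float = 1.0, h_freq: float = 10.0, ntaps: int = 501
) -> AlignedDataset:
    """Zero-phase 1–10 Hz FIR applied per epoch with reflection padding."""
    if ds.n_epochs == 0:
        return ds
    taps = signal.firwin(ntaps, [l_freq, h_freq], pass_zero=False, fs=ds.sfreq)
    per = ds.epochs.shape[2]
    pad = per  # reflect a full epoch on both sides to tame transients
    padded = np.pad(ds.epochs, [(0, 0), (0, 0), (pad, pad)], mode="reflect")
    filtered = _fir_zero_phase(
        padded.reshape(-1, padded.shape[2]), taps
    ).reshape(padded.shape)[:, :, pad:-pad]
    return AlignedDataset(
        epochs=filtered,
        envelope_segments=ds.envelope_segments,
        condition=ds.condition,
        sfreq=ds.sfreq,
        ch_names=list(ds.ch_names),
        total_epoch_count=ds.total_epoch_count,
        excluded=ds.excluded,
        log=ds.log + [{"step": "bandpass_final", "l_freq": l_freq, "h_freq": h_freq, "ntaps": ntaps}],
    )


# ---------------------------------------------------------------------------
# pipeline


def preprocess_pipeline(
    raw: RawEEG,
    envelope: BroadbandEnvelope,
    condition: str,
    line_freqs: Iterable[float] = (50.0, 100.0),
    bad_channel_passes: int = 2,
    final_band: tuple[float, float] = (1.0, 10.0),
) -> AlignedDataset:
    """Run the full cleaning chain and return the envelope-aligned dataset."""
    eeg = bandpass_raw(raw)
    eeg = remove_line_noise(eeg, freqs=line_freqs)
    bads = detect_bad_channels(eeg, passes=bad_channel_passes)
    eeg = wavelet_denoise(eeg)
    eeg = interpolate_channels(eeg, bads)
    clean = rereference_average(eeg)
    ds = epoch_and_reject(clean, envelope, condition)
    return bandpass_final(ds, *final_band)
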