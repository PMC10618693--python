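"""File interfaces: WAV, BrainVision/EDF, array bundles, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .audio import AudioTrack, BroadbandEnvelope
from .preprocess import RawEEG

__all__ = [
    "write_wav",
    "read_wav",
    "write_brainvision",
    "read_raw_eeg",
    "save_array_bundle",
    "load_array_bundle",
    "save_envelope",
    "load_envelope",
    "save_json",
    "load_json",
]


def write_wav(path: str | Path, track: AudioTrack) -> Path:
    """Write PCM 16-bit WAV, rescaled to 90% full scale."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    peak = np.max(np.abs(track.samples)) or 1.0
    data = np.int16(np.round(track.samples / peak * 0.9 * 32767))
    wavfile.write(path, track.sample_rate, data)
    return path


def read_wav(path: str | Path) -> AudioTrack:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / np.abs(np.iinfo(data.dtype).min)
    return AudioTrack(np.asarray(data, dtype=float), int(rate))


def write_brainvision(basepath: str | Path, eeg: RawEEG) -> Path:
    """Write a minimal BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE float32,
    multiplexed, μV)."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name
    vhdr = base.with_suffix(".vhdr")
    vmrk = base.with_suffix(".vmrk")
    eegf = base.with_suffix(".eeg")
    interval_us = 1e6 / eeg.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by singtrack",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={eeg.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(eeg.ch_names, start=1):
        lines.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={name}.eeg\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    eeg.data.T.astype("<f4").tofile(eegf)
    return vhdr


def read_raw_eeg(path: str | Path) -> RawEEG:
    """Read BrainVision (.vhdr) or EDF (.edf) into a RawEEG (μV)."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG container: {path.suffix}")
    return RawEEG(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
    )


def save_array_bundle(basepath: str | Path, array: np.ndarray, header: dict) -> Path:
    """Binary array file (.npy) with a JSON sidecar header."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.save(base.with_suffix(".npy"), np.asarray(array))
    save_json(base.with_suffix(".json"), header)
    return base.with_suffix(".npy")


def load_array_bundle(basepath: str | Path) -> tuple[np.ndarray, dict]:
    base = Path(basepath)
    return np.load(base.with_suffix(".npy")), load_json(base.with_suffix(".json"))


def save_envelope(basepath: str | Path, env: BroadbandEnvelope, provenance: dict | None = None) -> Path:
    header = {"sample_rate": env.sample_rate, "length": int(env.values.size)}
    header.update(provenance or {})
    return save_array_bundle(basepath, env.values, header)


def load_envelope(basepath: str | Path) -> BroadbandEnvelope:
    values, header = load_array_bundle(basepath)
    return BroadbandEnvelope(values, header.get("sample_rate", 500.0))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return super().default(obj)


def save_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder), encoding="utf-8")
    return path


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
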