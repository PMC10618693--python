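"""Shared fixtures; expensive end-to-end simulations are session-scoped so
unit and acceptance tests reuse one computation."""

from __future__ import annotations

import numpy as np
import pytest

from singtrack.audio import envelope_from_audio
from singtrack.preprocess import AlignedDataset
from singtrack.synth import SongSpec, default_kernel, make_song_audio, make_synthetic_eeg
from singtrack.trf import TRFEncoder


def dataset_from_raw(raw, env, condition="playsong"):
    """Epoch synthetic EEG directly (no cleaning chain), for encoder tests."""
    T = min(env.values.size, raw.data.shape[1])
    per = 500
    n_ep = T // per
    n_ch = raw.data.shape[0]
    epochs = raw.data[:, : n_ep * per].reshape(n_ch, n_ep, per).transpose(1, 0, 2)
    envseg = env.values[: n_ep * per].reshape(n_ep, per)
    return AlignedDataset(
        epochs=epochs,
        envelope_segments=envseg,
        condition=condition,
        ch_names=list(raw.ch_names),
        total_epoch_count=n_ep,
    )


def make_coupled_dataset(
    snr: float,
    seed: int,
    duration_s: float = 60.0,
    n_channels: int = 8,
    artifact_rate: float = 0.0,
):
    spec = SongSpec.for_condition("playsong", seed=seed)
    audio = make_song_audio(spec, duration_s=duration_s)
    env = envelope_from_audio(audio)
    kernel = default_kernel(n_channels, snr=snr)
    raw = make_synthetic_eeg(
        env, kernel, n_channels=n_channels, artifact_rate=artifact_rate, seed=seed + 1
    )
    return raw, env


@pytest.fixture(scope="session")
def coupled_fit():
    """One coupled subject (snr=1, 90 s) with a CV-fitted TRF."""
    raw, env = make_coupled_dataset(snr=1.0, seed=11, duration_s=90.0)
    ds = dataset_from_raw(raw, env)
    results = TRFEncoder(ds).fit()
    return raw, ds, results


@pytest.fixture(scope="session")
def kernel_recovery_by_snr():
    """Mean correlation between fitted and ground-truth TRF weights at
    snr 4 / 1 / 0.25, each from >= 240 one-second epochs."""
    out = {}
    for snr in (4.0, 1.0, 0.25):
        raw, env = make_coupled_dataset(snr=snr, seed=21, duration_s=245.0)
        ds = dataset_from_raw(raw, env)
        res = TRFEncoder(ds, train_fraction=0.98).fit()
        gt = raw.meta["ground_truth"]["effective_kernel"]
        cors = [
            np.corrcoef(res.weights[c], gt[c])[0, 1] for c in range(gt.shape[0])
        ]
        out[snr] = float(np.mean(cors))
    return out


@pytest.fixture(scope="session")
def cluster_type1_fraction():
    """Fraction of 200 null cohorts (no common kernel) with any significant
    cluster at alpha = 0.05."""
    from singtrack.inference import cluster_test

    rng = np.random.default_rng(1234)
    n_subj, n_ch, n_lags = 12, 6, 40
    adjacency = np.zeros((n_ch, n_ch), dtype=bool)  # chain adjacency
    for i in range(n_ch - 1):
        adjacency[i, i + 1] = adjacency[i + 1, i] = True
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        weights = rng.standard_normal((n_subj, n_ch, n_lags))
        result = cluster_test(
            weights,
            adjacency=adjacency,
            n_randomizations=250,
            alpha=0.05,
            seed=rep,
        )
        if result.significant():
            hits += 1
    return hits / n_rep
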