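"""Stage orchestration: configuration, seeds, manifests, file interfaces.

A run directory is populated stage by stage (simulate → features →
preprocess → trf → permute → cluster → stats); every stage writes its
outputs plus a manifest entry with the configuration snapshot, input/output
hashes, and wall time. All randomness flows from one master seed that spawns
per-stage child seeds recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .audio import FeatureConfig, acoustic_features, envelope_from_audio
from .inference import cluster_test, shifted_null
from .preprocess import preprocess_pipeline
from .stats import fit_accuracy_model, fit_movement_model, fit_vocabulary_models
from .synth import BehaviorSpec, SongSpec, default_kernel, make_dyad_table, make_song_audio, make_synthetic_eeg
from .trf import LagConfig, LambdaGrid, TRFEncoder, accuracy_table

__all__ = ["RunConfig", "RunManifest", "run_stage", "STAGES"]

STAGES = ("simulate", "features", "preprocess", "trf", "permute", "cluster", "stats")


class ConfigError(ValueError):
    """Configuration failed schema validation."""


@dataclass
class RunConfig:
    """All run parameters; every analysis default is present and overridable."""

    n_dyads: int = 6  # the cluster stage needs at least 6 subjects
    conditions: Sequence[str] = ("playsong", "lullaby")
    duration_s: float = 60.0
    n_channels: int = 8
    snr: float = 1.0
    artifact_rate: float = 2.0
    # filtering / rejection
    bandpass_low_hz: float = 0.3
    bandpass_high_hz: float = 100.0
    line_freqs: Sequence[float] = (50.0, 100.0)
    bad_channel_passes: int = 2
    final_band_hz: Sequence[float] = (1.0, 10.0)
    reject_sd_uv: float = 100.0
    reject_window_s: float = 0.2
    min_epochs: int = 90
    # encoding
    lag_t_min_ms: float = -100.0
    lag_t_max_ms: float = 500.0
    lag_step_ms: float = 2.0
    lambda_min_exponent: int = -7
    lambda_max_exponent: int = 7
    folds: int = 5
    train_fraction: float = 0.8
    # inference
    n_permutations: int = 400
    n_randomizations: int = 1000
    cluster_alpha: float = 0.05
    # descriptors
    bpm_min: float = 55.0
    bpm_max: float = 210.0
    seed: int = 0
    out_dir: str = "runs/demo"

    def __post_init__(self) -> None:
        checks = [
            (self.n_dyads >= 1, "n_dyads must be >= 1"),
            (self.duration_s > 0, "duration_s must be positive"),
            (self.n_channels >= 2, "n_channels must be >= 2"),
            (self.snr >= 0, "snr must be nonnegative"),
            (self.lambda_min_exponent <= self.lambda_max_exponent, "empty lambda grid"),
            (self.folds >= 2, "folds must be >= 2"),
            (0 < self.train_fraction < 1, "train_fraction must be in (0,1)"),
            (self.n_permutations >= 1, "n_permutations must be >= 1"),
            (self.bpm_min < self.bpm_max, "bpm search range is empty"),
            (all(c in ("playsong", "lullaby") for c in self.conditions), "unknown condition"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    @property
    def lag_config(self) -> LagConfig:
        return LagConfig(self.lag_t_min_ms, self.lag_t_max_ms, self.lag_step_ms)

    @property
    def lambda_grid(self) -> LambdaGrid:
        return LambdaGrid(self.lambda_min_exponent, self.lambda_max_exponent)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31 - 1)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, outputs: dict, seed: int) -> None:
        self.stages[stage] = {
            "wall_time_s": round(seconds, 3),
            "seed": seed,
            "outputs": outputs,
        }

    def save(self, out_dir: Path) -> Path:
        return io.save_json(out_dir / "manifest.json", {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
        })

    @classmethod
    def load_or_new(cls, out_dir: Path, config: "RunConfig") -> "RunManifest":
        path = out_dir / "manifest.json"
        if path.exists():
            payload = io.load_json(path)
            return cls(config=payload.get("config", asdict(config)),
                       version=payload.get("version", __version__),
                       stages=payload.get("stages", {}))
        return cls(config=asdict(config))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _dyad_ids(cfg: RunConfig) -> list[str]:
    return [f"D{i + 1:03d}" for i in range(cfg.n_dyads)]


def _audio_base(out: Path, dyad: str, cond: str) -> Path:
    return out / "audio" / f"{dyad}_{cond}"


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    kernel = default_kernel(cfg.n_channels, cfg.lag_config, snr=cfg.snr)
    ground_truth = {"snr": cfg.snr, "seed": cfg.seed, "dyads": {}}
    for dyad in _dyad_ids(cfg):
        for cond in cfg.conditions:
            song_seed = int(rng.integers(2**31 - 1))
            eeg_seed = int(rng.integers(2**31 - 1))
            spec = SongSpec.for_condition(cond, seed=song_seed)
            audio = make_song_audio(spec, duration_s=cfg.duration_s)
            io.write_wav(_audio_base(out, dyad, cond).with_suffix(".wav"), audio)
            env = envelope_from_audio(audio)
            raw = make_synthetic_eeg(
                env, kernel, n_channels=cfg.n_channels,
                artifact_rate=cfg.artifact_rate, seed=eeg_seed, lags=cfg.lag_config,
            )
            io.write_brainvision(out / "eeg" / f"{dyad}_{cond}", raw)
            ground_truth["dyads"][f"{dyad}_{cond}"] = {
                "song_seed": song_seed, "eeg_seed": eeg_seed,
            }
    behavior = BehaviorSpec(seed=int(rng.integers(2**31 - 1)))
    table = make_dyad_table(max(cfg.n_dyads, 2), behavior, seed=behavior.seed)
    table.to_csv(out / "behavior.csv", index=False)
    io.save_json(out / "ground_truth.json", {
        **ground_truth,
        "kernel_lag_ms": kernel.lag_axis_ms,
        "kernel_weights": kernel.weights,
    })
    return {"behavior": _hash_file(out / "behavior.csv")}


def _stage_features(cfg: RunConfig, out: Path, seed: int) -> dict:
    feat_cfg = FeatureConfig(bpm_min=cfg.bpm_min, bpm_max=cfg.bpm_max)
    rows = []
    for dyad in _dyad_ids(cfg):
        for cond in cfg.conditions:
            wav = _audio_base(out, dyad, cond).with_suffix(".wav")
            if not wav.exists():
                raise FileNotFoundError(f"missing input {wav}; run the simulate stage first")
            audio = io.read_wav(wav)
            mask_csv = _audio_base(out, dyad, cond).with_suffix(".exclude.csv")
            mask = None
            if mask_csv.exists():
                mask = [tuple(r) for r in pd.read_csv(mask_csv).to_numpy()]
            env = envelope_from_audio(audio)
            io.save_envelope(out / "envelopes" / f"{dyad}_{cond}", env,
                             provenance={"source": wav.name})
            feats = acoustic_features(audio, feat_cfg, exclusion_mask=mask)
            rows.append({"dyad_id": dyad, "condition": cond, **feats.as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(out / "acoustic_features.csv", index=False)
    return {"acoustic_features": _hash_file(out / "acoustic_features.csv")}


def _stage_preprocess(cfg: RunConfig, out: Path, seed: int) -> dict:
    outputs = {}
    for dyad in _dyad_ids(cfg):
        for cond in cfg.conditions:
            vhdr = (out / "eeg" / f"{dyad}_{cond}").with_suffix(".vhdr")
            if not vhdr.exists():
                raise FileNotFoundError(f"missing input {vhdr}; run the simulate stage first")
            raw = io.read_raw_eeg(vhdr)
            env = io.load_envelope(out / "envelopes" / f"{dyad}_{cond}")
            ds = preprocess_pipeline(
                raw, env, cond,
                line_freqs=cfg.line_freqs,
                bad_channel_passes=cfg.bad_channel_passes,
                final_band=tuple(cfg.final_band_hz),
            )
            base = out / "aligned" / f"{dyad}_{cond}"
            io.save_array_bundle(base.with_name(base.name + "_epochs"), ds.epochs, {
                "condition": cond, "sfreq": ds.sfreq, "ch_names": list(ds.ch_names),
                "retained": ds.retained_epoch_count, "total": ds.total_epoch_count,
                "excluded": ds.excluded, "log": ds.log,
            })
            io.save_array_bundle(
                base.with_name(base.name + "_envseg"), ds.envelope_segments,
                {"condition": cond, "sfreq": ds.sfreq},
            )
            outputs[f"{dyad}_{cond}_retained"] = ds.retained_epoch_count
    return outputs


def _load_aligned(out: Path, dyad: str, cond: str):
    from .preprocess import AlignedDataset

    base = out / "aligned" / f"{dyad}_{cond}"
    epochs, header = io.load_array_bundle(base.with_name(base.name + "_epochs"))
    envseg, _ = io.load_array_bundle(base.with_name(base.name + "_envseg"))
    return AlignedDataset(
        epochs=epochs, envelope_segments=envseg, condition=cond,
        sfreq=header["sfreq"], ch_names=header["ch_names"],
        total_epoch_count=header["total"], excluded=header["excluded"],
    )


def _stage_trf(cfg: RunConfig, out: Path, seed: int) -> dict:
    records = []
    outputs = {}
    for dyad in _dyad_ids(cfg):
        for cond in cfg.conditions:
            ds = _load_aligned(out, dyad, cond)
            enc = TRFEncoder(
                ds, lags=cfg.lag_config, grid=cfg.lambda_grid,
                folds=cfg.folds, train_fraction=cfg.train_fraction, dyad_id=dyad,
            )
            res = enc.fit()
            base = out / "trf" / f"{dyad}_{cond}"
            io.save_array_bundle(base, res.weights, {
                "dyad_id": dyad, "condition": cond,
                "lambda_selected": res.lambda_selected,
                "lags_ms": res.lags_ms, "ch_names": res.ch_names,
                "intercept": res.intercept,
                "cv": res.cv_accuracy_by_lambda.to_dict(orient="list")
                if res.cv_accuracy_by_lambda is not None else None,
                "n_train": int(enc.train_idx.size), "n_test": int(enc.test_idx.size),
            })
            records.extend(res.score())
            outputs[f"{dyad}_{cond}_lambda"] = res.lambda_selected
    accuracy_table(records).to_csv(out / "accuracy_true.csv", index=False)
    outputs["accuracy_true"] = _hash_file(out / "accuracy_true.csv")
    return outputs


def _refit(cfg: RunConfig, out: Path, dyad: str, cond: str):
    ds = _load_aligned(out, dyad, cond)
    base = out / "trf" / f"{dyad}_{cond}"
    weights, header = io.load_array_bundle(base)
    enc = TRFEncoder(
        ds, lags=cfg.lag_config, grid=cfg.lambda_grid,
        folds=cfg.folds, train_fraction=cfg.train_fraction, dyad_id=dyad,
    )
    from .trf import TRFResults

    return TRFResults(
        encoder=enc, weights=weights,
        intercept=np.asarray(header["intercept"], dtype=float),
        lambda_selected=header["lambda_selected"],
    )


def _stage_permute(cfg: RunConfig, out: Path, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    rows = []
    for dyad in _dyad_ids(cfg):
        for cond in cfg.conditions:
            res = _refit(cfg, out, dyad, cond)
            null = shifted_null(
                res, n_permutations=cfg.n_permutations, seed=int(rng.integers(2**31 - 1))
            )
            for ch, name in enumerate(null.ch_names):
                rows.append({
                    "dyad_id": dyad, "condition": cond, "data_type": "shifted",
                    "channel": name,
                    "r": float(null.per_permutation_r[:, ch].mean()),
                    "z": float(null.mean_z[ch]),
                })
    pd.DataFrame(rows).to_csv(out / "accuracy_shifted.csv", index=False)
    return {"accuracy_shifted": _hash_file(out / "accuracy_shifted.csv")}


def _stage_cluster(cfg: RunConfig, out: Path, seed: int) -> dict:
    stacks = []
    header = None
    for dyad in _dyad_ids(cfg):
        per_cond = []
        for cond in cfg.conditions:
            w, header = io.load_array_bundle(out / "trf" / f"{dyad}_{cond}")
            per_cond.append(w)
        stacks.append(np.mean(per_cond, axis=0))
    weights = np.stack(stacks)
    result = cluster_test(
        weights,
        ch_names=header["ch_names"],
        lags_ms=np.asarray(header["lags_ms"]),
        n_randomizations=cfg.n_randomizations,
        alpha=cfg.cluster_alpha,
        seed=seed,
    )
    io.save_json(out / "clusters.json", {
        "n_randomizations": result.n_randomizations,
        "alpha": result.alpha,
        "clusters": [
            {
                "channels": c.channels, "lag_ms_min": c.lag_ms_min,
                "lag_ms_max": c.lag_ms_max, "mass": c.mass,
                "p_value": c.p_value, "sign": c.sign,
            }
            for c in result.clusters
        ],
    })
    return {"clusters": _hash_file(out / "clusters.json")}


def _stage_stats(cfg: RunConfig, out: Path, seed: int) -> dict:
    acc_true = pd.read_csv(out / "accuracy_true.csv")
    acc_shift = pd.read_csv(out / "accuracy_shifted.csv")
    acc = pd.concat([acc_true.assign(data_type="true"), acc_shift], ignore_index=True)
    acc = acc.rename(columns={"z": "z_accuracy"})
    behavior = pd.read_csv(out / "behavior.csv")
    reports = {}
    reports["accuracy"] = fit_accuracy_model(acc, channel_mode="mean").as_dict()
    try:
        reports["movement"] = fit_movement_model(behavior).as_dict()
    except ValueError as err:
        reports["movement"] = {"error": str(err)}
    merged = acc.merge(
        behavior[["dyad_id", "condition", "movement_prop", "vocabulary"]],
        on=["dyad_id", "condition"], how="inner",
    )
    try:
        track_rep, move_rep = fit_vocabulary_models(merged)
        reports["vocabulary_tracking"] = track_rep.as_dict()
        reports["vocabulary_movement"] = move_rep.as_dict()
    except ValueError as err:
        reports["vocabulary"] = {"error": str(err)}
    io.save_json(out / "model_reports.json", reports)
    summary_lines = [f"== {k} ==\n{v}" for k, v in reports.items()]
    (out / "model_reports.txt").write_text("\n\n".join(str(s) for s in summary_lines))
    return {"model_reports": _hash_file(out / "model_reports.json")}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "preprocess": _stage_preprocess,
    "trf": _stage_trf,
    "permute": _stage_permute,
    "cluster": _stage_cluster,
    "stats": _stage_stats,
}


def run_stage(stage: str, cfg: RunConfig) -> RunManifest:
    """Execute one stage (or 'run-all') and update the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.load_or_new(out, cfg)
    manifest.config = asdict(cfg)
    stages = STAGES if stage == "run-all" else (stage,)
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ConfigError(f"unknown stage {name!r}; choose from {STAGES + ('run-all',)}")
        t0 = time.perf_counter()
        stage_seed = cfg.stage_seed(name)
        outputs = _STAGE_FUNCS[name](cfg, out, stage_seed)
        manifest.record(name, time.perf_counter() - t0, outputs, stage_seed)
        manifest.save(out)
    return manifest
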