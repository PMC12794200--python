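"""End-to-end pipeline wiring: simulate -> label -> clean -> decode -> report.

A single :class:`PipelineConfig` (loadable from YAML) drives every stage;
one global seed feeds all randomness.  Stage outputs are cached in the
run directory and re-used when the configuration hash matches, so a run
is resumable at stage boundaries.  The :class:`RunManifest` records the
configuration snapshot, seeds, artifact paths and checksums needed to
reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import WindowDataset, build_dataset
from .decoders import DecoderSpec
from .io import _config_dict, write_json, write_subject
from .kinematics import AngleEpoch, fit_circle_center, repair_outliers, \
    resample_uniform, synchronize_and_epoch, to_polar, PolarTrace
from .channels import CHANNELS
from .preprocessing import CleanEpoch, PreprocessConfig
from .signatures import compute_ersp, compute_mrcp
from .synthetic import (EncodingConfig, ProtocolConfig, TrialRecording,
                        concatenate_session, simulate_subject)
from .training import (TrainConfig, chance_level, compare_to_chance,
                       cross_validate)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "kinematics", "preprocess", "build", "train", "signatures")


@dataclass
class PipelineConfig:
    """Full run configuration; defaults mirror the study protocol."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    models: tuple = ("eegnet_lstm",)
    n_test: int = 20
    n_folds: int = 10
    with_chance: bool = True
    with_signatures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed cascades into every stage-level seed
        self.encoding.seed = self.seed
        self.preprocess.ica_seed = self.seed + 1
        self.train.seed = self.seed + 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs: dict = {}
        for name, sub_cls in (("protocol", ProtocolConfig), ("encoding", EncodingConfig),
                              ("preprocess", PreprocessConfig), ("train", TrainConfig)):
            if name in raw:
                sub = dict(raw[name])
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                bad = set(sub) - sub_known
                if bad:
                    raise KeyError(f"unknown key(s) in '{name}': {sorted(bad)}")
                for key, val in sub.items():
                    if isinstance(val, list):
                        sub[key] = tuple(val)
                kwargs[name] = sub_cls(**sub)
        for name in ("models", "n_test", "n_folds", "with_chance",
                     "with_signatures", "seed"):
            if name in raw:
                kwargs[name] = tuple(raw[name]) if name == "models" else raw[name]
        return cls(**kwargs)

    def snapshot(self) -> dict:
        return {
            "protocol": _config_dict(self.protocol),
            "encoding": _config_dict(self.encoding),
            "preprocess": _config_dict(self.preprocess),
            "train": _config_dict(self.train),
            "models": list(self.models),
            "n_test": self.n_test,
            "n_folds": self.n_folds,
            "with_chance": self.with_chance,
            "with_signatures": self.with_signatures,
            "seed": self.seed,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    config_digest: str
    seed: int
    stages_completed: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def record(self, stage: str, path: Path | None) -> None:
        self.stages_completed.append(stage)
        if path is not None and Path(path).exists():
            data = Path(path).read_bytes()
            self.artifacts[stage] = str(path)
            self.checksums[stage] = hashlib.sha256(data).hexdigest()[:16]
        log_path = getattr(self, "_log_path", None)
        if log_path is not None:
            import time

            event = {"event": "stage_complete", "stage": stage,
                     "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                     "artifact": self.artifacts.get(stage)}
            with open(log_path, "a") as fh:
                fh.write(json.dumps(event) + "\n")


def parse_model_name(name: str) -> DecoderSpec:
    """'eegnet' / 'deep_lstm' / ... -> a DecoderSpec."""
    use_lstm = name.endswith("_lstm")
    family = name[:-5] if use_lstm else name
    return DecoderSpec(family=family, use_lstm=use_lstm)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def kinematics_stage(trials: list[TrialRecording], protocol: ProtocolConfig,
                     jump_threshold: float = 3.0) -> list[AngleEpoch]:
    """Per-trial angle labels with a per-session circle-centre fit."""
    by_session: dict[int, list[TrialRecording]] = {}
    for tr in trials:
        by_session.setdefault(tr.session_id, []).append(tr)
    triggers_s = {"move_on_s": protocol.move_onset_s,
                  "move_off_s": protocol.move_offset_s}
    angles = []
    for _, sess_trials in sorted(by_session.items()):
        repaired = []
        for tr in sess_trials:
            uniform = resample_uniform(tr.kinematics, 1000.0)
            fixed, _ = repair_outliers(uniform, jump_threshold=jump_threshold)
            repaired.append(fixed)
        cx, cy, _ = fit_circle_center(
            np.concatenate([t.x for t in repaired]),
            np.concatenate([t.y for t in repaired]),
        )
        for tr, fixed in zip(sess_trials, repaired):
            theta = to_polar(fixed.x - cx, fixed.y - cy)
            ptrace = PolarTrace(timestamps=fixed.timestamps, theta=theta)
            angles.append(synchronize_and_epoch(ptrace, triggers_s,
                                                trial_id=tr.trial_id))
    angles.sort(key=lambda a: a.trial_id)
    return angles


def preprocess_stage(
    trials: list[TrialRecording],
    protocol: ProtocolConfig,
    config: PreprocessConfig,
) -> tuple[list[CleanEpoch], list[CleanEpoch], list[dict]]:
    """Clean each session; epoch for decoding and (wider) for signatures."""
    by_session: dict[int, list[TrialRecording]] = {}
    for tr in trials:
        by_session.setdefault(tr.session_id, []).append(tr)
    decode_epochs: list[CleanEpoch] = []
    signature_epochs: list[CleanEpoch] = []
    logs = []
    sig_config = dataclasses.replace(config, epoch_window=(-1.0, config.epoch_window[1]))
    from .preprocessing import clean_session_continuous, epoch_and_baseline

    for sid, sess_trials in sorted(by_session.items()):
        eeg, triggers = concatenate_session(sess_trials)
        fs = protocol.eeg_rate_hz
        x, bad, removed, scores = clean_session_continuous(eeg, fs, config)
        decode_epochs.extend(epoch_and_baseline(
            x, triggers, fs, config,
            bad_channel_log=bad, removed_component_count=removed))
        # signature epochs reuse the cleaned continuous data: only the
        # (cheap) epoching is rerun with the wider window
        signature_epochs.extend(epoch_and_baseline(
            x, triggers, fs, sig_config,
            bad_channel_log=bad, removed_component_count=removed))
        logs.append({
            "session_id": sid,
            "bad_channels": [CHANNELS[i] for i in bad],
            "removed_components": removed,
            "component_scores": np.round(scores, 4).tolist(),
            "notch_hz": config.notch_hz,
            "bandpass": list(config.bandpass),
            "out_rate_hz": config.out_rate_hz,
        })
    decode_epochs.sort(key=lambda e: e.trial_id)
    signature_epochs.sort(key=lambda e: e.trial_id)
    return decode_epochs, signature_epochs, logs


def signatures_stage(signature_epochs: list[CleanEpoch],
                     config: PipelineConfig,
                     arrays_path: Path | None = None) -> dict:
    """MRCP and ERSP at the motor channels, summarized for the report."""
    arr = np.stack([e.eeg for e in signature_epochs])
    rate = signature_epochs[0].rate_hz
    t0 = -1.0
    times = t0 + np.arange(arr.shape[-1]) / rate
    mrcp = compute_mrcp(arr, times, ("C3", "Cz", "C4"), fs=rate)
    ersp = compute_ersp(arr, times, ("C3", "Cz", "C4"), fs=rate,
                        baseline=(-1.0, 0.0))
    if arrays_path is not None:
        from .io import write_signature_arrays

        write_signature_arrays(arrays_path, mrcp, ersp)
    move = (0.5, config.protocol.move_s - 0.5)
    out = {"mrcp": {}, "ersp_alpha_db": {}, "ersp_beta_db": {}}
    from .signatures import erd_band_power

    for m in mrcp:
        pre = (m.time >= -1.0) & (m.time < 0.0)
        out["mrcp"][m.channel] = {
            "pre_movement_min_uv": float(m.mean[pre].min()),
            "movement_mean_uv": float(m.mean[(m.time >= 0) & (m.time <= 6)].mean()),
        }
    for e in ersp:
        out["ersp_alpha_db"][e.channel] = erd_band_power(e, (8, 12), move)
        out["ersp_beta_db"][e.channel] = erd_band_power(e, (12, 30), move)
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir, until: str = "signatures") -> RunManifest:
    """Execute the pipeline through stage ``until``; cache stage artifacts.

    Returns the manifest; results land in ``outdir`` (``subject.h5``,
    ``results.json``, ``tables.csv``, ``manifest.json``).
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), config_digest=config.digest(),
                           seed=config.seed)
    manifest._log_path = outdir / "log.jsonl"  # stage events as JSON lines
    last = STAGES.index(until)

    subject_path = outdir / "subject.h5"
    cached = _cached_digest(outdir)
    if subject_path.exists() and cached == config.digest():
        logger.info("stage simulate: reusing cached %s", subject_path)
        from .io import read_subject

        trials, _ = read_subject(subject_path)
    else:
        logger.info("stage simulate: %d trials", config.protocol.n_trials)
        trials = simulate_subject(config.protocol, config.encoding)
        write_subject(subject_path, trials, config.protocol, config.encoding)
    manifest.record("simulate", subject_path)
    if last < 1:
        return _finish(manifest, outdir)

    logger.info("stage kinematics")
    angles = kinematics_stage(trials, config.protocol,
                              jump_threshold=3.0)
    from .io import write_angles

    write_angles(outdir / "angles.h5", angles)
    manifest.record("kinematics", outdir / "angles.h5")
    if last < 2:
        return _finish(manifest, outdir)

    logger.info("stage preprocess")
    decode_epochs, signature_epochs, logs = preprocess_stage(
        trials, config.protocol, config.preprocess)
    write_json(outdir / "preprocess_log.json", {"sessions": logs})
    manifest.record("preprocess", outdir / "preprocess_log.json")
    if last < 3:
        return _finish(manifest, outdir)

    logger.info("stage build")
    dataset = build_dataset(decode_epochs, angles, shuffle_seed=config.seed + 3,
                            n_test=config.n_test, n_folds=config.n_folds)
    write_json(outdir / "split_manifest.json", {
        "shuffle_seed": config.seed + 3,
        "assignment": {str(k): int(v) for k, v in dataset.split_assignment.items()},
    })
    manifest.record("build", outdir / "split_manifest.json")
    if last < 4:
        return _finish(manifest, outdir)

    logger.info("stage train: models %s", config.models)
    results: dict = {}
    evals: dict = {}
    for name in config.models:
        spec = parse_model_name(name)
        spec.seed = config.seed + 4
        decoded = cross_validate(spec, dataset, config.train)
        evals[name] = decoded
        entry = {
            "per_fold": [dataclasses.asdict(_strip(f)) for f in decoded.per_fold],
            "aggregate": decoded.aggregate(),
        }
        if config.with_chance:
            chance = chance_level(spec, dataset, config.train,
                                  permutation_seed=config.seed + 5)
            entry["chance_aggregate"] = chance.aggregate()
            entry["vs_chance"] = compare_to_chance(decoded, chance)
        results[name] = entry
    write_json(outdir / "results.json", results)
    _write_tables(outdir / "tables.csv", results)
    _write_training_curves(outdir / "training_curves.csv", evals)
    manifest.record("train", outdir / "results.json")
    if last < 5 or not config.with_signatures:
        return _finish(manifest, outdir)

    logger.info("stage signatures")
    sig = signatures_stage(signature_epochs, config,
                           arrays_path=outdir / "signatures.h5")
    write_json(outdir / "signatures.json", sig)
    manifest.record("signatures", outdir / "signatures.json")
    return _finish(manifest, outdir)


def _strip(fold_result):
    out = dataclasses.replace(fold_result)
    out.predictions = None
    out.history = None
    return out


def _write_training_curves(path: Path, results: dict) -> None:
    import pandas as pd

    rows = []
    for model_name, eval_result in results.items():
        for fold, fr in enumerate(eval_result.per_fold, start=1):
            for epoch, (train_loss, val_loss) in enumerate(fr.history or [], 1):
                rows.append({"model": model_name, "fold": fold, "epoch": epoch,
                             "train_loss": train_loss, "val_loss": val_loss})
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_tables(path: Path, results: dict) -> None:
    import pandas as pd

    rows = []
    for name, entry in results.items():
        row = {"model": name}
        for metric, (mean, sd) in entry["aggregate"].items():
            row[metric] = f"{mean:.3f} +/- {sd:.3f}"
        if "chance_aggregate" in entry:
            for metric, (mean, sd) in entry["chance_aggregate"].items():
                row[f"chance_{metric}"] = f"{mean:.3f} +/- {sd:.3f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _cached_digest(outdir: Path) -> str | None:
    path = outdir / "manifest.json"
    if not path.exists():
        return None
    try:
        return json.loads(path.read_text()).get("config_digest")
    except (json.JSONDecodeError, OSError):
        return None


def _finish(manifest: RunManifest, outdir: Path) -> RunManifest:
    write_json(outdir / "manifest.json", dataclasses.asdict(manifest))
    return manifest
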