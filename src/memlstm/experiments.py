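"""Declarative experiment runner for the three study designs.

Three numerical experiments mirror the study protocol:

* ``single_subject`` — one long recording, chronological 4:1
  train/test split, normalization fitted on the training segment;
* ``pooled`` — several subjects, each split 4:1 and normalized
  per-recording; training windows are pooled, evaluation runs on the
  pooled test windows and per subject;
* ``leave_one_out`` — one fold per subject: train on everyone else's
  full recording, test on the held-out subject;
* ``device_demo`` — no network: characterize one memristor with an I-V
  sweep and export the trace.

Every run is seeded end to end and writes a manifest (config, seed,
versions) from which it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .device import MemristorParams, iv_sweep
from .errors import ConfigError
from .evalmetrics import detect_events, event_precision_recall, rmse
from .io import read_recording
from .lstm import (
    LSTMNetwork,
    PersistenceForecaster,
    TrainConfig,
    XbarConfig,
    to_memristive,
    train,
)
from .signalprep import (
    Recording,
    gaussian_filter,
    make_windows,
    multistep_predict_batch,
    split_4to1,
    zscore_fit_apply,
)
from .synthlfp import SynthConfig, generate, generate_cohort

logger = logging.getLogger("memlstm")

EXPERIMENTS = ("single_subject", "pooled", "leave_one_out", "device_demo")


@dataclass(frozen=True)
class PreprocessingConfig:
    sigma_samples: float = 2.0     # Gaussian filter width, samples
    window: int = 20               # input window length L


@dataclass(frozen=True)
class EvaluationConfig:
    max_steps: int = 5             # horizon of the RMSE-vs-step curve
    k_sd: float = 5.0              # high-amplitude event criterion
    tol_samples: int = 5           # event matching tolerance (40 ms at 8 ms)
    event_horizon: int = 5         # forecast horizon for event scoring
    merge_gap_samples: int = 10    # sub-threshold gap still one event


@dataclass(frozen=True)
class MemristiveConfig:
    mode: str = "off"              # off | ideal | custom
    levels: int | None = 256
    noise_sigma: float = 0.0
    g_min: float = 1e-5
    g_max: float = 1e-4


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    seed: int = 0
    output_dir: str = "runs/latest"
    data_paths: tuple[str, ...] = ()           # empty => synthetic
    synthetic: SynthConfig | None = None
    n_subjects: int = 6
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    model: TrainConfig = TrainConfig()
    memristive: MemristiveConfig = MemristiveConfig()
    evaluation: EvaluationConfig = EvaluationConfig()
    device: MemristorParams = MemristorParams()

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.experiment in ("pooled", "leave_one_out"):
            n = len(self.data_paths) if self.data_paths else self.n_subjects
            if n < 2:
                raise ConfigError(f"{self.experiment} needs >= 2 recordings")
        if self.memristive.mode not in ("off", "ideal", "custom"):
            raise ConfigError("memristive.mode must be off|ideal|custom")


def config_from_dict(d: dict) -> ExperimentConfig:
    """Build a validated config from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    if "experiment" not in d:
        raise ConfigError("config is missing the required 'experiment' key")
    sub = {
        "preprocessing": PreprocessingConfig,
        "model": TrainConfig,
        "evaluation": EvaluationConfig,
        "memristive": MemristiveConfig,
        "synthetic": SynthConfig,
        "device": MemristorParams,
    }
    kwargs = {}
    for key, val in d.items():
        if key in sub:
            if not isinstance(val, dict):
                raise ConfigError(f"config block {key!r} must be a mapping")
            try:
                kwargs[key] = sub[key](**val)
            except TypeError as exc:
                raise ConfigError(f"invalid {key} block: {exc}") from exc
        elif key == "data_paths":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    try:
        return ExperimentConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_from_yaml(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# pipeline pieces shared by the experiment designs


def _load_recordings(cfg: ExperimentConfig) -> list[Recording]:
    if cfg.data_paths:
        return [read_recording(p) for p in cfg.data_paths]
    base = cfg.synthetic or SynthConfig()
    if cfg.experiment == "single_subject":
        sig = generate(dataclasses.replace(base, seed=cfg.seed))
        return [sig.recording]
    cohort = generate_cohort(cfg.n_subjects, base, seed=cfg.seed)
    return [s.recording for s in cohort]


def prepare_split(rec: Recording, prep: PreprocessingConfig):
    """Filter, 4:1 split and train-fitted normalization for one recording.

    Returns ``(train Recording, test Recording, (mean, sd))`` with both
    segments already normalized.
    """
    smooth = gaussian_filter(rec, prep.sigma_samples)
    train_rec, test_rec = split_4to1(smooth)
    (tr, te), stats = zscore_fit_apply(train_rec.samples, test_rec.samples)
    return (
        Recording(tr, dt_ms=rec.dt_ms, subject_id=rec.subject_id),
        Recording(te, dt_ms=rec.dt_ms, subject_id=rec.subject_id),
        stats,
    )


def evaluate_model(model, test_rec: Recording, ev: EvaluationConfig,
                   L: int = 20) -> dict:
    """Forecast metrics on one normalized test recording.

    Computes single-step RMSE (model and persistence baseline), the
    RMSE-vs-step curve, and event precision/recall at the configured
    forecast horizon, where events on both the true and the forecast
    series are extracted with the same k-SD criterion.
    """
    ds = make_windows(test_rec, L)
    x = test_rec.samples
    horizon = max(ev.max_steps, ev.event_horizon)
    # one batched rollout serves the step curve and the event series
    preds = multistep_predict_batch(model, ds.inputs, horizon)
    out = {
        "rmse_single_step": rmse(ds.targets, preds[:, 0]),
        "rmse_persistence": rmse(ds.targets, ds.inputs[:, -1]),
    }
    out["rmse_vs_step"] = {}
    for s in range(1, ev.max_steps + 1):
        n_admissible = len(x) - L - s + 1
        out["rmse_vs_step"][s] = rmse(x[L + s - 1:], preds[:n_admissible, s - 1])
    s = ev.event_horizon
    n_admissible = len(x) - L - s + 1
    fc, truth = preds[:n_admissible, s - 1], x[L + s - 1:]
    true_ev = detect_events(truth, ev.k_sd, ev.merge_gap_samples)
    pred_ev = detect_events(fc, ev.k_sd, ev.merge_gap_samples)
    precision, recall, matches = event_precision_recall(
        true_ev, pred_ev, ev.tol_samples
    )
    out["events"] = {
        "horizon": ev.event_horizon,
        "n_true": len(true_ev),
        "n_predicted": len(pred_ev),
        "matches": matches,
        "precision": precision,
        "recall": recall,
    }
    return out


def _train_on(datasets, model_cfg: TrainConfig, seed: int) -> tuple[LSTMNetwork, dict]:
    """Train one network on the concatenation of windowed datasets."""
    X = np.concatenate([d.inputs for d in datasets])
    y = np.concatenate([d.targets for d in datasets])
    from .signalprep import WindowedDataset

    return train(WindowedDataset(inputs=X, targets=y, L=datasets[0].L),
                 hyper=model_cfg, seed=seed)


def _memristive_variant(network: LSTMNetwork, mem: MemristiveConfig, seed: int):
    if mem.mode == "off":
        return None
    if mem.mode == "ideal":
        cfg = XbarConfig(g_min=mem.g_min, g_max=mem.g_max,
                         levels=None, noise_sigma=0.0)
    else:
        cfg = XbarConfig(g_min=mem.g_min, g_max=mem.g_max, levels=mem.levels,
                         noise_sigma=mem.noise_sigma, seed=seed)
    return to_memristive(network, cfg)


# ---------------------------------------------------------------------------
# experiment designs


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute one configured experiment and write its report bundle.

    Writes ``metrics.json``, ``step_curve.csv``, a model checkpoint and
    ``manifest.json`` into ``cfg.output_dir`` and returns the metrics.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("experiment=%s seed=%d out=%s", cfg.experiment, cfg.seed, out_dir)

    if cfg.experiment == "device_demo":
        metrics = _run_device_demo(cfg, out_dir)
    elif cfg.experiment == "single_subject":
        metrics = _run_single_subject(cfg, out_dir)
    elif cfg.experiment == "pooled":
        metrics = _run_pooled(cfg, out_dir)
    else:
        metrics = _run_leave_one_out(cfg, out_dir)

    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    _write_manifest(cfg, out_dir)
    return metrics


def _write_manifest(cfg: ExperimentConfig, out_dir: Path) -> None:
    cfg_dict = asdict(cfg)
    blob = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "versions": {"memlstm": __version__, "numpy": np.__version__},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )


def _write_step_curve(metrics: dict, out_dir: Path) -> None:
    curve = metrics.get("rmse_vs_step")
    if curve:
        pd.DataFrame(
            {"step": list(curve), "rmse": list(curve.values())}
        ).to_csv(out_dir / "step_curve.csv", index=False)


def _run_device_demo(cfg: ExperimentConfig, out_dir: Path) -> dict:
    trace = iv_sweep(amplitude=1.5, period=1.0, cycles=2, params=cfg.device)
    trace.to_csv(out_dir / "iv_trace.csv")
    return {
        "experiment": "device_demo",
        "loop_area": trace.loop_area(),
        "w_final": float(trace.states[-1]),
        "n_samples": int(len(trace.times)),
    }


def _run_single_subject(cfg: ExperimentConfig, out_dir: Path) -> dict:
    rec = _load_recordings(cfg)[0]
    train_rec, test_rec, stats = prepare_split(rec, cfg.preprocessing)
    L = cfg.preprocessing.window
    network, history = _train_on([make_windows(train_rec, L)], cfg.model, cfg.seed)
    network.save(out_dir / "model.h5", seed=cfg.seed)

    metrics = {"experiment": "single_subject",
               "subject": rec.subject_id,
               "normalization": {"mean": stats[0], "sd": stats[1]},
               "epochs_run": len(history["train_loss"]),
               "final_train_loss": history["train_loss"][-1]}
    metrics.update(evaluate_model(network, test_rec, cfg.evaluation, L))
    mem = _memristive_variant(network, cfg.memristive, cfg.seed)
    if mem is not None:
        metrics["memristive"] = evaluate_model(mem, test_rec, cfg.evaluation, L)
    _write_step_curve(metrics, out_dir)
    return metrics


def _run_pooled(cfg: ExperimentConfig, out_dir: Path) -> dict:
    recs = _load_recordings(cfg)
    L = cfg.preprocessing.window
    splits = [prepare_split(r, cfg.preprocessing) for r in recs]
    network, history = _train_on(
        [make_windows(tr, L) for tr, _, _ in splits], cfg.model, cfg.seed
    )
    network.save(out_dir / "model.h5", seed=cfg.seed)
    per_subject = {
        te.subject_id: evaluate_model(network, te, cfg.evaluation, L)
        for _, te, _ in splits
    }
    pooled_rmse = float(np.sqrt(np.mean([
        m["rmse_single_step"] ** 2 for m in per_subject.values()
    ])))
    metrics = {"experiment": "pooled",
               "n_subjects": len(recs),
               "epochs_run": len(history["train_loss"]),
               "rmse_single_step": pooled_rmse,
               "per_subject": per_subject}
    first = next(iter(per_subject.values()))
    metrics["rmse_vs_step"] = first["rmse_vs_step"]
    _write_step_curve(metrics, out_dir)
    return metrics


def _run_leave_one_out(cfg: ExperimentConfig, out_dir: Path) -> dict:
    recs = _load_recordings(cfg)
    L = cfg.preprocessing.window
    folds = {}
    for held_out in range(len(recs)):
        train_sets = []
        for i, rec in enumerate(recs):
            if i == held_out:
                continue
            smooth = gaussian_filter(rec, cfg.preprocessing.sigma_samples)
            (norm,), _ = zscore_fit_apply(smooth.samples)
            train_sets.append(
                make_windows(Recording(norm, rec.dt_ms, rec.subject_id), L)
            )
        network, _ = _train_on(train_sets, cfg.model, cfg.seed + held_out)
        test_smooth = gaussian_filter(recs[held_out], cfg.preprocessing.sigma_samples)
        (test_norm,), _ = zscore_fit_apply(test_smooth.samples)
        test_rec = Recording(test_norm, recs[held_out].dt_ms,
                             recs[held_out].subject_id)
        folds[test_rec.subject_id] = evaluate_model(
            network, test_rec, cfg.evaluation, L
        )
        folds[test_rec.subject_id]["trained_on"] = [
            r.subject_id for i, r in enumerate(recs) if i != held_out
        ]
    mean_rmse = float(np.mean([m["rmse_single_step"] for m in folds.values()]))
    metrics = {"experiment": "leave_one_out",
               "n_subjects": len(recs),
               "rmse_single_step_mean": mean_rmse,
               "folds": folds}
    return metrics
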