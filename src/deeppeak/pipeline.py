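"""End-to-end orchestration: simulate -> detect -> featurize -> train ->
predict -> evaluate, driven by a single YAML config with one global seed.

The pipeline writes per-stage artifacts (peak tables, labeled examples,
a trained cascade, predictions) plus ``report.json`` and a
``manifest.json`` recording seeds, per-stage counts and file checksums.
Identical config + seed reproduces identical reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .classify import TrainConfig, predict_cascade, save_cascade, train_cascade
from .featurize import examples_from_segment, feature_matrix, make_splits
from .roi_detect import DetectionParams, detect_gfp_rois, detect_segment
from .simulate import SimConfig, SizeCategory, simulate_day

log = logging.getLogger("deeppeak")


class ConfigError(ValueError):
    """A pipeline config fails schema validation."""


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_days: int = 4
    segments_per_day: int = 1
    ctcc_rates_by_day: list[float] | None = None  # cycled across days if given
    n_stages: int = 2
    test_fraction: float = 11 / 34
    val_fraction: float = 0.21
    n_folds: int = 1
    seed: int = 0
    log_level: str = "INFO"


_SECTION_TYPES = {"sim": SimConfig, "detection": DetectionParams, "train": TrainConfig}


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    if cls is SimConfig and "ctcc_size_distribution" in data:
        data = dict(data)
        data["ctcc_size_distribution"] = tuple(
            SizeCategory(**c) for c in data["ctcc_size_distribution"]
        )
    for name in ("channel_baseline_variance", "band", "single_cell_length",
                 "single_cell_amplitude", "ctcc_amplitude", "confounder_amplitude",
                 "confounder_length_range"):
        if name in data and isinstance(data[name], list):
            data = dict(data)
            data[name] = tuple(data[name])
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {section!r}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    top_names = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    validate_config(cfg)
    return cfg


def validate_config(cfg: PipelineConfig) -> None:
    """Cross-field checks that single sections cannot see."""
    nyquist = cfg.sim.sample_rate / 2.0
    if cfg.detection.band[1] >= nyquist:
        raise ConfigError(
            f"detection.band high ({cfg.detection.band[1]} Hz) must be below the "
            f"Nyquist frequency of sim.sample_rate ({nyquist} Hz)"
        )
    if cfg.n_days < 3:
        raise ConfigError("n_days must be >= 3 (day-wise splits need 3 days)")
    if not 1 <= cfg.n_stages <= 10:
        raise ConfigError("n_stages must be in [1, 10]")


def _child_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns the evaluation report dict.

    Artifacts are written under ``out_dir``; traces themselves are not
    persisted (they can be regenerated from the config and seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    all_examples = []
    counts_by_day: dict[int, dict[str, int]] = {}
    for day in range(cfg.n_days):
        sim = cfg.sim
        if cfg.ctcc_rates_by_day:
            rate = cfg.ctcc_rates_by_day[day % len(cfg.ctcc_rates_by_day)]
            sim = dataclasses.replace(sim, ctcc_rate=rate)
        segments, truth = simulate_day(
            sim, cfg.segments_per_day, seed=_child_seed(cfg.seed, day), day_id=day
        )
        n_pos = 0
        n_events = 0
        for seg in segments:
            rois, clot = detect_segment(seg, cfg.detection)
            gfp = detect_gfp_rois(seg, cfg.detection)
            df = examples_from_segment(seg, rois, gfp, min_fwhm=cfg.detection.min_fwhm)
            all_examples.append(df)
            n_pos += int((df["label"] == 1).sum())
            n_events += len(df)
            log.info(
                "day %d segment %d: %d ROIs (%d labeled clusters), clot=%s",
                day, seg.segment_id, len(df), int((df["label"] == 1).sum()),
                clot.detected,
            )
        counts_by_day[day] = {"events": n_events, "labeled_positive": n_pos}

    non_empty = [df for df in all_examples if len(df)]
    if not non_empty:
        raise RuntimeError("no ROIs detected on any day; nothing to train on")
    examples = pd.concat(non_empty, ignore_index=True)
    examples.to_csv(out / "examples.csv", index=False, float_format="%.6g")

    splits = make_splits(
        sorted(examples["day_id"].unique()),
        test_fraction=cfg.test_fraction, n_folds=cfg.n_folds,
        val_fraction=cfg.val_fraction, seed=cfg.seed,
    )
    split = splits[0]
    train_mask = examples["day_id"].isin(split.train_days)
    val_mask = examples["day_id"].isin(split.val_days)
    test_mask = examples["day_id"].isin(split.test_days)
    X_train, y_train = feature_matrix(examples[train_mask])
    X_val, y_val = feature_matrix(examples[val_mask])

    cascade = train_cascade(
        (X_train, y_train), (X_val, y_val), cfg.train, n_models=cfg.n_stages
    )
    save_cascade(cascade, out / "cascade")

    X_all, y_all = feature_matrix(examples)
    pred_all, dropped_at = predict_cascade(cascade, X_all)
    pred_df = examples[["day_id", "segment_id", "peak_index", "label"]].copy()
    pred_df["predicted"] = pred_all
    pred_df["dropped_at_stage"] = dropped_at
    pred_df.to_csv(out / "predictions.csv", index=False)

    c_test = ev.confusion(y_all[test_mask.to_numpy()], pred_all[test_mask.to_numpy()])
    metrics = ev.core_metrics(c_test)
    per_day = pred_df.groupby("day_id").agg(
        detected=("predicted", "sum"), true=("label", "sum")
    )
    pcc = None
    if len(per_day) >= 3 and per_day["detected"].std() > 0 and per_day["true"].std() > 0:
        pcc = ev.pearson_correlation(per_day["detected"], per_day["true"])

    report = {
        "split": {
            "train_days": [int(d) for d in split.train_days],
            "val_days": [int(d) for d in split.val_days],
            "test_days": [int(d) for d in split.test_days],
        },
        "counts_by_day": {str(k): v for k, v in counts_by_day.items()},
        "cascade": {
            "n_stages": len(cascade.stages_),
            "stage_train_sizes": [int(v) for v in cascade.stage_train_sizes_],
            "stage_positive_fraction": [float(v) for v in cascade.stage_positive_fraction_],
        },
        "test_confusion": dataclasses.asdict(c_test),
        "test_metrics": dataclasses.asdict(metrics),
        "detected_vs_true_pcc": None if pcc is None else float(pcc),
        "per_day": {
            str(d): {"detected": int(r.detected), "true": int(r.true)}
            for d, r in per_day.iterrows()
        },
        "seed": cfg.seed,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    manifest = {
        "seed": cfg.seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.csv")) + [out / "report.json"]
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
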