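"""End-to-end orchestration: generate -> preprocess -> topomap -> correlate
-> train -> evaluate, with a config object and a checksummed run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .correlation import average_correlation, correlation_matrix, evaluate_hypotheses
from .montage import CATEGORIES
from .plotting import matrix_to_csv, plot_heatmap
from .preprocessing import preprocess
from .recording import Dataset
from .soft_sensor import (ClassifierSpec, SoftSensor, accuracy, plan_split,
                          stack_images)
from .synthetic import generate_study, profile_set
from .topomap import render_recording

ALL_STAGES = ("generate", "preprocess", "topomap", "correlate", "train", "evaluate")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All stage parameters of one reproducible run."""

    out_dir: str = "runs/run0"
    seed: int = 0
    n_pairs: int = 14
    duration_s: float = 60.0
    rate_hz: float = 128.0
    profile_set: str = "default"  # default | separable | identity
    recording_format: str = "delimited"
    hp_cutoff: float = 0.2
    lp_cutoff: float = 50.0
    bound: float = 10.0
    window_s: float = 0.5
    image_size: int = 360
    summary_method: str = "mean"
    average_method: str = "fisher_z"
    span: str = "full"
    n_train: int = 10
    n_val: int = 2
    n_test: int = 2
    classifier: dict = field(default_factory=lambda: dataclasses.asdict(ClassifierSpec()))
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        self.classifier = dict(self.classifier)
        self.classifier["conv_filters"] = list(self.classifier["conv_filters"])
        self.stages = tuple(self.stages)

    def classifier_spec(self) -> ClassifierSpec:
        spec = dict(self.classifier)
        spec["input_size"] = self.image_size
        spec["conv_filters"] = tuple(spec["conv_filters"])
        return ClassifierSpec(**spec)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["classifier"]["conv_filters"] = list(d["classifier"]["conv_filters"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        if "classifier" in d:
            d["classifier"]["conv_filters"] = tuple(d["classifier"]["conv_filters"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Checksummed record of one pipeline run."""

    config: dict
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def add_outputs(self, stage: str, root: Path, files) -> None:
        self.outputs[stage] = {
            str(Path(f).relative_to(root)): _sha256(Path(f)) for f in files
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> RunManifest:
    """Execute the configured stages in order, writing one directory per
    stage under ``config.out_dir``; identical config and seed give identical
    checksums for the deterministic stages."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["stages"] = list(cfg_dict["stages"])
    manifest = RunManifest(cfg_dict, started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    config.to_yaml(root / "config.yaml")

    dataset = processed = images = results = None
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise StageError(f"stage {stage!r}: unknown stage name")
        try:
            if stage == "generate":
                dataset = generate_study(
                    config.n_pairs, profile_set(config.profile_set), config.seed,
                    duration_s=config.duration_s, rate_hz=config.rate_hz)
                out = root / "generate"
                eio.write_dataset(dataset, out, config.recording_format, config.seed)
                manifest.add_outputs(stage, root, sorted(out.iterdir()))
            elif stage == "preprocess":
                dataset = dataset or _load(root / "generate", stage)
                processed = dataset.map(lambda r: preprocess(
                    r, config.hp_cutoff, config.lp_cutoff, config.bound))
                out = root / "preprocess"
                eio.write_dataset(processed, out, config.recording_format, config.seed)
                manifest.add_outputs(stage, root, sorted(out.iterdir()))
            elif stage == "topomap":
                processed = processed or _load(root / "preprocess", stage)
                out = root / "topomap"
                out.mkdir(exist_ok=True)
                all_maps, label_rows = [], []
                for rec in processed:
                    for img in render_recording(rec, config.window_s,
                                                config.image_size,
                                                config.summary_method):
                        img.save(out / img.filename)
                        all_maps.append(img)
                        label_rows.append({"filename": img.filename,
                                           "category": img.category,
                                           "pair": img.pair_id})
                (out / "labels.json").write_text(json.dumps(label_rows, indent=2))
                images = stack_images(all_maps)
                manifest.add_outputs(stage, root, sorted(out.iterdir()))
            elif stage == "correlate":
                processed = processed or _load(root / "preprocess", stage)
                out = root / "correlate"
                out.mkdir(exist_ok=True)
                cat_mats = {}
                for cat in CATEGORIES:
                    mats = [correlation_matrix(r, config.span)
                            for r in processed.by_category(cat)]
                    avg = average_correlation(mats, config.average_method)
                    cat_mats[cat] = avg
                    matrix_to_csv(avg, out / f"{cat}.csv")
                    plot_heatmap(avg, out / f"{cat}.png")
                report = evaluate_hypotheses(cat_mats)
                report.to_json(out / "hypotheses.json")
                manifest.metrics["hypotheses"] = {
                    r.hypothesis_id + "/" + r.category: r.verdict
                    for r in report.results
                }
                manifest.add_outputs(stage, root, sorted(out.iterdir()))
            elif stage == "train":
                if images is None:
                    raise FileNotFoundError("topomap stage output not in memory")
                plan = plan_split(sorted(set(images.pair_ids.tolist())),
                                  config.n_train, config.n_val, config.n_test,
                                  config.seed)
                results = SoftSensor(config.classifier_spec()).fit(
                    images, plan, seed=config.seed, verbose=verbose)
                out = root / "train"
                out.mkdir(exist_ok=True)
                hist = results.history
                with open(out / "history.csv", "w") as fh:
                    fh.write("epoch,train_loss,train_accuracy,val_loss,val_accuracy\n")
                    for i in range(len(hist)):
                        fh.write(f"{i + 1},{hist.train_loss[i]},{hist.train_accuracy[i]},"
                                 f"{hist.val_loss[i]},{hist.val_accuracy[i]}\n")
                (out / "split.json").write_text(json.dumps(
                    {str(k): v for k, v in plan.assignment.items()}, indent=2))
                manifest.add_outputs(stage, root, sorted(out.iterdir()))
            elif stage == "evaluate":
                if results is None:
                    raise FileNotFoundError("train stage output not in memory")
                cm = results.evaluate(images.for_split(results.plan, "test"))
                out = root / "evaluate"
                out.mkdir(exist_ok=True)
                np.savetxt(out / "confusion.csv", cm.counts, fmt="%d", delimiter=",",
                           header=",".join(cm.categories), comments="")
                metrics = {"test_accuracy": accuracy(cm),
                           "n_test_images": cm.total}
                (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
                manifest.metrics.update(metrics)
                manifest.add_outputs(stage, root, sorted(out.iterdir()))
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(root / "run_manifest.json")
    return manifest


def _load(path: Path, stage: str) -> Dataset:
    if not path.exists():
        raise FileNotFoundError(f"missing input directory {path}")
    return eio.read_dataset(path)
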