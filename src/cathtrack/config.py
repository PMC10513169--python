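"""Shared pipeline configuration, seed fan-out and provenance records.

A single YAML file (one section per stage) fully determines every stage of
the workflow.  The global seed fans out to per-stage seeds through fixed
offsets so that stages can be re-run independently yet reproducibly, and
every artifact directory receives a provenance record (config hash, seed,
library versions) sufficient to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .segmentation import TrainingConfig
from .synthetic import DatasetConfig

__all__ = ["PipelineConfig", "stage_seed", "write_provenance"]

#: fixed per-stage offsets for fanning the global seed out
_STAGE_OFFSETS = {"generate": 0, "dynamics": 101, "train": 211, "track": 307, "evaluate": 401}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    if stage not in _STAGE_OFFSETS:
        raise ValueError(f"unknown stage {stage!r}")
    return (int(global_seed) + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class TrackingOptions:
    scoring: str = "mean"  # "mean" or "peak" region intensity


@dataclass
class EvaluationOptions:
    missed_gt_label: str = "FP"  # convention for wrong-region-on-catheter
    n_dynamics: int = 60
    dynamics_negative_fraction: float = 0.25


@dataclass
class PipelineConfig:
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    tracking: TrackingOptions = field(default_factory=TrackingOptions)
    evaluation: EvaluationOptions = field(default_factory=EvaluationOptions)
    global_seed: int = 0
    workdir: str = "cathtrack_run"

    def __post_init__(self) -> None:
        # fan the global seed out to the stages
        self.dataset.rng_seed = stage_seed(self.global_seed, "generate")
        self.training.rng_seed = stage_seed(self.global_seed, "train")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return listify(asdict(self))

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {"dataset", "training", "tracking", "evaluation", "global_seed", "workdir"}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")

        def build(klass, section):
            section = dict(section or {})
            valid = {f.name for f in klass.__dataclass_fields__.values()}  # type: ignore[attr-defined]
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown keys in {klass.__name__}: {sorted(bad)}")
            return klass(**section)

        cfg = cls(
            dataset=build(DatasetConfig, d.get("dataset")),
            training=build(TrainingConfig, d.get("training")),
            tracking=build(TrackingOptions, d.get("tracking")),
            evaluation=build(EvaluationOptions, d.get("evaluation")),
            global_seed=int(d.get("global_seed", 0)),
            workdir=str(d.get("workdir", "cathtrack_run")),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def write_provenance(artifact_dir: str | Path, config: PipelineConfig,
                     stage: str) -> Path:
    """Drop a provenance JSON next to a stage's artifacts."""
    import cathtrack

    artifact_dir = Path(artifact_dir)
    artifact_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "global_seed": config.global_seed,
        "stage_seed": stage_seed(config.global_seed, stage) if stage in _STAGE_OFFSETS else None,
        "cathtrack_version": cathtrack.__version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
    }
    path = artifact_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=2))
    return path
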