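"""Run configuration and pipeline orchestration.

A single declarative YAML config drives reproducible runs: one master seed
deterministically derives every stage seed (cohort generation, splits, model
initialization, augmentation, dropout), and every artifact directory is
stamped with the config hash and seed so a run directory alone identifies
the computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .experiment import ExperimentConfig, run_experiment
from .preprocessing import PreprocessParams
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger("milcta")


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs/run"
    artery: str = "LAD"
    input_dir: str | None = None  # directory of slice images; None → synthetic mode
    labels_csv: str | None = None
    synthetic: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=lambda: {"output_size": (48, 48)})
    model: dict = field(default_factory=dict)
    n_repeats: int = 5
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    shuffle_labels: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def synthetic_config(self) -> SyntheticConfig:
        params = dict(self.synthetic)
        params.setdefault("rng_seed", self.seed)
        params.setdefault("artery", self.artery)
        if "slices_per_patient_range" in params:
            params["slices_per_patient_range"] = tuple(params["slices_per_patient_range"])
        return SyntheticConfig(**params)

    def experiment_config(self) -> ExperimentConfig:
        pp = dict(self.preprocess)
        if "output_size" in pp:
            pp["output_size"] = tuple(pp["output_size"])
        if "windows" in pp:
            pp["windows"] = tuple(tuple(w) for w in pp["windows"])
        base = ExperimentConfig(
            n_repeats=self.n_repeats,
            base_seed=self.seed,
            fractions=tuple(self.fractions),
            preprocess=PreprocessParams(**pp),
            shuffle_labels=self.shuffle_labels,
        )
        base.model_params.update(self.model)
        return base


def run_pipeline(config: RunConfig):
    """Execute the full pipeline and write artifacts; returns the summary.

    Synthetic mode (no ``input_dir``) generates the cohort in memory.  File
    mode requires the labels CSV to exist; a missing input is a clean error
    before any artifact is written.
    """
    out_dir = Path(config.out_dir)
    if config.input_dir is not None:
        if config.labels_csv is None or not Path(config.labels_csv).exists():
            raise FileNotFoundError(f"labels CSV not found: {config.labels_csv}")
        raise NotImplementedError(
            "file-based cohorts: load slices with milcta.core.read_slice and "
            "assemble a CohortManifest; the bundled pipeline runs in synthetic mode"
        )
    cohort = generate_cohort(config.synthetic_config())
    n_slices = sum(cohort.slice_counts().values())
    logger.info(
        "cohort: %d patients, %d slices, %d positives",
        len(cohort.patient_ids),
        n_slices,
        sum(cohort.labels.values()),
    )
    summary = run_experiment(cohort, config.experiment_config(), out_dir=out_dir)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    (out_dir / "run.json").write_text(json.dumps(stamp, indent=2))
    config.to_yaml(out_dir / "config.yaml")
    return summary
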