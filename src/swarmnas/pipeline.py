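"""Experiment orchestration: config -> data -> search -> final evaluation.

A single :class:`ExperimentConfig` (loadable from YAML or JSON) describes
one end-to-end run: where the labelled images come from (a directory +
CSV in the ``id_code,diagnosis`` dialect, or a synthetic-data spec), which
search to run (ACO or PSO) with which budget, how candidates are trained,
and how the final best model is evaluated.  Artifacts — best-architecture
JSON, per-candidate history CSV, metrics CSV and a log — are written to
the output directory together with the full config and seed, sufficient
to replay the run bit-identically with the deterministic trainer.

A run also records a success flag against configurable goal/epsilon pairs
(metric + epsilon >= G), defaulting to the strongest pretrained-baseline
scores the search is meant to beat: accuracy >= 74.8 (epsilon 1.5
percentage points), AUC >= 0.91 (epsilon 0.2), kappa >= 0.776
(epsilon 0.02).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import synth
from .aco import ACOConfig, run_aco_search
from .arch import Architecture, ConstraintSet, SearchSpaceSpec, aco_default_space, desk_space, pso_default_space
from .evaluation import SurrogateEvaluator, TrainerSpec, TrainingEvaluator
from .pso import PSOConfig, run_pso_search

__all__ = ["ExperimentConfig", "GoalSpec", "run_experiment", "load_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoalSpec:
    """One success criterion: metric + epsilon >= goal."""

    metric: str
    goal: float
    epsilon: float

    def satisfied(self, value: float) -> bool:
        return value + self.epsilon >= self.goal


#: Best pretrained-baseline scores, the default search goals.
DEFAULT_GOALS = (
    GoalSpec("accuracy", 74.8, 1.5),  # percent scale
    GoalSpec("auc", 0.91, 0.2),
    GoalSpec("kappa", 0.776, 0.02),
)


@dataclass
class ExperimentConfig:
    mode: str = "pso"  # "aco" | "pso"
    # data source: exactly one of (data_dir + labels_csv) or synth_spec
    data_dir: str | None = None
    labels_csv: str | None = None
    synth_spec: synth.SynthSpec | None = None
    space: str = "desk"  # "desk" | "aco" | "pso"
    aco: ACOConfig = field(default_factory=ACOConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    trainer: TrainerSpec = field(default_factory=TrainerSpec)
    trainer_backend: str = "numpy"  # "numpy" | "surrogate"
    epochs_final: int = 5
    folds: int = 1
    goals: tuple[GoalSpec, ...] = DEFAULT_GOALS
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("aco", "pso"):
            raise ValueError(f"mode must be 'aco' or 'pso', got {self.mode!r}")
        has_dir = self.data_dir is not None and self.labels_csv is not None
        has_synth = self.synth_spec is not None
        if has_dir == has_synth:
            raise ValueError("exactly one data source (directory+CSV | synth) required")
        if self.trainer_backend not in ("numpy", "surrogate"):
            raise ValueError(f"unknown trainer backend {self.trainer_backend!r}")
        if self.space not in ("desk", "aco", "pso"):
            raise ValueError(f"unknown search space preset {self.space!r}")


def load_config(path: str) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = ExperimentConfig(
        mode=raw.get("mode", "pso"),
        data_dir=raw.get("data_dir"),
        labels_csv=raw.get("labels_csv"),
        synth_spec=(
            synth.SynthSpec(**{**raw["synth"], "class_proportions": tuple(
                raw["synth"].get("class_proportions", synth.APTOS_PROPORTIONS)
            )})
            if "synth" in raw
            else None
        ),
        space=raw.get("space", "desk"),
        aco=ACOConfig(**raw.get("aco", {})),
        pso=PSOConfig(**raw.get("pso", {})),
        trainer=TrainerSpec(**raw.get("trainer", {})),
        trainer_backend=raw.get("trainer_backend", "numpy"),
        epochs_final=raw.get("epochs_final", 5),
        folds=raw.get("folds", 1),
        out_dir=raw.get("out_dir", "results"),
        seed=raw.get("seed", 0),
    )
    cfg.validate()
    return cfg


def _space_for(cfg: ExperimentConfig) -> SearchSpaceSpec:
    return {"desk": desk_space, "aco": aco_default_space, "pso": pso_default_space}[
        cfg.space
    ]()


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run one seeded experiment end to end; returns the result bundle."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    log_path = os.path.join(cfg.out_dir, "run.log")
    handler = logging.FileHandler(log_path)
    logging.getLogger("swarmnas").addHandler(handler)
    try:
        return _run(cfg)
    finally:
        logging.getLogger("swarmnas").removeHandler(handler)
        handler.close()


def _run(cfg: ExperimentConfig) -> dict:
    rules = ConstraintSet()
    space = _space_for(cfg)
    trainer = dataclasses.replace(cfg.trainer, rng_seed=cfg.seed)

    if cfg.synth_spec is not None:
        spec = dataclasses.replace(cfg.synth_spec, rng_seed=cfg.seed)
        ds = synth.generate_dataset(spec)
        images, labels = ds.images, ds.labels
    else:
        images, labels, _ = synth.read_dataset(
            cfg.data_dir, cfg.labels_csv, image_size=trainer.image_size
        )
    input_shape = images.shape[1:]

    train_eval = TrainingEvaluator(images, labels, trainer)
    evaluator = (
        SurrogateEvaluator(seed=cfg.seed)
        if cfg.trainer_backend == "surrogate"
        else train_eval
    )

    if cfg.mode == "aco":
        aco_cfg = dataclasses.replace(cfg.aco, rng_seed=cfg.seed)
        best_arch, history = run_aco_search(
            evaluator, aco_cfg, space, rules, input_shape=input_shape
        )
        records = history.records
        n_expected = aco_cfg.n_ants * aco_cfg.depth
    else:
        pso_cfg = dataclasses.replace(cfg.pso, rng_seed=cfg.seed)
        best_arch, history = run_pso_search(
            evaluator, pso_cfg, space, rules, input_shape=input_shape
        )
        records = history.records
        n_expected = pso_cfg.runs * pso_cfg.iterations * pso_cfg.swarm_size

    # final retrain + metrics of the returned architecture
    result, _ = train_eval.score(best_arch, epochs=cfg.epochs_final)
    metrics = {
        "accuracy": result.accuracy * 100.0,  # percent, matching the goal scale
        "auc": result.auc,
        "kappa": result.kappa,
        "kappa_quadratic": result.kappa_quadratic,
        "parameter_count": result.parameter_count,
    }
    success = {
        g.metric: g.satisfied(metrics[g.metric]) for g in cfg.goals if g.metric in metrics
    }

    # artifacts
    arch_path = os.path.join(cfg.out_dir, "best_architecture.json")
    with open(arch_path, "w") as fh:
        fh.write(best_arch.to_json())
    hist_path = os.path.join(cfg.out_dir, "history.csv")
    pd.DataFrame(records).to_csv(hist_path, index=False)
    metrics_path = os.path.join(cfg.out_dir, "metrics.csv")
    pd.DataFrame([metrics]).to_csv(metrics_path, index=False)
    env_record = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "space": cfg.space,
        "trainer_backend": cfg.trainer_backend,
        "n_evaluations": len(records),
        "n_evaluations_expected": n_expected,
        "goals": [dataclasses.asdict(g) for g in cfg.goals],
        "success": success,
    }
    with open(os.path.join(cfg.out_dir, "experiment.json"), "w") as fh:
        json.dump(env_record, fh, indent=2)

    return {
        "best_architecture": best_arch,
        "history": records,
        "metrics": metrics,
        "success": success,
        "environment": env_record,
        "artifacts": {
            "architecture": arch_path,
            "history": hist_path,
            "metrics": metrics_path,
        },
    }
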