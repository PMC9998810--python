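"""End-to-end experiment driver: tiles -> features -> MLP -> reports.

Bundles the stages the command-line interface and the test-bench both
run: synthesise (or load) labeled tiles, extract the 46 descriptors,
make the 2:1:1 split, run the BP + conjugate-gradient training
schedule, and tabulate classification statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mlp as mlp_mod
from .datatypes import LabeledImage
from .features import build_feature_table, extract_features
from .mlp import (
    ClassificationStatistics,
    MLPModel,
    SplitIndex,
    TrainingTrace,
    classification_statistics,
    prepare_training_arrays,
    split_dataset,
    train_bp,
    train_cg,
)
from .synthetic_data import PowderClassSpec, default_class_specs, generate_tile

__all__ = ["TrainSettings", "ExperimentResult", "synthetic_feature_table", "train_and_evaluate", "run_synthetic_experiment"]


@dataclass
class TrainSettings:
    """Hyperparameters of the two-stage training schedule."""

    epochs_bp: int = 50
    epochs_cg: int = 119
    learning_rate: float = 0.1
    momentum: float = 0.3
    accept_threshold: float = 0.5
    n_hidden: int = 11


@dataclass
class ExperimentResult:
    model: MLPModel
    table: pd.DataFrame
    split: SplitIndex
    statistics: ClassificationStatistics
    traces: list[TrainingTrace] = field(default_factory=list)

    def rms_summary(self) -> dict[str, float]:
        x, y = prepare_training_arrays(self.table)
        return {
            name: self.model.rms(x[self.split.subset(name)], y[self.split.subset(name)])
            for name in ("training", "validation", "test")
        }


def synthetic_feature_table(
    n_tiles_per_class: int,
    height: int = 400,
    width: int = 400,
    seed: int = 0,
    specs: list[PowderClassSpec] | None = None,
) -> pd.DataFrame:
    """Feature table of a balanced synthetic tile set.

    Tiles are generated and reduced to their descriptors one at a time,
    so arbitrarily many 400x400 tiles fit in memory.
    """
    if specs is None:
        specs = default_class_specs()
    seeds = np.random.default_rng(seed).integers(0, 2**31, size=len(specs) * n_tiles_per_class)
    rows, labels, prov = [], [], []
    k = 0
    for spec in specs:
        for _ in range(n_tiles_per_class):
            tile = generate_tile(spec, height, width, int(seeds[k]))
            rows.append(extract_features(tile))
            labels.append((spec.sample_id, spec.juice_content, spec.saccharification))
            prov.append(tile.source)
            k += 1
    table = pd.DataFrame(rows).reset_index(drop=True)
    lab = pd.DataFrame(labels, columns=["sample_id", "juice_content", "saccharification"])
    table = pd.concat([table, lab], axis=1)
    table["provenance"] = prov
    return table


def train_and_evaluate(
    table: pd.DataFrame,
    seed: int = 0,
    settings: TrainSettings | None = None,
) -> ExperimentResult:
    """Split, train (BP then CG) and tabulate classification statistics."""
    settings = settings or TrainSettings()
    x, y = prepare_training_arrays(table)
    split = split_dataset(len(table), seed=seed)
    model = MLPModel(n_input=x.shape[1], n_hidden=settings.n_hidden, n_output=y.shape[1])
    model.initialize(seed=seed)
    model.fit_standardization(x[split.train])
    traces = [
        train_bp(
            model, x, y, split,
            epochs=settings.epochs_bp,
            learning_rate=settings.learning_rate,
            momentum=settings.momentum,
            seed=seed,
        ),
        train_cg(model, x, y, split, max_epochs=settings.epochs_cg),
    ]
    stats = classification_statistics(
        model, table, split, accept_threshold=settings.accept_threshold
    )
    return ExperimentResult(model=model, table=table, split=split,
                            statistics=stats, traces=traces)


def run_synthetic_experiment(
    n_tiles_per_class: int,
    height: int = 400,
    width: int = 400,
    seed: int = 0,
    specs: list[PowderClassSpec] | None = None,
    settings: TrainSettings | None = None,
) -> ExperimentResult:
    """Full synthetic pipeline with one master seed."""
    table = synthetic_feature_table(n_tiles_per_class, height, width, seed, specs)
    return train_and_evaluate(table, seed=seed, settings=settings)
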