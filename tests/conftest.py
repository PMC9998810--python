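import numpy as np
import pandas as pd
import pytest

from powdervision.mlp import (
    MLPModel,
    encode_targets,
    split_dataset,
    train_bp,
    train_cg,
)
from powdervision.pipeline import (
    synthetic_feature_table,
    train_and_evaluate,
)


@pytest.fixture(scope="session")
def small_table():
    """Feature table of a small separable synthetic set (120 rows)."""
    return synthetic_feature_table(20, height=64, width=64, seed=3)


@pytest.fixture(scope="session")
def trained_small(small_table):
    """A model trained end-to-end on the small synthetic set."""
    return train_and_evaluate(small_table, seed=3)


def make_toy_task(seed: int, n: int = 400, sd_signal: float = 0.7):
    """Two-feature toy classification: f1 drives the class, f2 is noise.

    The class means on f1 sit 2 units apart with overlap sd_signal, so
    the task carries irreducible error — a meaningful baseline for
    error-quotient ratios. Returns (model, table, targets, split) with
    the model trained by the BP + CG schedule on a 2-input network.
    """
    rng = np.random.default_rng(seed)
    cls = rng.integers(0, 2, size=n)
    table = pd.DataFrame(
        {
            "f1": cls * 2.0 + rng.normal(0, sd_signal, n),
            "f2": rng.normal(0, 1.0, n),
            "sample_id": np.where(cls == 0, 1, 2),
            "juice_content": np.where(cls == 0, 30, 40),
            "saccharification": np.where(cls == 0, "L", "H"),
        }
    )
    x = table[["f1", "f2"]].to_numpy(float)
    y = encode_targets(table)
    split = split_dataset(n, seed=seed)
    model = MLPModel(n_input=2, n_hidden=6, n_output=10, feature_names=("f1", "f2"))
    model.initialize(seed=seed)
    model.fit_standardization(x[split.train])
    train_bp(model, x, y, split, epochs=50, seed=seed)
    train_cg(model, x, y, split, max_epochs=119)
    return model, table, y, split
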