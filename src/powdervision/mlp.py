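"""Multi-layer perceptron classifier for powder tiles.

The network is a 46-11-10 perceptron with logistic activations on the
hidden and output layers and a sum-of-squares loss. The ten output
units decompose into three heads:

* units 0-5: one-of-N code of the sample number (1-6),
* units 6-8: one-of-N code of the dry-juice content (30/40/50 %),
* unit 9:   two-state code of carrier saccharification (H = 1, L = 0).

Training follows a two-stage schedule: stochastic back-propagation with
momentum for a fixed number of epochs, then full-batch Polak-Ribiere
conjugate gradient with an Armijo line search, retaining the weights
with the best validation RMS seen (the guard against over-learning).

Classification uses a reject option: a head answers only when its
winning unit's activation clears an acceptance threshold, otherwise the
case is counted as Unknown. Per-subset, per-class Correct / Wrong /
Unknown counts make up the classification statistics report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import JUICE_LEVELS, SAMPLE_IDS
from .features import FEATURE_NAMES, LABEL_COLUMNS, feature_matrix

__all__ = [
    "SplitIndex",
    "MLPModel",
    "Prediction",
    "ClassificationStatistics",
    "split_dataset",
    "rms_error",
    "accuracy",
    "train_bp",
    "train_cg",
    "conjugate_gradient_minimize",
    "classify",
    "predict_batch",
    "classification_statistics",
    "UNKNOWN",
]

UNKNOWN = "Unknown"
SUBSETS = ("training", "validation", "test")
TASKS = ("sample_id", "juice_content", "saccharification")

_HEAD_SLICES = {
    "sample_id": slice(0, 6),
    "juice_content": slice(6, 9),
    "saccharification": slice(9, 10),
}
_HEAD_LEVELS = {
    "sample_id": list(SAMPLE_IDS),
    "juice_content": list(JUICE_LEVELS),
}


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint training / validation / test row indices (2:1:1 rule)."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def subset(self, name: str) -> np.ndarray:
        return {"training": self.train, "validation": self.validation,
                "test": self.test}[name]


def split_dataset(n_rows: int, seed: int = 0) -> SplitIndex:
    """Seeded 2:1:1 split into training, validation and test rows.

    Sizes are (round(n/2), floor(n/4), remainder) — half-up rounding —
    assigned by a uniform shuffle followed by contiguous slicing, so
    4218 rows give 2109 / 1054 / 1055.
    """
    if n_rows < 4:
        raise ValueError("need at least 4 rows to form a 2:1:1 split")
    n_train = int(np.floor(n_rows / 2 + 0.5))
    n_val = n_rows // 4
    perm = np.random.default_rng(seed).permutation(n_rows)
    return SplitIndex(
        train=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
    )


def rms_error(actual, predicted) -> float:
    """Root-mean-square deviation sqrt(sum((y - z)^2) / n).

    Arrays are flattened; for a whole output matrix the mean runs over
    every (case, unit) element, so RMS stays in [0, 1] when targets and
    outputs do.
    """
    y = np.asarray(actual, dtype=np.float64).ravel()
    z = np.asarray(predicted, dtype=np.float64).ravel()
    if y.shape != z.shape:
        raise ValueError(f"length mismatch: {y.size} vs {z.size}")
    if y.size == 0:
        raise ValueError("rms_error requires at least one case")
    return float(np.sqrt(np.mean((y - z) ** 2)))


def accuracy(t_correct: int, n_total: int) -> float:
    """Fraction of correctly classified cases, t / n."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= t_correct <= n_total:
        raise ValueError(f"t_correct={t_correct} outside [0, {n_total}]")
    return t_correct / n_total


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class MLPModel:
    """Weights, input standardisation and output coding of the network."""

    n_input: int = 46
    n_hidden: int = 11
    n_output: int = 10
    feature_names: tuple[str, ...] = tuple(FEATURE_NAMES)
    w1: np.ndarray | None = None
    b1: np.ndarray | None = None
    w2: np.ndarray | None = None
    b2: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None

    def initialize(self, seed: int = 0) -> "MLPModel":
        """Seeded uniform [-0.5, 0.5] weight and bias initialisation."""
        rng = np.random.default_rng(seed)
        self.w1 = rng.uniform(-0.5, 0.5, (self.n_input, self.n_hidden))
        self.b1 = rng.uniform(-0.5, 0.5, self.n_hidden)
        self.w2 = rng.uniform(-0.5, 0.5, (self.n_hidden, self.n_output))
        self.b2 = rng.uniform(-0.5, 0.5, self.n_output)
        return self

    def fit_standardization(self, x_train: np.ndarray) -> None:
        """Per-feature mean/SD from training rows only.

        A feature that is constant on the training rows (SD zero up to
        floating-point residue relative to its magnitude) gets SD 1, so
        standardisation never amplifies rounding noise.
        """
        self.x_mean = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        degenerate = sd <= 1e-9 * np.maximum(1.0, np.abs(self.x_mean))
        self.x_sd = np.where(degenerate, 1.0, sd)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            raise RuntimeError("standardization constants not fitted")
        return (x - self.x_mean) / self.x_sd

    def forward(self, x: np.ndarray, standardized: bool = False) -> np.ndarray:
        xs = x if standardized else self.standardize(x)
        a1 = _sigmoid(xs @ self.w1 + self.b1)
        return _sigmoid(a1 @ self.w2 + self.b2)

    def rms(self, x: np.ndarray, y: np.ndarray, standardized: bool = False) -> float:
        return rms_error(y, self.forward(x, standardized=standardized))

    # -- flat parameter vector helpers (used by conjugate gradient) --

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [self.w1.ravel(), self.b1, self.w2.ravel(), self.b2]
        )

    def set_params(self, theta: np.ndarray) -> None:
        i, j = self.n_input * self.n_hidden, self.n_hidden
        k = self.n_hidden * self.n_output
        self.w1 = theta[:i].reshape(self.n_input, self.n_hidden).copy()
        self.b1 = theta[i : i + j].copy()
        self.w2 = theta[i + j : i + j + k].reshape(self.n_hidden, self.n_output).copy()
        self.b2 = theta[i + j + k :].copy()

    # -- persistence --

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "powdervision-mlp",
            "version": 1,
            "layer_sizes": [self.n_input, self.n_hidden, self.n_output],
            "feature_names": list(self.feature_names),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "powdervision-mlp":
            raise ValueError(f"{path} is not a powdervision MLP model file")
        n_in, n_hid, n_out = payload["layer_sizes"]
        model = cls(n_input=n_in, n_hidden=n_hid, n_output=n_out,
                    feature_names=tuple(payload["feature_names"]))
        model.w1 = np.array(payload["w1"])
        model.b1 = np.array(payload["b1"])
        model.w2 = np.array(payload["w2"])
        model.b2 = np.array(payload["b2"])
        model.x_mean = np.array(payload["x_mean"])
        model.x_sd = np.array(payload["x_sd"])
        return model


def encode_targets(labels: pd.DataFrame) -> np.ndarray:
    """Map the three labels of each row onto the 10-unit target code."""
    n = len(labels)
    y = np.zeros((n, 10))
    sid = labels["sample_id"].to_numpy()
    juice = labels["juice_content"].to_numpy()
    sacch = labels["saccharification"].to_numpy()
    for k, s in enumerate(SAMPLE_IDS):
        y[sid == s, k] = 1.0
    for k, j in enumerate(JUICE_LEVELS):
        y[juice == j, 6 + k] = 1.0
    y[:, 9] = (sacch == "H").astype(float)
    return y


def prepare_training_arrays(table: pd.DataFrame):
    """(X, Y) from a feature table: canonical 46 columns + encoded labels."""
    missing = [c for c in LABEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks label columns: {missing}")
    return feature_matrix(table), encode_targets(table)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _sse_and_grad(model: MLPModel, xs: np.ndarray, y: np.ndarray):
    """Half sum-of-squares loss and its gradient as a flat vector."""
    a1 = _sigmoid(xs @ model.w1 + model.b1)
    a2 = _sigmoid(a1 @ model.w2 + model.b2)
    err = a2 - y
    loss = 0.5 * float(np.sum(err**2))
    d2 = err * a2 * (1.0 - a2)
    gw2 = a1.T @ d2
    gb2 = d2.sum(axis=0)
    d1 = (d2 @ model.w2.T) * a1 * (1.0 - a1)
    gw1 = xs.T @ d1
    gb1 = d1.sum(axis=0)
    return loss, np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])


@dataclass
class TrainingTrace:
    """Per-epoch RMS history of one training stage."""

    stage: str
    train_rms: list[float] = field(default_factory=list)
    validation_rms: list[float] = field(default_factory=list)


def train_bp(
    model: MLPModel,
    x: np.ndarray,
    y: np.ndarray,
    split: SplitIndex,
    epochs: int = 50,
    learning_rate: float = 0.1,
    momentum: float = 0.3,
    seed: int = 0,
) -> TrainingTrace:
    """Stochastic back-propagation with momentum on the training rows.

    Rows are reshuffled each epoch with a seeded generator; the trace
    records training and validation RMS after every epoch (entry 0 is
    the pre-training state). The model is updated in place.
    """
    if model.w1 is None:
        model.initialize(seed)
    if model.x_mean is None:
        model.fit_standardization(x[split.train])
    xs = model.standardize(x)
    xtr, ytr = xs[split.train], y[split.train]
    xva, yva = xs[split.validation], y[split.validation]

    trace = TrainingTrace(stage="bp")
    trace.train_rms.append(model.rms(xtr, ytr, standardized=True))
    trace.validation_rms.append(model.rms(xva, yva, standardized=True))

    rng = np.random.default_rng(seed)
    vel = np.zeros(model.get_params().size)
    n_tr = len(xtr)
    for _ in range(epochs):
        order = rng.permutation(n_tr)
        for i in order:
            _, grad = _sse_and_grad(model, xtr[i : i + 1], ytr[i : i + 1])
            vel = momentum * vel - learning_rate * grad
            model.set_params(model.get_params() + vel)
        tr_rms = model.rms(xtr, ytr, standardized=True)
        if not np.isfinite(tr_rms):
            raise FloatingPointError(
                "training diverged (non-finite RMS); lower the learning rate"
            )
        trace.train_rms.append(tr_rms)
        trace.validation_rms.append(model.rms(xva, yva, standardized=True))
    return trace


def conjugate_gradient_minimize(
    fun_grad,
    theta0: np.ndarray,
    max_iters: int,
    callback=None,
    armijo_c1: float = 1e-4,
    max_backtracks: int = 40,
) -> tuple[np.ndarray, list[float]]:
    """Polak-Ribiere (PR+) conjugate gradient with Armijo backtracking.

    ``fun_grad(theta)`` returns (loss, gradient). Each accepted
    iteration satisfies the sufficient-decrease condition, so the loss
    sequence is strictly non-increasing. When the conjugate direction
    fails the line search the iteration restarts as steepest descent; a
    second failure terminates. Returns the final parameters and the
    loss after every accepted iteration (entry 0 is the start).
    """
    theta = np.asarray(theta0, dtype=np.float64).copy()
    loss, grad = fun_grad(theta)
    losses = [loss]
    direction = -grad
    alpha = 1.0 / max(1.0, float(np.linalg.norm(grad)))
    for _ in range(max_iters):
        accepted = False
        for attempt_dir in (direction, -grad):
            slope = float(grad @ attempt_dir)
            if slope >= 0:
                continue
            a = alpha
            for _ in range(max_backtracks):
                cand = theta + a * attempt_dir
                cand_loss, cand_grad = fun_grad(cand)
                if cand_loss <= loss + armijo_c1 * a * slope:
                    g_prev = grad
                    theta, loss, grad = cand, cand_loss, cand_grad
                    beta = max(
                        0.0,
                        float(grad @ (grad - g_prev))
                        / max(float(g_prev @ g_prev), 1e-300),
                    )
                    direction = -grad + beta * attempt_dir
                    alpha = max(a * 2.0, 1e-10)
                    accepted = True
                    break
                a *= 0.5
            if accepted:
                break
        if not accepted:
            break
        losses.append(loss)
        if callback is not None:
            callback(theta, loss)
    return theta, losses


def train_cg(
    model: MLPModel,
    x: np.ndarray,
    y: np.ndarray,
    split: SplitIndex,
    max_epochs: int = 119,
) -> TrainingTrace:
    """Full-batch conjugate-gradient refinement after back-propagation.

    Runs :func:`conjugate_gradient_minimize` on the training-set
    sum-of-squares loss, recording training and validation RMS per
    accepted iteration. The weights with the lowest validation RMS seen
    are restored at the end, so a late over-fitting drift cannot
    degrade the returned model (the guard against over-learning).
    """
    if model.w1 is None or model.x_mean is None:
        raise RuntimeError("train_cg expects a BP-initialized, standardized model")
    xs = model.standardize(x)
    xtr, ytr = xs[split.train], y[split.train]
    xva, yva = xs[split.validation], y[split.validation]

    trace = TrainingTrace(stage="cg")
    trace.train_rms.append(model.rms(xtr, ytr, standardized=True))
    trace.validation_rms.append(model.rms(xva, yva, standardized=True))

    n_elems = ytr.size
    best = {"val": trace.validation_rms[0], "theta": model.get_params()}

    def fun_grad(theta):
        model.set_params(theta)
        return _sse_and_grad(model, xtr, ytr)

    def record(theta, loss):
        model.set_params(theta)
        trace.train_rms.append(float(np.sqrt(2.0 * loss / n_elems)))
        val = model.rms(xva, yva, standardized=True)
        trace.validation_rms.append(val)
        if val < best["val"]:
            best["val"] = val
            best["theta"] = theta.copy()

    conjugate_gradient_minimize(
        fun_grad, model.get_params(), max_iters=max_epochs, callback=record
    )
    model.set_params(best["theta"])
    return trace


# ---------------------------------------------------------------------------
# Classification with reject option
# ---------------------------------------------------------------------------


@dataclass
class Prediction:
    """Per-head activations and accept/reject decisions for one case."""

    activations: dict[str, np.ndarray]
    decisions: dict[str, object]


def _decide(acts: np.ndarray, threshold: float) -> list:
    """Vectorised head decisions for an n x 10 activation matrix."""
    decisions = {}
    for task in ("sample_id", "juice_content"):
        block = acts[:, _HEAD_SLICES[task]]
        winner = block.argmax(axis=1)
        accept = block.max(axis=1) >= threshold
        levels = np.array(_HEAD_LEVELS[task], dtype=object)
        decisions[task] = np.where(accept, levels[winner], UNKNOWN)
    a = acts[:, 9]
    decisions["saccharification"] = np.where(
        a >= threshold, "H", np.where(a <= 1.0 - threshold, "L", UNKNOWN)
    )
    return decisions


def classify(model: MLPModel, row: np.ndarray, accept_threshold: float = 0.5) -> Prediction:
    """Classify one feature row; a head below threshold answers Unknown.

    For the single-unit saccharification head, activation >= threshold
    means H and activation <= 1 - threshold means L.
    """
    acts = model.forward(np.atleast_2d(np.asarray(row, dtype=np.float64)))
    decided = _decide(acts, accept_threshold)
    return Prediction(
        activations={t: acts[0, _HEAD_SLICES[t]] for t in TASKS},
        decisions={t: decided[t][0] for t in TASKS},
    )


def predict_batch(model: MLPModel, x: np.ndarray, accept_threshold: float = 0.5) -> pd.DataFrame:
    """Head decisions for every row of ``x`` as a DataFrame."""
    acts = model.forward(x)
    return pd.DataFrame(_decide(acts, accept_threshold))


@dataclass
class ClassificationStatistics:
    """Correct / Wrong / Unknown counts per task, subset and true class."""

    table: pd.DataFrame  # columns: task, subset, class, total, correct, wrong, unknown

    def cell(self, task: str, subset: str, cls) -> pd.Series:
        sel = self.table[
            (self.table["task"] == task)
            & (self.table["subset"] == subset)
            & (self.table["class"].astype(str) == str(cls))
        ]
        return sel.iloc[0]

    def subset_quality(self, task: str, subset: str) -> float:
        sel = self.table[(self.table["task"] == task) & (self.table["subset"] == subset)]
        return accuracy(int(sel["correct"].sum()), int(sel["total"].sum()))

    def overall_accuracy(self, task: str) -> float:
        sel = self.table[self.table["task"] == task]
        return accuracy(int(sel["correct"].sum()), int(sel["total"].sum()))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def report(self) -> str:
        lines = ["Classification statistics (Correct / Wrong / Unknown by true class)"]
        for task in TASKS:
            lines.append(f"\n== {task} ==")
            for subset in SUBSETS:
                sel = self.table[(self.table["task"] == task)
                                 & (self.table["subset"] == subset)]
                q = self.subset_quality(task, subset)
                lines.append(f"  {subset} (quality {q:.2f}):")
                for _, r in sel.iterrows():
                    lines.append(
                        f"    class {r['class']}: total {r['total']}, "
                        f"correct {r['correct']}, wrong {r['wrong']}, "
                        f"unknown {r['unknown']}"
                    )
            lines.append(f"  overall accuracy: {self.overall_accuracy(task):.2f}")
        return "\n".join(lines)


def classification_statistics(
    model: MLPModel,
    table: pd.DataFrame,
    split: SplitIndex,
    accept_threshold: float = 0.5,
) -> ClassificationStatistics:
    """Tabulate per-subset, per-class counts for all three heads.

    Every cell satisfies total = correct + wrong + unknown by
    construction.
    """
    x = table.loc[:, list(model.feature_names)].to_numpy(dtype=np.float64)
    decisions = predict_batch(model, x, accept_threshold)
    rows = []
    for task in TASKS:
        truth = table[task].to_numpy()
        decided = decisions[task].to_numpy()
        levels = _HEAD_LEVELS.get(task, ["L", "H"])
        for subset in SUBSETS:
            idx = split.subset(subset)
            for cls in levels:
                in_cls = idx[truth[idx] == cls]
                d = decided[in_cls]
                n_unknown = int(np.sum(d == UNKNOWN))
                n_correct = int(np.sum(d == cls))
                rows.append(
                    {
                        "task": task,
                        "subset": subset,
                        "class": cls,
                        "total": len(in_cls),
                        "correct": n_correct,
                        "wrong": len(in_cls) - n_correct - n_unknown,
                        "unknown": n_unknown,
                    }
                )
    return ClassificationStatistics(table=pd.DataFrame(rows))
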