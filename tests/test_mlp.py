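"""MLP classifier: split rule, error metrics, training, reject option."""

import numpy as np
import pandas as pd
import pytest

from powdervision.mlp import (
    UNKNOWN,
    MLPModel,
    accuracy,
    classification_statistics,
    classify,
    conjugate_gradient_minimize,
    encode_targets,
    rms_error,
    split_dataset,
    train_bp,
    train_cg,
)
from powdervision.pipeline import train_and_evaluate

from conftest import make_toy_task


class TestSplit:
    @pytest.mark.parametrize(
        "n, sizes",
        [(4218, (2109, 1054, 1055)), (12, (6, 3, 3)), (5, (3, 1, 1)), (4, (2, 1, 1))],
    )
    def test_sizes(self, n, sizes):
        s = split_dataset(n, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == sizes

    def test_disjoint_cover(self):
        s = split_dataset(101, seed=3)
        all_idx = np.concatenate([s.train, s.validation, s.test])
        assert sorted(all_idx) == list(range(101))

    def test_seed_determinism(self):
        a, b = split_dataset(50, seed=9), split_dataset(50, seed=9)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)
        c = split_dataset(50, seed=10)
        assert not np.array_equal(a.train, c.train)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(3)


class TestMetrics:
    def test_rms_examples(self):
        assert rms_error([1, 0, 1], [1, 0, 1]) == 0.0
        assert rms_error([1, 0, 1], [0.5, 0.5, 0.5]) == pytest.approx(0.5)
        assert rms_error([1, 0], [0, 0]) == pytest.approx(np.sqrt(0.5))

    def test_rms_mismatch(self):
        with pytest.raises(ValueError):
            rms_error([1, 2], [1])

    def test_rms_bounded_for_unit_interval_data(self):
        rng = np.random.default_rng(0)
        y, z = rng.random((10, 10)), rng.random((10, 10))
        assert 0.0 <= rms_error(y, z) <= 1.0

    def test_accuracy(self):
        # pooled correct counts of the published classification table
        assert round(accuracy(3862, 4218), 2) == 0.92
        assert accuracy(5, 5) == 1.0
        assert accuracy(0, 7) == 0.0
        with pytest.raises(ValueError):
            accuracy(8, 7)
        with pytest.raises(ValueError):
            accuracy(-1, 7)


def _separable(seed=0, n=80):
    rng = np.random.default_rng(seed)
    cls = np.arange(n) % 2
    table = pd.DataFrame(
        {
            "sample_id": cls + 1,
            "juice_content": np.where(cls == 0, 30, 40),
            "saccharification": np.where(cls == 0, "L", "H"),
        }
    )
    x = np.column_stack([cls * 4.0 + rng.normal(0, 0.2, n), rng.normal(0, 1, n)])
    return x, encode_targets(table), split_dataset(n, seed=seed)


class TestTrainBP:
    def test_learning_reduces_rms(self):
        x, y, split = _separable()
        model = MLPModel(n_input=2, n_hidden=4, feature_names=("f1", "f2")).initialize(0)
        model.fit_standardization(x[split.train])
        trace = train_bp(model, x, y, split, epochs=50, seed=0)
        assert trace.train_rms[-1] < trace.train_rms[0]
        assert len(trace.train_rms) == 51

    def test_zero_learning_rate_is_null_update(self):
        x, y, split = _separable()
        model = MLPModel(n_input=2, n_hidden=4, feature_names=("f1", "f2")).initialize(0)
        model.fit_standardization(x[split.train])
        before = model.get_params().copy()
        trace = train_bp(model, x, y, split, epochs=5, learning_rate=0.0, momentum=0.0)
        np.testing.assert_array_equal(model.get_params(), before)
        assert len(set(np.round(trace.train_rms, 12))) == 1

    def test_seeded_determinism(self):
        results = []
        for _ in range(2):
            x, y, split = _separable(seed=4)
            model = MLPModel(n_input=2, n_hidden=4, feature_names=("f1", "f2"))
            model.initialize(4)
            model.fit_standardization(x[split.train])
            train_bp(model, x, y, split, epochs=10, seed=4)
            results.append(model.get_params())
        np.testing.assert_array_equal(results[0], results[1])


class TestConjugateGradient:
    def test_quadratic_toy_reaches_analytic_minimum(self):
        """2-weight quadratic: CG lands on the closed-form minimiser."""
        a_mat = np.array([[3.0, 1.0], [1.0, 2.0]])
        b = np.array([1.0, -4.0])
        opt = np.linalg.solve(a_mat, -b)  # minimiser of 0.5 x'Ax + b'x

        def fun_grad(theta):
            return 0.5 * theta @ a_mat @ theta + b @ theta, a_mat @ theta + b

        theta, losses = conjugate_gradient_minimize(fun_grad, np.zeros(2), max_iters=100)
        np.testing.assert_allclose(theta, opt, atol=1e-6)
        assert losses == sorted(losses, reverse=True)

    def test_cg_trace_monotone_and_not_worse_than_bp(self):
        x, y, split = _separable(seed=1)
        model = MLPModel(n_input=2, n_hidden=4, feature_names=("f1", "f2")).initialize(1)
        model.fit_standardization(x[split.train])
        train_bp(model, x, y, split, epochs=20, seed=1)
        bp_val = model.rms(x[split.validation], y[split.validation])
        trace = train_cg(model, x, y, split, max_epochs=60)
        diffs = np.diff(trace.train_rms)
        assert (diffs <= 1e-12).all()  # accepted iterations never increase RMS
        cg_val = model.rms(x[split.validation], y[split.validation])
        assert cg_val <= bp_val + 1e-12

    def test_requires_initialized_model(self):
        x, y, split = _separable()
        with pytest.raises(RuntimeError):
            train_cg(MLPModel(n_input=2, feature_names=("f1", "f2")), x, y, split)


def _fixed_output_model(activations):
    """A model whose outputs are constant: w=0, biases at the logits."""
    acts = np.array(activations, dtype=float)
    model = MLPModel(n_input=2, n_hidden=1, n_output=10, feature_names=("f1", "f2"))
    model.w1 = np.zeros((2, 1))
    model.b1 = np.array([0.0])
    model.w2 = np.zeros((1, 10))
    model.b2 = np.log(acts / (1 - acts))
    model.x_mean = np.zeros(2)
    model.x_sd = np.ones(2)
    return model


class TestClassify:
    def test_confident_head_decides(self):
        acts = [0.05] * 10
        acts[0] = 0.9         # sample 1
        acts[6] = 0.9         # juice 30
        acts[9] = 0.9         # saccharification H
        pred = classify(_fixed_output_model(acts), np.zeros(2))
        assert pred.decisions == {
            "sample_id": 1, "juice_content": 30, "saccharification": "H"
        }

    def test_below_threshold_is_unknown(self):
        pred = classify(_fixed_output_model([0.4] * 10), np.zeros(2), accept_threshold=0.5)
        assert pred.decisions["sample_id"] == UNKNOWN
        assert pred.decisions["juice_content"] == UNKNOWN
        # the two-sided single-unit rule: 0.4 <= 1 - 0.5 reads as L
        assert pred.decisions["saccharification"] == "L"

    def test_single_unit_unknown_band(self):
        # with threshold > 0.5 a middling activation is rejected
        pred = classify(_fixed_output_model([0.5] * 10), np.zeros(2), accept_threshold=0.7)
        assert pred.decisions["saccharification"] == UNKNOWN

    def test_low_single_unit_means_l(self):
        acts = [0.9] * 10
        acts[9] = 0.1
        pred = classify(_fixed_output_model(acts), np.zeros(2))
        assert pred.decisions["saccharification"] == "L"

    def test_zero_threshold_never_unknown(self):
        pred = classify(_fixed_output_model([0.1] * 10), np.zeros(2), accept_threshold=0.0)
        assert UNKNOWN not in pred.decisions.values()

    def test_impossible_threshold_all_unknown(self):
        pred = classify(_fixed_output_model([0.9] * 10), np.zeros(2), accept_threshold=1.01)
        assert all(v == UNKNOWN for v in pred.decisions.values())


class TestClassificationStatistics:
    def _table(self, n=40):
        rng = np.random.default_rng(0)
        cls = np.arange(n) % 2
        return pd.DataFrame(
            {
                "f1": cls * 4.0 + rng.normal(0, 0.2, n),
                "f2": rng.normal(0, 1, n),
                "sample_id": cls + 1,
                "juice_content": np.where(cls == 0, 30, 40),
                "saccharification": np.where(cls == 0, "L", "H"),
            }
        )

    def test_always_unknown_model(self):
        # threshold above 0.5 so even the single-unit head can reject
        table = self._table()
        split = split_dataset(len(table), seed=0)
        stats = classification_statistics(
            _fixed_output_model([0.4] * 10), table, split, accept_threshold=0.7
        )
        assert (stats.table["correct"] == 0).all()
        assert (stats.table["wrong"] == 0).all()
        assert (stats.table["unknown"] == stats.table["total"]).all()

    def test_count_conservation(self, trained_small):
        t = trained_small.statistics.table
        assert (t["total"] == t["correct"] + t["wrong"] + t["unknown"]).all()
        # totals per subset match the split sizes for every task
        for task in ("sample_id", "juice_content", "saccharification"):
            sub = t[t["task"] == task]
            assert sub.groupby("subset")["total"].sum().to_dict() == {
                "training": len(trained_small.split.train),
                "validation": len(trained_small.split.validation),
                "test": len(trained_small.split.test),
            }

    def test_quality_and_accuracy_definitions(self, trained_small):
        t = trained_small.statistics.table
        sub = t[(t["task"] == "sample_id") & (t["subset"] == "training")]
        expected = sub["correct"].sum() / sub["total"].sum()
        assert trained_small.statistics.subset_quality("sample_id", "training") == pytest.approx(expected)


def test_end_to_end_seeded_reproducibility(small_table):
    a = train_and_evaluate(small_table, seed=11)
    b = train_and_evaluate(small_table, seed=11)
    pd.testing.assert_frame_equal(a.statistics.table, b.statistics.table)
    np.testing.assert_array_equal(a.model.get_params(), b.model.get_params())


def test_model_json_round_trip(tmp_path, trained_small):
    path = tmp_path / "model.json"
    trained_small.model.to_json(path)
    back = MLPModel.from_json(path)
    np.testing.assert_allclose(back.get_params(), trained_small.model.get_params())
    x = np.random.default_rng(0).normal(size=(3, 46)) * 10 + 100
    np.testing.assert_allclose(back.forward(x), trained_small.model.forward(x))


def test_toy_task_trains():
    model, table, y, split = make_toy_task(seed=0)
    x = table[["f1", "f2"]].to_numpy(float)
    assert model.rms(x[split.test], y[split.test]) < 0.25
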