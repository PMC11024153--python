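import math

import numpy as np
import pytest

from pgm_transfer import DataError, ModelConfig, TaskSpec, featurize
from pgm_transfer.model import (
    _forward,
    extractor_gradient,
    forward_loss,
    init_model,
    loss_and_gradients,
    make_batch,
)


def _zeroed(state):
    for name in state.params:
        state.params[name][:] = 0.0
    return state


class TestInit:
    def test_deterministic_given_seed(self, small_gin_config):
        a, b = init_model(small_gin_config), init_model(small_gin_config)
        assert a.params.keys() == b.params.keys()
        for name in a.params:
            assert np.array_equal(a.params[name], b.params[name])

    def test_extractor_identical_across_predictor_widths(self, small_gin_config):
        a = init_model(small_gin_config.with_predictor_out(1))
        b = init_model(small_gin_config.with_predictor_out(12))
        for name in a.extractor_names:
            assert np.array_equal(a.params[name], b.params[name])
        assert a.params["predictor.W"].shape != b.params["predictor.W"].shape

    def test_seed_changes_extractor(self, small_gin_config):
        from dataclasses import replace

        a = init_model(small_gin_config)
        b = init_model(replace(small_gin_config, init_seed=8))
        assert any(
            not np.array_equal(a.params[n], b.params[n]) for n in a.extractor_names
        )


class TestForwardLoss:
    def test_classification_loss_is_ln2_at_zero_logits(self, small_batch):
        task = TaskSpec("classification", 1)
        state = _zeroed(init_model(ModelConfig(encoder_depth=2, hidden_width=8)))
        assert forward_loss(state, small_batch, task) == pytest.approx(math.log(2), abs=1e-12)

    def test_regression_loss_zero_at_exact_prediction(self, small_gin_config):
        state = _zeroed(init_model(small_gin_config))
        graphs = [featurize("CCO"), featurize("c1ccccc1")]
        batch = make_batch(graphs, np.zeros((2, 1)), np.ones((2, 1), bool))
        assert forward_loss(state, batch, TaskSpec("regression", 1)) == 0.0

    def test_masked_batch_loss_matches_per_cell_oracle(self, small_gin_config):
        """Mean over observed cells only, recomputed cell by cell."""
        cfg = small_gin_config.with_predictor_out(2)
        state = init_model(cfg)
        graphs = [featurize("CCO"), featurize("c1ccncc1")]
        labels = np.array([[1.0, 0.0], [0.0, 1.0]])
        observed = np.array([[True, True], [True, False]])
        batch = make_batch(graphs, labels, observed)
        logits, _ = _forward(state, batch)
        cells = []
        for i in range(2):
            for j in range(2):
                if observed[i, j]:
                    z, y = logits[i, j], labels[i, j]
                    cells.append(max(z, 0) - z * y + math.log1p(math.exp(-abs(z))))
        expected = sum(cells) / len(cells)
        got = forward_loss(state, batch, TaskSpec("classification", 2))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariance_of_batch_loss(self, tiny_classification_dataset):
        records, task = tiny_classification_dataset
        state = init_model(ModelConfig(encoder_depth=2, hidden_width=8))
        graphs = [featurize(r) for r in records]
        labels = np.stack([r.labels for r in records])
        observed = np.stack([r.observed for r in records])
        perm = np.random.default_rng(0).permutation(len(records))
        a = forward_loss(state, make_batch(graphs, labels, observed), task)
        b = forward_loss(
            state,
            make_batch([graphs[i] for i in perm], labels[perm], observed[perm]),
            task,
        )
        assert abs(a - b) < 1e-6 * abs(a)

    def test_zero_observed_labels_signals_skip(self, small_gin_config):
        state = init_model(small_gin_config)
        batch = make_batch([featurize("CCO")], np.array([[0.0]]), np.array([[False]]))
        with pytest.raises(DataError):
            forward_loss(state, batch, TaskSpec("classification", 1))


class TestExtractorGradient:
    def test_length_invariant_to_predictor_width(self, small_gin_config, small_batch):
        g1 = extractor_gradient(
            init_model(small_gin_config.with_predictor_out(1)),
            small_batch, TaskSpec("classification", 1))
        state12 = init_model(small_gin_config.with_predictor_out(12))
        batch12 = make_batch(
            [featurize("CCO"), featurize("c1ccccc1")],
            np.ones((2, 12)), np.ones((2, 12), bool))
        g12 = extractor_gradient(state12, batch12, TaskSpec("classification", 12))
        assert g1.shape == g12.shape == (state12.extractor_size(),)

    @pytest.mark.parametrize("task_type", ["classification", "regression"])
    def test_matches_central_finite_differences(self, task_type):
        """Hand-derived backprop vs central differences on a small model."""
        cfg = ModelConfig(encoder_depth=1, hidden_width=4, init_seed=5)
        state = init_model(cfg)
        graphs = [featurize(s) for s in ("CCO", "c1ccncc1", "CC(=O)Cl")]
        labels = np.array([[1.0], [0.0], [1.0]])
        observed = np.ones((3, 1), bool)
        batch = make_batch(graphs, labels, observed)
        task = TaskSpec(task_type, 1)
        analytic = extractor_gradient(state, batch, task)
        h = 1e-6
        fd = np.empty_like(analytic)
        pos = 0
        for name in state.extractor_names:
            arr = state.params[name]
            flat = arr.ravel()
            for k in range(flat.size):
                orig = flat[k]
                flat[k] = orig + h
                lp = forward_loss(state, batch, task)
                flat[k] = orig - h
                lm = forward_loss(state, batch, task)
                flat[k] = orig
                fd[pos] = (lp - lm) / (2 * h)
                pos += 1
        assert np.allclose(analytic, fd, rtol=1e-4, atol=1e-7)

    def test_duplicating_molecules_leaves_mean_gradient_unchanged(self, small_gin_config):
        state = init_model(small_gin_config)
        graphs = [featurize("CCO"), featurize("c1ccccc1")]
        labels = np.array([[1.0], [0.0]])
        observed = np.ones((2, 1), bool)
        task = TaskSpec("classification", 1)
        g1 = extractor_gradient(state, make_batch(graphs, labels, observed), task)
        g2 = extractor_gradient(
            state,
            make_batch(graphs * 2, np.tile(labels, (2, 1)), np.tile(observed, (2, 1))),
            task,
        )
        assert np.allclose(g1, g2, atol=1e-14)

    def test_no_dead_parameters(self, small_gin_config, small_batch):
        state = init_model(small_gin_config)
        _, grads = loss_and_gradients(state, small_batch, TaskSpec("classification", 1))
        for name, g in grads.items():
            assert np.any(g != 0.0), f"parameter {name} received no gradient"

    def test_bag_encoder_gradient(self, bag_config, small_batch):
        state = init_model(bag_config)
        g = extractor_gradient(state, small_batch, TaskSpec("classification", 1))
        assert g.shape == (state.extractor_size(),)
        assert np.linalg.norm(g) > 0
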