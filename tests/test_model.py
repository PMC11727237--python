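"""Network primitives, masked loss, training contract, persistence."""

import math

import numpy as np
import pandas as pd
import pytest

from gdop.compounds import LabeledPair
from gdop.model import (
    EarlyStopping,
    GDOPResults,
    ModelConfig,
    _forward_batch,
    forward,
    init_model,
    masked_cross_entropy,
    sgcn_encode,
)
from gdop.pipeline import build_model, curate_directory
from gdop.ppi import GeneSpace, PPINetwork, PropagationOperator, propagation_operator

from test_ppi import random_network

TINY = ModelConfig(
    sgcn_channels=1,
    sgcn_order=0,
    dense_widths=(2,),
    dropout_rates=(0.0, 0.0),
    fingerprint_bits=2,
)


class TestConfig:
    def test_default_widths_and_dropout_pattern(self):
        cfg = ModelConfig()
        assert cfg.dense_widths == (4096, 3016, 2048, 1024)
        assert cfg.dropout_rates == (0.2, 0.5, 0.5, 0.5, 0.2)

    def test_dropout_list_must_cover_sgcn_layer(self):
        with pytest.raises(ValueError, match="dropout_rates"):
            ModelConfig(dropout_rates=(0.5, 0.5, 0.5, 0.2))

    @pytest.mark.parametrize("rates", [(0.2, 0.5, 0.5, 0.5, 1.0), (-0.1, 0, 0, 0, 0)])
    def test_dropout_rates_within_unit_interval(self, rates):
        with pytest.raises(ValueError):
            ModelConfig(dropout_rates=rates)


class TestInitModel:
    def test_default_architecture_shapes(self):
        cfg = ModelConfig()
        gs = GeneSpace([f"G{i}" for i in range(10)])
        params = init_model(cfg, gs, n_pathways=7, seed=0)
        d_in = 10 * cfg.sgcn_channels + cfg.fingerprint_bits
        assert params["W0"].shape == (d_in, 4096)
        assert params["W1"].shape == (4096, 3016)
        assert params["W2"].shape == (3016, 2048)
        assert params["W3"].shape == (2048, 1024)
        assert params["Wout"].shape == (1024, 7)

    def test_deterministic_under_seed(self):
        cfg = ModelConfig.small()
        a = init_model(cfg, 10, 5, seed=3)
        b = init_model(cfg, 10, 5, seed=3)
        c = init_model(cfg, 10, 5, seed=4)
        assert all(np.array_equal(a[k], b[k]) for k in a)
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_spectral_mixing_starts_at_identity_basis(self):
        params = init_model(ModelConfig.small(), 10, 5, seed=0)
        assert np.array_equal(params["sgcn_W"], np.array([[1.0, 0.0], [0.0, 1.0]]))


class TestSgcnEncode:
    def test_single_node_identity_weights_is_relu(self):
        op = PropagationOperator(np.array([[1.0]]))
        cfg = ModelConfig(
            sgcn_channels=1, sgcn_order=1,
            dense_widths=(2,), dropout_rates=(0.0, 0.0), fingerprint_bits=2,
        )
        params = init_model(cfg, 1, 2, seed=0)  # sgcn_W = [[1],[0]]
        assert sgcn_encode(params, np.array([2.5]), op, cfg) == pytest.approx([2.5])
        assert sgcn_encode(params, np.array([-2.5]), op, cfg) == pytest.approx([0.0])

    @pytest.mark.parametrize("n,order", [(5, 1), (15, 2), (20, 3)])
    def test_matches_dense_polynomial_filter(self, n, order):
        rng = np.random.default_rng(n + order)
        op = propagation_operator(random_network(rng, n))
        cfg = ModelConfig(
            sgcn_channels=3, sgcn_order=order,
            dense_widths=(4,), dropout_rates=(0.0, 0.0), fingerprint_bits=2,
        )
        params = init_model(cfg, n, 2, seed=1)
        params["sgcn_W"] = rng.normal(size=params["sgcn_W"].shape)
        params["sgcn_b"] = rng.normal(size=params["sgcn_b"].shape)
        x = rng.normal(size=n)
        # independent dense computation: sum_k (S^k x) W_k, then bias + ReLU
        s_pow = np.eye(n)
        acc = np.zeros((n, 3))
        for k in range(order + 1):
            acc += np.outer(s_pow @ x, params["sgcn_W"][k])
            s_pow = s_pow @ op.matrix
        expected = np.maximum(acc + params["sgcn_b"], 0.0).reshape(-1)
        got = sgcn_encode(params, x, op, cfg)
        assert np.allclose(got, expected, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        n, c = 12, 2
        op = propagation_operator(random_network(rng, n))
        cfg = ModelConfig(
            sgcn_channels=c, sgcn_order=1,
            dense_widths=(4,), dropout_rates=(0.0, 0.0), fingerprint_bits=2,
        )
        params = init_model(cfg, n, 2, seed=2)
        x = rng.normal(size=n)
        perm = rng.permutation(n)
        p = np.eye(n)[perm]
        op_perm = PropagationOperator(p @ op.matrix @ p.T)
        lat = sgcn_encode(params, x, op, cfg).reshape(n, c)
        lat_perm = sgcn_encode(params, p @ x, op_perm, cfg).reshape(n, c)
        assert np.allclose(lat_perm, p @ lat, atol=1e-12)


class TestForward:
    def test_zero_output_head_scores_half(self):
        params = init_model(TINY, 3, 4, seed=0)
        params["Wout"][:] = 0.0
        params["bout"][:] = 0.0
        scores = forward(params, np.ones(3), np.array([1.0, 0.0]), TINY)
        assert np.allclose(scores, 0.5)

    def test_inference_deterministic(self):
        cfg = ModelConfig(
            sgcn_channels=1, sgcn_order=0,
            dense_widths=(4, 3), dropout_rates=(0.2, 0.5, 0.5), fingerprint_bits=2,
        )
        params = init_model(cfg, 3, 4, seed=0)
        a = forward(params, np.ones(3), np.array([1.0, 0.0]), cfg, training=False)
        b = forward(params, np.ones(3), np.array([1.0, 0.0]), cfg, training=False)
        assert np.array_equal(a, b)

    def test_hand_computed_two_pathway_pass(self):
        # latent [1.5, 0], fp [1, 0]; dense pre-activations [0.9, -0.15];
        # logits by hand: [0.9, -0.7]
        params = {
            "sgcn_W": np.array([[1.0]]),
            "sgcn_b": np.array([0.5]),
            "W0": np.array([[0.2, -0.1], [0.3, 0.4], [0.5, 0.2], [0.1, 0.1]]),
            "b0": np.array([0.1, -0.2]),
            "Wout": np.array([[1.0, -1.0], [0.5, 0.5]]),
            "bout": np.array([0.0, 0.2]),
        }
        op = PropagationOperator(np.eye(2))
        latent = sgcn_encode(params, np.array([1.0, -2.0]), op, TINY)
        assert latent == pytest.approx([1.5, 0.0])
        scores = forward(params, latent, np.array([1.0, 0.0]), TINY)
        expected = [1 / (1 + math.exp(-0.9)), 1 / (1 + math.exp(0.7))]
        assert np.allclose(scores, expected, atol=1e-8)

    def test_batch_path_matches_single_path(self):
        rng = np.random.default_rng(0)
        n = 6
        op = propagation_operator(random_network(rng, n))
        cfg = ModelConfig(
            sgcn_channels=2, sgcn_order=1,
            dense_widths=(8, 4), dropout_rates=(0.2, 0.5, 0.5), fingerprint_bits=16,
        )
        params = init_model(cfg, n, 5, seed=1)
        x = rng.normal(size=n)
        fp = (rng.random(16) < 0.3).astype(float)
        single = forward(params, sgcn_encode(params, x, op, cfg), fp, cfg)
        phi = op.powers(x, cfg.sgcn_order)[None]
        logits, _ = _forward_batch(params, phi, fp[None], cfg, False, None)
        batch = 1 / (1 + np.exp(-logits[0]))
        assert np.allclose(single, batch, atol=1e-12)


class TestMaskedCrossEntropy:
    PAIRS = [
        LabeledPair("c1", "P0", True),
        LabeledPair("c1", "P1", False),
        LabeledPair("c2", "P2", True),
    ]
    INDEX = {"P0": 0, "P1": 1, "P2": 2}

    def test_uniform_half_scores_give_ln2(self):
        scores = {"c1": np.full(3, 0.5), "c2": np.full(3, 0.5)}
        loss = masked_cross_entropy(scores, self.PAIRS, self.INDEX)
        assert abs(loss - math.log(2)) <= 1e-9

    def test_unlabeled_perturbation_is_ignored(self):
        scores = {"c1": np.array([0.9, 0.1, 0.5]), "c2": np.array([0.5, 0.5, 0.8])}
        base = masked_cross_entropy(scores, self.PAIRS, self.INDEX)
        scores["c1"][2] = 0.999  # (c1, P2) carries no label
        scores["c2"][0] = 0.001  # (c2, P0) carries no label
        assert masked_cross_entropy(scores, self.PAIRS, self.INDEX) == base

    def test_confident_correct_scores_drive_loss_to_zero(self):
        eps = 1e-9
        scores = {
            "c1": np.array([1 - eps, eps, 0.5]),
            "c2": np.array([0.5, 0.5, 1 - eps]),
        }
        assert masked_cross_entropy(scores, self.PAIRS, self.INDEX) < 1e-8

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            masked_cross_entropy({}, [], {})


class TestEarlyStopping:
    def test_strictly_worsening_stops_after_patience(self):
        stopper = EarlyStopping(patience=3)
        stopper.update(1.0, epoch=1)
        for epoch, value in [(2, 1.1), (3, 1.2), (4, 1.3)]:
            stopper.update(value, epoch)
        assert stopper.should_stop
        assert stopper.best_epoch == 1
        assert stopper.best_value == 1.0

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        for epoch, value in [(1, 1.0), (2, 1.5), (3, 0.9), (4, 1.5)]:
            stopper.update(value, epoch)
        assert not stopper.should_stop
        assert stopper.best_epoch == 3


@pytest.fixture(scope="module")
def trained(small_bundle_module):
    gdop, results, truth = small_bundle_module
    return gdop, results


@pytest.fixture(scope="module")
def small_bundle_module(tmp_path_factory):
    from gdop import SyntheticConfig, make_fixture

    cfg = SyntheticConfig(
        n_genes=24, n_pathways=6, pathway_size_range=(3, 5), n_compounds=40, seed=11
    )
    bundle = make_fixture(cfg, tmp_path_factory.mktemp("train_bundle"))
    ds = curate_directory(bundle.pathways.parent)
    fast = ModelConfig(
        sgcn_channels=2,
        dense_widths=(16, 12, 8, 8),
        dropout_rates=(0.2, 0.5, 0.5, 0.5, 0.2),
        learning_rate=3e-3,
        max_epochs=12,
        patience=4,
        batch_size=16,
        fingerprint_bits=256,
    )
    gdop = build_model(ds, config=fast, seed=5)
    results = gdop.fit(seed=5)
    return gdop, results, bundle.load_truth()


class TestTraining:
    def test_history_and_weights_reproducible(self, small_bundle_module):
        gdop, results, _ = small_bundle_module
        again = gdop.fit(seed=5)
        pd.testing.assert_frame_equal(results.history, again.history)
        assert all(
            np.array_equal(results.params[k], again.params[k]) for k in results.params
        )

    def test_returns_best_validation_checkpoint(self, small_bundle_module):
        gdop, results, _ = small_bundle_module
        hist = results.history
        assert results.best_epoch == int(hist.loc[hist.val_loss.idxmin(), "epoch"])
        assert results.best_val_loss == pytest.approx(hist.val_loss.min())
        # the stored weights reproduce exactly the best validation loss
        assert gdop._loss_on(results.params, gdop.val_rows) == pytest.approx(
            results.best_val_loss
        )

    def test_validation_loss_improves_from_start(self, small_bundle_module):
        _, results, _ = small_bundle_module
        assert results.best_val_loss < results.history.val_loss.iloc[0]

    def test_checkpoint_reload_is_bit_identical(self, small_bundle_module, tmp_path):
        gdop, results, _ = small_bundle_module
        ckpt = tmp_path / "model.npz"
        results.save(ckpt)
        reloaded = GDOPResults.load(ckpt)
        compound = gdop.compounds[0]
        a = results.predict_rank(compound)
        b = reloaded.predict_rank(compound)
        assert a.pathway_ids == b.pathway_ids
        assert np.array_equal(a.scores, b.scores)

    def test_reloaded_checkpoint_cannot_evaluate(self, small_bundle_module, tmp_path):
        _, results, _ = small_bundle_module
        ckpt = tmp_path / "model2.npz"
        results.save(ckpt)
        with pytest.raises(ValueError, match="reloaded checkpoint"):
            GDOPResults.load(ckpt).top_n_report("test")

    def test_summary_mentions_architecture_and_fit(self, small_bundle_module):
        _, results, _ = small_bundle_module
        text = results.summary()
        assert "dense widths" in text
        assert "best validation loss" in text
        assert "top-N" in text

    def test_rankings_cover_every_pathway_once(self, small_bundle_module):
        gdop, results, _ = small_bundle_module
        for ranking in results.rankings("test"):
            assert sorted(ranking.pathway_ids) == sorted(gdop.pathways.ids)
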