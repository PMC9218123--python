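"""Loss closed forms, decomposition, optimisation behaviour."""

import math

import numpy as np
import pytest

from sndm.model import (BetaValue, DensityOutputs, ModelConfig, SideLogits,
                        build_model)
from sndm.nn import autograd as ag
from sndm.nn.autograd import Tensor
from sndm.nn.optim import Adam
from sndm.training import (LossBreakdown, TrainConfig, bce_map_loss,
                           total_loss, train)


def _outputs_from_maps(maps, beta=1.0):
    return DensityOutputs(maps=list(maps),
                          logits=SideLogits(maps=[], fused=maps[0]),
                          beta=BetaValue(beta=beta),
                          predicted_count=float(maps[0].sum()))


class TestBceMapLoss:
    def test_all_half_two_by_two_closed_form(self):
        P = np.full((2, 2), 0.5)
        assert bce_map_loss(P, P) == pytest.approx(4 * math.log(2), abs=1e-9)

    def test_single_pixel_closed_form(self):
        assert bce_map_loss(np.array([[0.8]]), np.array([[1.0]])) == \
            pytest.approx(-math.log(0.8), abs=1e-9)

    def test_loss_vanishes_at_binary_target(self):
        P_G = np.array([[1.0, 0.0], [0.0, 1.0]])
        P = np.clip(P_G, 1e-12, 1 - 1e-12)
        assert bce_map_loss(P, P_G) < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            bce_map_loss(np.full((2, 2), 0.5), np.full((3, 3), 0.5))

    def test_degenerate_probabilities_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            bce_map_loss(np.array([[1.0]]), np.array([[1.0]]))


class TestTotalLoss:
    def test_seven_identical_maps_structure(self, rng):
        view = np.clip(rng.random((6, 6)), 1e-6, 1 - 1e-6)
        P = np.full((6, 6), 0.3)
        out = _outputs_from_maps([P] * 7, beta=0.8)
        lb = total_loss(out, view, 0.8)
        single = bce_map_loss(P, view)
        assert len(lb.per_map_bce) == 7
        assert lb.total == pytest.approx(7 * single + 0.5 * 0.2 ** 2)

    def test_beta_one_zero_penalty(self, rng):
        view = np.clip(rng.random((4, 4)), 1e-6, 1 - 1e-6)
        out = _outputs_from_maps([np.full((4, 4), 0.4)] * 3, beta=1.0)
        assert total_loss(out, view, 1.0).penalty == 0.0

    def test_penalty_closed_form_batch_of_one(self):
        view = np.full((2, 2), 1e-6)
        out = _outputs_from_maps([np.full((2, 2), 0.2)], beta=0.9)
        assert total_loss(out, view, 0.9).penalty == pytest.approx(0.005)

    def test_batch_sums_over_images(self, rng):
        views = [np.clip(rng.random((3, 3)), 1e-6, 1 - 1e-6) for _ in range(2)]
        outs = [_outputs_from_maps([np.full((3, 3), p)] * 2, beta=b)
                for p, b in ((0.3, 0.9), (0.6, 1.1))]
        lb = total_loss(outs, views, [0.9, 1.1])
        assert lb.penalty == pytest.approx(0.5 * 0.01 + 0.5 * 0.01)
        assert lb.total == pytest.approx(sum(lb.per_map_bce) + lb.penalty)

    def test_decomposition_invariant_enforced(self):
        with pytest.raises(ValueError, match="total"):
            LossBreakdown(per_map_bce=[1.0, 2.0], penalty=0.5, total=4.0)


class TestTrainConfig:
    def test_defaults_match_training_protocol(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.0001
        assert cfg.weight_decay == 0.0005
        assert cfg.batch_size == 2

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(early_stopping_metric="accuracy")


class TestTrainLoop:
    def test_sanity_descent_on_small_set(self, tiny_splits, tiny_model_config):
        model = build_model(tiny_model_config)
        result = train(model, tiny_splits["train"], tiny_splits["val"],
                       TrainConfig(max_epochs=5, patience=5,
                                   learning_rate=2e-3, seed=1))
        h = result.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]
        assert set(h.columns) >= {"epoch", "train_loss", "val_loss",
                                  "val_count_mae", "mean_beta"}

    def test_dm_mode_beta_column_is_one(self, tiny_splits):
        cfg = ModelConfig(mode="dm", input_size=48, n_stages=3,
                          base_channels=4, seed=2)
        result = train(build_model(cfg), tiny_splits["train"],
                       tiny_splits["val"],
                       TrainConfig(max_epochs=2, patience=2, seed=1))
        assert (result.history["mean_beta"] == 1.0).all()

    def test_early_stopping_returns_best_checkpoint(self, tiny_splits):
        cfg = ModelConfig(mode="sndm", input_size=48, n_stages=2,
                          base_channels=4, seed=4)
        model = build_model(cfg)
        tcfg = TrainConfig(max_epochs=12, patience=2, learning_rate=5e-3,
                           seed=2)
        result = train(model, tiny_splits["train"], tiny_splits["val"], tcfg)
        h = result.history
        assert result.best_epoch == int(h["val_count_mae"].idxmin())
        if len(h) < tcfg.max_epochs:   # stopped early: patience exhausted
            tail = h["val_count_mae"].iloc[result.best_epoch + 1:]
            assert len(tail) == tcfg.patience
            assert (tail >= h["val_count_mae"].min()).all()
        # the returned model reproduces the best recorded validation MAE
        from sndm.training import predict_counts
        counts = predict_counts(model, tiny_splits["val"])
        mae_now = float(np.abs(counts - tiny_splits["val"].counts).mean())
        assert mae_now == pytest.approx(result.best_metric, rel=1e-5)

    def test_divergent_loss_aborts(self, tiny_splits, tiny_model_config):
        model = build_model(tiny_model_config)
        poisoned = tiny_splits["train"].subset(range(4))
        poisoned.images = poisoned.images.copy()
        poisoned.images[0] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            train(model, poisoned, tiny_splits["val"],
                  TrainConfig(max_epochs=1, seed=0))

    def test_empty_dataset_rejected(self, tiny_splits, tiny_model_config):
        model = build_model(tiny_model_config)
        with pytest.raises(ValueError):
            train(model, tiny_splits["train"].subset([]), tiny_splits["val"],
                  TrainConfig(max_epochs=1))


class TestEndToEndOverfit:
    def test_miniature_overfits_sixteen_scenes_below_unit_mae(self):
        """The whole pipeline (scenes -> targets -> network -> counts) can
        drive count error below one colony when overfitting 16 dishes."""
        from sndm.data import generate_scene_set
        from sndm.synth import SceneParams, TruncatedExponentialCounts
        params = SceneParams(
            image_size=96, seed=42,
            count_distribution=TruncatedExponentialCounts(max_count=60, mean=15))
        ds = generate_scene_set(16, params, output_stride=2)
        model = build_model(ModelConfig(mode="sndm", input_size=96,
                                        output_stride=2, base_channels=8,
                                        dropout_rate=0.0, seed=1))
        result = train(model, ds, ds,
                       TrainConfig(max_epochs=130, patience=130,
                                   learning_rate=2e-3, weight_decay=0.0,
                                   seed=0))
        assert result.history["val_count_mae"].min() < 1.0
        assert result.best_metric < 1.0


class TestPenaltyGradient:
    def test_beta_head_converges_to_one_under_penalty_only(self, rng):
        # freeze the trunk: optimise the head alone on fixed features
        model = build_model(ModelConfig(mode="sndm", input_size=32,
                                        n_stages=2, base_channels=4, seed=0))
        feats = Tensor(rng.normal(size=(4, 4, 4, 8)).astype(np.float32))
        head = model.head
        # perturb the head so beta starts away from 1
        head.fc2.b.data = np.full(1, 2.5, dtype=np.float32)
        opt = Adam(head.parameters(), lr=1e-2)
        for _ in range(300):
            beta = head(feats)
            ones = Tensor(np.ones_like(beta.data))
            loss = ag.mul(Tensor(np.float32(0.5)),
                          ag.sum_all(ag.pow_const(ag.sub(ones, beta), 2.0)))
            opt.zero_grad()
            loss.backward()
            opt.step()
        final = head(feats).data
        assert np.allclose(final, 1.0, atol=0.05)
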