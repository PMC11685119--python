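"""Gradient reversal, adversarial objective, and the training loop."""

import numpy as np
import pytest

from eegdann.autograd import Tensor, gradient_reversal
from eegdann.dann import (
    DannModel,
    TrainConfig,
    lambda_schedule,
    make_rng_streams,
    predict,
    total_loss,
    train,
)
from eegdann.dataset import Normalizer
from eegdann.nn import Linear
from eegdann.satfem import GatBranchConfig, ResNetBranchConfig

from tests.conftest import make_random_dataset

SMALL_GAT = GatBranchConfig(hidden_dims=(8,))
SMALL_RESNET = ResNetBranchConfig(conv1_out=4, stage_widths=(4, 8, 8, 8))


def small_model(rngs, n_classes=3, use_dann=True, dropout=0.0,
                use_activity=True, use_topology=True):
    return DannModel(
        n_classes=n_classes, rng_streams=rngs, gat_cfg=SMALL_GAT,
        resnet_cfg=SMALL_RESNET, use_dann=use_dann, dropout=dropout,
        use_activity=use_activity, use_topology=use_topology,
    )


class TestGradientReversal:
    def test_forward_is_identity(self):
        x = np.linspace(-3, 3, 11)
        for lam in (0.0, 0.5, 1.0, 2.0):
            np.testing.assert_array_equal(
                gradient_reversal(Tensor(x), lam).data, x
            )

    def test_chain_rule_sign_flip(self):
        # f(R_1(x)) with f(u)=u^2 at x=3: df/dx = -6
        x = Tensor(np.array([3.0]), True)
        (gradient_reversal(x, 1.0) ** 2).sum().backward()
        np.testing.assert_allclose(x.grad, [-6.0])

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_scaled_negative_of_control_gradient_small_net(self, lam):
        """Through a small MLP, grad with GRL equals -lam times the grad
        without it, and matches central finite differences at 1e-4."""
        rng = np.random.default_rng(0)
        lin1 = Linear(4, 5, rng)
        lin2 = Linear(5, 2, rng)
        x0 = rng.standard_normal((3, 4))
        labels = np.array([0, 1, 0])

        def loss_through(x_arr, with_grl):
            t = Tensor(x_arr, True)
            h = t
            if with_grl:
                h = gradient_reversal(h, lam)
            out = lin2(lin1(h).relu()).cross_entropy(labels)
            return t, out

        t_grl, loss_grl = loss_through(x0, True)
        loss_grl.backward()
        t_ctl, loss_ctl = loss_through(x0, False)
        loss_ctl.backward()
        np.testing.assert_allclose(t_grl.grad, -lam * t_ctl.grad, atol=1e-12)

        eps = 1e-5
        fd = np.zeros_like(x0)
        for idx in np.ndindex(*x0.shape):
            xp = x0.copy(); xp[idx] += eps
            xm = x0.copy(); xm[idx] -= eps
            fd[idx] = (float(loss_through(xp, False)[1].data)
                       - float(loss_through(xm, False)[1].data)) / (2 * eps)
        np.testing.assert_allclose(t_grl.grad, -lam * fd, atol=1e-4)


class TestForwardContract:
    def test_heads_on_probability_simplex(self, adjacency):
        rngs = make_rng_streams(1)
        model = small_model(rngs)
        model.eval()
        rng = np.random.default_rng(2)
        _, y, d = model(rng.standard_normal((4, 5, 9, 9)),
                        rng.standard_normal((4, 62, 5)), adjacency, lam=0.7)
        np.testing.assert_allclose(y.data.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(d.data.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weight_heads_uniform(self, adjacency):
        rngs = make_rng_streams(3)
        model = small_model(rngs)
        model.eval()
        model.emotion_head.weight.data[...] = 0
        model.emotion_head.bias.data[...] = 0
        model.domain_fc2.weight.data[...] = 0
        model.domain_fc2.bias.data[...] = 0
        rng = np.random.default_rng(4)
        _, y, d = model(rng.standard_normal((3, 5, 9, 9)),
                        rng.standard_normal((3, 62, 5)), adjacency, lam=1.0)
        np.testing.assert_allclose(y.data, 1 / 3, atol=1e-12)
        np.testing.assert_allclose(d.data, 1 / 2, atol=1e-12)

    def test_lambda_does_not_change_forward_values(self, adjacency):
        rngs = make_rng_streams(5)
        model = small_model(rngs)
        model.eval()
        rng = np.random.default_rng(6)
        maps = rng.standard_normal((2, 5, 9, 9))
        nodes = rng.standard_normal((2, 62, 5))
        h0, y0, d0 = model(maps, nodes, adjacency, lam=0.0)
        h1, y1, d1 = model(maps, nodes, adjacency, lam=1.0)
        np.testing.assert_array_equal(h0.data, h1.data)
        np.testing.assert_array_equal(y0.data, y1.data)
        np.testing.assert_array_equal(d0.data, d1.data)


class TestTotalLoss:
    def _batches(self, adjacency, seed=7, n=6):
        rng = np.random.default_rng(seed)
        source = (rng.standard_normal((n, 5, 9, 9)),
                  rng.standard_normal((n, 62, 5)),
                  rng.integers(0, 3, n))
        target = (rng.standard_normal((n, 5, 9, 9)),
                  rng.standard_normal((n, 62, 5)))
        return source, target

    def test_lambda_zero_total_equals_emotion(self, adjacency):
        model = small_model(make_rng_streams(8))
        model.eval()
        source, target = self._batches(adjacency)
        lb = total_loss(model, source, target, adjacency, lam=0.0)
        assert lb.e_total == lb.l_emotion
        assert lb.l_domain > 0

    def test_objective_decomposition(self, adjacency):
        model = small_model(make_rng_streams(9))
        model.eval()
        source, target = self._batches(adjacency)
        lam = 0.6
        lb = total_loss(model, source, target, adjacency, lam=lam)
        assert lb.e_total == pytest.approx(lb.l_emotion - lam * lb.l_domain)

    def test_hand_computed_cross_entropies(self, adjacency):
        """2-sample batch with forced probabilities matches -mean log p."""
        model = small_model(make_rng_streams(10))
        model.eval()
        source, target = self._batches(adjacency, n=2)
        # force known emotion logits by zeroing the extractor contribution
        model.emotion_head.weight.data[...] = 0
        model.emotion_head.bias.data[...] = np.log([0.7, 0.2, 0.1])
        model.domain_fc1.weight.data[...] = 0
        model.domain_fc1.bias.data[...] = 0
        model.domain_fc2.weight.data[...] = 0
        model.domain_fc2.bias.data[...] = np.log([0.9, 0.1])
        s_maps, s_nodes, _ = source
        lb = total_loss(model, (s_maps, s_nodes, np.array([0, 1])), target,
                        adjacency, lam=1.0)
        assert lb.l_emotion == pytest.approx(-(np.log(0.7) + np.log(0.2)) / 2)
        # domain: sources predicted 0.9 on label 0, targets 0.1 on label 1
        assert lb.l_domain == pytest.approx(
            0.5 * (-np.log(0.9)) + 0.5 * (-np.log(0.1))
        )

    def test_target_emotion_labels_rejected(self, adjacency):
        model = small_model(make_rng_streams(11))
        source, target = self._batches(adjacency)
        with pytest.raises(ValueError, match="must not carry"):
            total_loss(model, source, target, adjacency, 0.5,
                       target_labels=np.array([0]))


class TestLambdaSchedule:
    def test_ramp_endpoints_and_constant(self):
        cfg = TrainConfig(lambda_mode="ramp", lambda_value=1.0)
        assert lambda_schedule(cfg, 0.0) == pytest.approx(0.0)
        assert lambda_schedule(cfg, 1.0) == pytest.approx(
            2 / (1 + np.exp(-10)) - 1
        )
        const = TrainConfig(lambda_mode="constant", lambda_value=0.3)
        assert lambda_schedule(const, 0.5) == 0.3
        off = TrainConfig(use_dann=False)
        assert lambda_schedule(off, 1.0) == 0.0


class TestTraining:
    def test_seeded_rerun_is_bitwise_identical(self, layout, adjacency):
        data = make_random_dataset(layout, adjacency, n_subjects=2,
                                   windows_per_subject=6, seed=1)
        source = data.split_by_subjects(["S00"])
        target = data.split_by_subjects(["S01"])
        cfg = TrainConfig(epochs=1, batch=8, dropout=0.5, seed=42)
        histories = []
        for _ in range(2):
            rngs = make_rng_streams(cfg.seed)
            model = small_model(rngs, dropout=0.5)
            _, hist = train(model, source, target, cfg, rng_streams=rngs)
            histories.append(hist)
        assert histories[0] == histories[1]

    def test_separable_source_reaches_full_accuracy(self, layout, adjacency):
        """Strong linear class signal, no domain shift, no adversary:
        source accuracy hits 1.0 within 50 epochs."""
        data = make_random_dataset(layout, adjacency, n_subjects=1,
                                   windows_per_subject=24, seed=2,
                                   class_shift=3.0)
        cfg = TrainConfig(epochs=50, batch=8, dropout=0.0, seed=0,
                          use_dann=False, lr=1e-3)
        rngs = make_rng_streams(cfg.seed)
        model = small_model(rngs, use_dann=False)
        model, hist = train(model, data, None, cfg, rng_streams=rngs,
                            eval_each_epoch=False)
        pred = predict(model, data, Normalizer.fit(data.de))
        assert (pred == data.labels).mean() == 1.0

    def test_lambda_zero_grl_equals_supervised_control(self, layout, adjacency):
        """grl_joint with constant lambda=0 reproduces the no-adversary
        control's per-step emotion losses exactly (same seed)."""
        data = make_random_dataset(layout, adjacency, n_subjects=2,
                                   windows_per_subject=8, seed=3)
        source = data.split_by_subjects(["S00"])
        target = data.split_by_subjects(["S01"])
        norm = Normalizer.fit(source.de)

        cfg_dann = TrainConfig(epochs=3, batch=8, dropout=0.7, seed=11,
                               lambda_mode="constant", lambda_value=0.0)
        rngs = make_rng_streams(cfg_dann.seed)
        m1 = small_model(rngs, dropout=0.7)
        _, hist_dann = train(m1, source, target, cfg_dann, normalizer=norm,
                             rng_streams=rngs, eval_each_epoch=False)

        cfg_ctl = TrainConfig(epochs=3, batch=8, dropout=0.7, seed=11,
                              use_dann=False)
        rngs2 = make_rng_streams(cfg_ctl.seed)
        m2 = small_model(rngs2, use_dann=False, dropout=0.7)
        _, hist_ctl = train(m2, source, None, cfg_ctl, normalizer=norm,
                            rng_streams=rngs2, eval_each_epoch=False)

        for a, b in zip(hist_dann, hist_ctl):
            assert a["l_emotion"] == b["l_emotion"]

    def test_alternating_mode_runs_and_learns(self, layout, adjacency):
        data = make_random_dataset(layout, adjacency, n_subjects=2,
                                   windows_per_subject=12, seed=4,
                                   class_shift=3.0)
        source = data.split_by_subjects(["S00"])
        target = data.split_by_subjects(["S01"])
        cfg = TrainConfig(epochs=10, batch=8, dropout=0.0, seed=5,
                          mode="alternating", lr=1e-3)
        rngs = make_rng_streams(cfg.seed)
        model = small_model(rngs)
        model, hist = train(model, source, target, cfg, rng_streams=rngs,
                            eval_each_epoch=False)
        assert hist[-1]["l_emotion"] < hist[0]["l_emotion"]

    def test_empty_domain_rejected(self, layout, adjacency):
        data = make_random_dataset(layout, adjacency, n_subjects=1,
                                   windows_per_subject=4, seed=6)
        empty = data.subset(np.zeros(len(data), dtype=bool))
        cfg = TrainConfig(epochs=1, batch=4, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(small_model(make_rng_streams(0)), empty, data, cfg)
        with pytest.raises(ValueError, match="empty"):
            train(small_model(make_rng_streams(0)), data, empty, cfg)

    def test_even_batch_required(self):
        with pytest.raises(ValueError, match="even"):
            TrainConfig(batch=7)
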