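import numpy as np
import pytest

from dbtpre import (adversarial_loss, cycle_consistency_loss,
                    iterations_per_epoch, mse, select_optimal_epoch,
                    ssim_fidelity_loss)
from dbtpre.losses import t_l1, t_lsgan, t_ssim_loss
from dbtpre.nn import Tensor
from dbtpre.nn.networks import DiscriminatorSpec, GeneratorSpec
from dbtpre.train import (LossWeights, OptimizerConfig, build_models,
                          load_checkpoint, save_checkpoint, train,
                          validation_mse)


class TestMSE:
    def test_identical_is_zero(self, rng):
        x = rng.random((8, 8))
        assert mse(x, x) == 0.0

    def test_unit_offset(self):
        assert mse(np.zeros(2), np.ones(2)) == pytest.approx(1.0)

    def test_loop_oracle(self, rng):
        a, b = rng.random((5, 7)), rng.random((5, 7))
        oracle = sum((a[i, j] - b[i, j]) ** 2 for i in range(5)
                     for j in range(7)) / 35
        assert mse(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros(3), np.zeros(4))


class TestSSIMFidelity:
    def test_identical_is_zero(self, rng):
        x = rng.random((32, 32))
        assert ssim_fidelity_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_exceeds_one(self, rng):
        # closed-form global-statistics SSIM: zero-mean a vs -a has unit
        # luminance and structure term near -1, so 1 - SSIM > 1
        a = rng.normal(size=(1, 32, 32))
        a -= a.mean()
        loss = float(t_ssim_loss(Tensor(a), Tensor(-a),
                                 data_range=2 * np.abs(a).max()).data)
        assert loss > 1.0

    def test_symmetric(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert ssim_fidelity_loss(a, b) == pytest.approx(
            ssim_fidelity_loss(b, a), abs=1e-12)

    def test_differentiable_version_agrees_at_identity(self, rng):
        a = rng.random((2, 16, 16))
        assert float(t_ssim_loss(Tensor(a), Tensor(a)).data) == pytest.approx(
            0.0, abs=1e-12)


class TestCycleLoss:
    def test_identity_and_offset(self, rng):
        x = rng.random((4, 8, 8))
        assert cycle_consistency_loss(x, x) == 0.0
        assert cycle_consistency_loss(x, x + 1.0) == pytest.approx(1.0)

    def test_loop_oracle(self, rng):
        a, b = rng.random((3, 4)), rng.random((3, 4))
        oracle = np.mean([abs(a[i, j] - b[i, j]) for i in range(3)
                          for j in range(4)])
        assert cycle_consistency_loss(a, b) == pytest.approx(oracle, abs=1e-12)
        assert float(t_l1(Tensor(a), Tensor(b)).data) == pytest.approx(oracle)


class TestAdversarialLoss:
    def test_closed_form(self):
        assert adversarial_loss(np.ones((3, 3)), True) == 0.0
        assert adversarial_loss(np.zeros((3, 3)), True) == pytest.approx(1.0)
        assert adversarial_loss(np.zeros((3, 3)), False) == 0.0

    def test_mixed_map_loop_oracle(self, rng):
        s = rng.normal(size=(4, 5))
        oracle = np.mean([(s[i, j] - 1.0) ** 2 for i in range(4)
                          for j in range(5)])
        assert adversarial_loss(s, True) == pytest.approx(oracle, abs=1e-12)
        assert float(t_lsgan(Tensor(s), True).data) == pytest.approx(oracle)


class TestEpochSelection:
    @pytest.mark.parametrize("curve,expected", [
        ([0.5], 1),
        ([3, 1, 2], 2),
        ([2, 1, 1], 2),  # earliest tie
    ])
    def test_rules(self, curve, expected):
        assert select_optimal_epoch(curve) == expected

    def test_argmin_oracle(self, rng):
        curve = rng.random(50).tolist()
        assert select_optimal_epoch(curve) == int(np.argmin(curve)) + 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_optimal_epoch([])


class TestConfigs:
    def test_iterations_per_epoch(self):
        assert iterations_per_epoch(86_400, 16) == 5_400
        assert iterations_per_epoch(100, 16) == 6

    def test_loss_weights_validation(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0)
        with pytest.raises(ValueError):
            LossWeights(-1, 1, 1)

    def test_optimizer_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(gradient_decay=1.5)


GEN = GeneratorSpec(kind="rSEAG", depth=1, base_channels=4)
DISC = DiscriminatorSpec(base_channels=4, n_layers=2)


def _toy_pools(rng, n=48, size=16):
    base = rng.normal(1.5, 0.1, size=(n, size, size))
    ref = base + rng.normal(0, 0.01, base.shape)
    obj = base + rng.normal(0, 0.08, base.shape)
    return ref, obj


class TestTraining:
    def test_smoke_run_records_curves(self, rng):
        ref, obj = _toy_pools(rng)
        state, models = train(ref, obj, GEN, DISC,
                              opt=OptimizerConfig(minibatch=8),
                              n_epochs=2, seed=0)
        for curve in state.loss_curves.values():
            assert len(curve) == 2
            assert all(v >= 0 for v in curve)
        assert len(state.val_mse) == 2

    def test_deterministic_given_seed(self, rng):
        ref, obj = _toy_pools(rng, n=24)
        run = lambda: train(ref, obj, GEN, DISC,
                            opt=OptimizerConfig(minibatch=8),
                            n_epochs=1, seed=7)[0]
        assert run().loss_curves == run().loss_curves

    def test_checkpoint_reload_reproduces_validation_mse(self, tmp_path, rng):
        ref, obj = _toy_pools(rng, n=24)
        state, models = train(ref, obj, GEN, DISC,
                              opt=OptimizerConfig(minibatch=8),
                              n_epochs=1, seed=3,
                              checkpoint_dir=tmp_path)
        fresh = build_models(GEN, DISC, seed=99)
        load_checkpoint(tmp_path / "epoch_001.npz", fresh)
        val = obj[-2:]
        assert validation_mse(fresh["G_or"], val) == validation_mse(
            models["G_or"], val)

    def test_cycle_only_training_reduces_cycle_loss(self, rng):
        ref, obj = _toy_pools(rng, n=32)
        state, _ = train(ref, obj, GEN, DISC,
                         weights=LossWeights(0.0, 10.0, 0.0),
                         opt=OptimizerConfig(learning_rate=5e-4, minibatch=8),
                         n_epochs=3, seed=1)
        cyc = state.loss_curves["cycle"]
        assert cyc[-1] < cyc[0]

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            train(np.zeros((0, 8, 8)), np.zeros((4, 8, 8)), GEN, DISC)
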