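"""Error-correction network: input encoding, prediction, training."""

import numpy as np
import pytest

from ecmri import (ComplexImage, Dataset, ECNetConfig, ECNetwork, TrainConfig,
                   ZeroFilledGuide, ec_input, predict_residual, train_ec,
                   undersample, zero_fill)
from ecmri.ecnet import desk_config, reference_train_config
from ecmri.nn import channels_to_complex, mse_loss
from .conftest import random_complex


@pytest.fixture()
def zf_and_guide(phantom64, mask64_cart30):
    y = undersample(phantom64, mask64_cart30)
    return zero_fill(y), ZeroFilledGuide().reconstruct(y)


class TestECInput:
    def test_channel_order_fixed(self, rng):
        zf = ComplexImage(random_complex(rng, (16, 16)))
        guide = ComplexImage(random_complex(rng, (16, 16)))
        x = ec_input(zf, guide)
        assert x.shape == (16, 16, 4)
        np.testing.assert_allclose(x[..., 0], zf.data.real, atol=1e-6)
        np.testing.assert_allclose(x[..., 1], zf.data.imag, atol=1e-6)
        np.testing.assert_allclose(x[..., 2], guide.data.real, atol=1e-6)
        np.testing.assert_allclose(x[..., 3], guide.data.imag, atol=1e-6)

    def test_real_inputs_zero_imaginary_channels(self):
        zf = ComplexImage(np.ones((16, 16), complex))
        x = ec_input(zf, zf)
        assert np.all(x[..., 1] == 0) and np.all(x[..., 3] == 0)
        assert np.all(x[..., 0] == 1) and np.all(x[..., 2] == 1)

    def test_round_trip_to_complex(self, rng):
        zf = ComplexImage(random_complex(rng, (8, 8)))
        guide = ComplexImage(random_complex(rng, (8, 8)))
        x = ec_input(zf, guide)
        np.testing.assert_allclose(channels_to_complex(x[..., :2]), zf.data, atol=1e-6)
        np.testing.assert_allclose(channels_to_complex(x[..., 2:]), guide.data, atol=1e-6)

    def test_permuting_channels_changes_output(self, rng):
        ecn = ECNetwork.fresh(ECNetConfig(n_layers=3, feature_maps=6), seed=2)
        # give the output path nonzero weights so the net is not the zero map
        for p in ecn.net.params:
            if not p.any():
                p[...] = 0.01
        zf = ComplexImage(random_complex(rng, (16, 16)))
        guide = ComplexImage(random_complex(rng, (16, 16)))
        a = ecn.net(ec_input(zf, guide)[None])
        b = ecn.net(ec_input(guide, zf)[None])
        assert np.max(np.abs(a - b)) > 1e-6

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ec_input(ComplexImage(random_complex(rng, (8, 8))),
                     ComplexImage(random_complex(rng, (16, 16))))


class TestPredict:
    def test_zero_network_predicts_zero_residual(self, zf_and_guide):
        zf, guide = zf_and_guide
        ecn = ECNetwork.zero(desk_config())
        res = predict_residual(ecn, zf, guide)
        assert np.all(res.data == 0)

    @pytest.mark.parametrize("shape", [(32, 32), (33, 47)])
    def test_output_shape_matches_input(self, rng, shape):
        ecn = ECNetwork.fresh(ECNetConfig(n_layers=3, feature_maps=4), seed=0)
        zf = ComplexImage(random_complex(rng, shape))
        res = predict_residual(ecn, zf, zf)
        assert res.shape == shape

    def test_provenance_mismatch_warns(self, zf_and_guide):
        zf, guide = zf_and_guide
        ecn = ECNetwork.zero(desk_config(), guide_name="sparse_tv")
        ecn.guide_name = "sparse_tv"
        with pytest.warns(UserWarning, match="trained with guide"):
            predict_residual(ecn, zf, guide, guide_name="zero_filled")

    def test_reference_architecture_defaults(self):
        cfg = ECNetConfig()
        assert (cfg.n_layers, cfg.feature_maps, cfg.ksize) == (18, 64, 3)
        assert (cfg.in_channels, cfg.out_channels) == (4, 2)

    def test_reference_training_defaults_recorded(self):
        tc = reference_train_config()
        assert (tc.iterations, tc.batch_size, tc.learning_rate) == (40000, 4, 1e-4)
        assert (tc.beta1, tc.beta2, tc.weight_decay) == (0.9, 0.99, 5e-4)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_net(self):
        return ECNetConfig(n_layers=3, feature_maps=8)

    def test_residual_target_identity(self, phantom64, mask64_cart30):
        # training labels satisfy x_true == guide + target by construction
        y = undersample(phantom64, mask64_cart30)
        guide = ZeroFilledGuide().reconstruct(y)
        target = phantom64.data - guide.data
        np.testing.assert_allclose(guide.data + target, phantom64.data, atol=1e-14)

    def test_overfit_single_sample(self, phantom64, mask64_cart30, tiny_net):
        ds = Dataset(train=[phantom64], val=[], test=[], seed=0)
        ecn = train_ec(ds, ZeroFilledGuide(), mask64_cart30,
                       ECNetConfig(n_layers=4, feature_maps=16),
                       TrainConfig(iterations=1000, batch_size=1, learning_rate=3e-3,
                                   weight_decay=0.0, seed=1))
        y = undersample(phantom64, mask64_cart30)
        zf = zero_fill(y)
        res = predict_residual(ecn, zf, zf)
        target = phantom64.data - zf.data
        mse = float(np.mean(np.abs(res.data - target) ** 2))
        assert mse < 1e-4

    def test_beats_zero_predictor_baseline(self, mask64_cart30):
        from ecmri import PhantomConfig, make_phantom
        imgs = [make_phantom(PhantomConfig(seed=s)) for s in range(6)]
        ds = Dataset(train=imgs, val=[], test=[], seed=0)
        cfg = ECNetConfig(n_layers=2, feature_maps=1)  # minimal capacity
        ecn = train_ec(ds, ZeroFilledGuide(), mask64_cart30, cfg,
                       TrainConfig(iterations=400, learning_rate=1e-3, seed=2))
        # zero-predictor baseline: loss of always predicting zero residual
        baselines, finals = [], []
        for img in imgs:
            y = undersample(img, mask64_cart30)
            zf = zero_fill(y)
            x = np.stack([np.stack([zf.data.real, zf.data.imag,
                                    zf.data.real, zf.data.imag], axis=-1)])
            t = np.stack([np.stack([(img.data - zf.data).real,
                                    (img.data - zf.data).imag], axis=-1)])
            baselines.append(mse_loss(np.zeros_like(t, dtype=np.float32), t)[0])
            finals.append(mse_loss(ecn.net(x.astype(np.float32)), t)[0])
        assert np.mean(finals) < np.mean(baselines)

    def test_same_seed_same_losses(self, mask64_cart30, tiny_net):
        from ecmri import PhantomConfig, make_phantom
        imgs = [make_phantom(PhantomConfig(seed=s)) for s in range(3)]
        ds = Dataset(train=imgs, val=[], test=[], seed=0)
        runs = [train_ec(ds, ZeroFilledGuide(), mask64_cart30, tiny_net,
                         TrainConfig(iterations=30, seed=9)).loss_history
                for _ in range(2)]
        assert runs[0] == runs[1]

    def test_empty_split_rejected(self, mask64_cart30, tiny_net):
        ds = Dataset(train=[], val=[], test=[], seed=0)
        with pytest.raises(ValueError):
            train_ec(ds, ZeroFilledGuide(), mask64_cart30, tiny_net)

    def test_provenance_recorded(self, phantom64, mask64_cart30, tiny_net):
        ds = Dataset(train=[phantom64], val=[], test=[], seed=0)
        ecn = train_ec(ds, ZeroFilledGuide(), mask64_cart30, tiny_net,
                       TrainConfig(iterations=5, seed=0))
        assert ecn.guide_name == "zero_filled"
        assert ecn.mask_pattern == "cartesian_1d"

    def test_checkpoint_round_trip(self, phantom64, mask64_cart30, tiny_net, tmp_path):
        ds = Dataset(train=[phantom64], val=[], test=[], seed=0)
        ecn = train_ec(ds, ZeroFilledGuide(), mask64_cart30, tiny_net,
                       TrainConfig(iterations=10, seed=4))
        ecn.save(tmp_path / "ckpt")
        loaded = ECNetwork.load(tmp_path / "ckpt")
        assert loaded.guide_name == ecn.guide_name
        y = undersample(phantom64, mask64_cart30)
        zf = zero_fill(y)
        a = predict_residual(ecn, zf, zf)
        b = predict_residual(loaded, zf, zf)
        np.testing.assert_array_equal(a.data, b.data)
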