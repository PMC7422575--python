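"""Guide algorithms: zero-filled, iterative sparse solver, cascade CNN."""

import numpy as np
import pytest

from ecmri import (ComplexImage, Dataset, IterativeSparseGuide, PhantomConfig,
                   SparseSolverConfig, StaticGuide, ZeroFilledGuide,
                   make_cartesian_mask, make_phantom, psnr, undersample,
                   zero_fill)
from ecmri.fourier import forward_fft
from ecmri.guides import (CascadeCNNGuide, CascadeGuideConfig, _soft_threshold,
                          train_cascade_guide)
from ecmri.nn import TrainConfig


class TestZeroFilledGuide:
    def test_delegates_to_zero_fill(self, phantom64, mask64_cart30):
        y = undersample(phantom64, mask64_cart30)
        np.testing.assert_array_equal(ZeroFilledGuide().reconstruct(y).data,
                                      zero_fill(y).data)

    def test_full_mask_recovers_truth(self, phantom64):
        full = make_cartesian_mask(64, 64, ratio=1.0, seed=0)
        rec = ZeroFilledGuide().reconstruct(undersample(phantom64, full))
        assert np.max(np.abs(rec.data - phantom64.data)) < 1e-12


class TestSparseSolver:
    def test_objective_monotone_nonincreasing(self, phantom64, mask64_cart30):
        g = IterativeSparseGuide(SparseSolverConfig(max_iters=40))
        g.reconstruct(undersample(phantom64, mask64_cart30))
        obj = g.last_objectives
        assert len(obj) > 2
        assert all(b <= a * (1 + 1e-9) for a, b in zip(obj, obj[1:]))

    def test_full_mask_small_reg_recovers_truth(self, phantom64):
        full = make_cartesian_mask(64, 64, ratio=1.0, seed=0)
        g = IterativeSparseGuide(SparseSolverConfig(reg_weight=1e-12, max_iters=5))
        rec = g.reconstruct(undersample(phantom64, full))
        assert np.max(np.abs(rec.data - phantom64.data)) < 1e-6

    def test_soft_threshold_scalar_closed_form(self):
        # complex soft-threshold: shrink magnitude by t, keep phase
        c = np.array([3.0 + 4.0j])  # |c| = 5
        out = _soft_threshold(c, 2.0)
        np.testing.assert_allclose(out, (3.0 + 4.0j) * (3.0 / 5.0), atol=1e-14)
        assert _soft_threshold(np.array([0.5 + 0.0j]), 2.0)[0] == 0.0

    def test_one_prox_step_on_sparse_signal(self):
        # a single proximal step on data already in the transform's range
        # reproduces the closed-form soft-threshold value coefficient-wise
        from ecmri.guides import _WaveletTransform
        psi = _WaveletTransform("db4", 2)
        x = np.zeros((32, 32), complex)
        arr = psi.analyze(x)
        arr[5, 7] = 2.0 + 0.0j  # 1-sparse in the wavelet domain
        x1 = psi.synthesize(arr)
        t = 0.5
        out = psi.analyze(psi.synthesize(_soft_threshold(psi.analyze(x1), t)))
        assert abs(out[5, 7] - 1.5) < 1e-10
        out[5, 7] = 0
        assert np.max(np.abs(out)) < 1e-10

    def test_bad_step_size_raises_with_guidance(self, phantom64, mask64_cart30):
        g = IterativeSparseGuide(SparseSolverConfig(step_size=5.0, max_iters=30))
        with pytest.raises(ValueError, match="auto"):
            g.reconstruct(undersample(phantom64, mask64_cart30))

    def test_beats_zero_fill_on_phantom_population(self, mask64_cart30):
        # the phantoms must be compressible enough that the sparse guide
        # beats zero-fill at 30% Cartesian sampling on >= 95% of samples
        g = IterativeSparseGuide(
            SparseSolverConfig(transform="tv", reg_weight=2e-3, max_iters=80))
        wins = 0
        n = 20
        for seed in range(n):
            ph = make_phantom(PhantomConfig(seed=1000 + seed))
            y = undersample(ph, mask64_cart30)
            wins += psnr(ph, g.reconstruct(y)) > psnr(ph, zero_fill(y))
        assert wins >= 0.95 * n

    def test_zero_fill_guide_worse_than_sparse_guide(self, mask64_cart30):
        g = IterativeSparseGuide(
            SparseSolverConfig(transform="tv", reg_weight=2e-3, max_iters=80))
        vals_zf, vals_sp = [], []
        for seed in range(5):
            ph = make_phantom(PhantomConfig(seed=2000 + seed))
            y = undersample(ph, mask64_cart30)
            vals_zf.append(psnr(ph, zero_fill(y)))
            vals_sp.append(psnr(ph, g.reconstruct(y)))
        assert np.mean(vals_sp) > np.mean(vals_zf)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SparseSolverConfig(reg_weight=-1.0)
        with pytest.raises(ValueError):
            SparseSolverConfig(transform="curvelet")


class TestCascadeGuide:
    @pytest.fixture(scope="class")
    def desk_cfg(self):
        return CascadeGuideConfig(n_blocks=2, convs_per_block=2, feature_maps=8)

    def test_zero_weights_hard_consistency_is_zero_filled(
            self, phantom64, mask64_cart30, desk_cfg):
        guide = CascadeCNNGuide(desk_cfg, seed=0)
        guide.zero_params()
        y = undersample(phantom64, mask64_cart30)
        out = guide.reconstruct(y)
        # hard data fidelity of the unchanged zero-filled image is zero-filled
        assert np.max(np.abs(out.data - zero_fill(y).data)) < 1e-6

    def test_hard_consistency_reproduces_measurements(
            self, phantom64, mask64_cart30, desk_cfg):
        guide = CascadeCNNGuide(desk_cfg, seed=1)  # untrained random weights
        y = undersample(phantom64, mask64_cart30)
        out_k = forward_fft(guide.reconstruct(y))
        sampled = mask64_cart30.data == 1
        assert np.max(np.abs(out_k[sampled] - y.data[sampled])) < 1e-5

    def test_overfits_single_image(self, phantom64, mask64_cart30):
        ds = Dataset(train=[phantom64], val=[], test=[], seed=0)
        guide, history = train_cascade_guide(
            ds, mask64_cart30,
            CascadeGuideConfig(n_blocks=2, convs_per_block=3, feature_maps=16),
            TrainConfig(iterations=800, batch_size=1, learning_rate=2e-3,
                        weight_decay=0.0, seed=0))
        assert history[-1] < 1e-4
        assert history[-1] < history[0]

    def test_training_loss_trend_decreases(self, mask64_cart30, desk_cfg):
        imgs = [make_phantom(PhantomConfig(seed=s)) for s in range(4)]
        ds = Dataset(train=imgs, val=[], test=[], seed=0)
        _, history = train_cascade_guide(
            ds, mask64_cart30, desk_cfg,
            TrainConfig(iterations=400, batch_size=2, learning_rate=2e-3, seed=0))
        # smoothed trend: mean of last quarter below mean of first quarter
        q = len(history) // 4
        assert np.mean(history[-q:]) < np.mean(history[:q])

    def test_empty_training_split_rejected(self, mask64_cart30, desk_cfg):
        ds = Dataset(train=[], val=[], test=[], seed=0)
        with pytest.raises(ValueError):
            train_cascade_guide(ds, mask64_cart30, desk_cfg)

    def test_reference_scale_defaults_recorded(self):
        cfg = CascadeGuideConfig()
        assert (cfg.n_blocks, cfg.convs_per_block, cfg.feature_maps) == (4, 4, 64)


class TestStaticGuide:
    def test_returns_images_in_order(self, phantom64, mask64_cart30):
        y = undersample(phantom64, mask64_cart30)
        g = StaticGuide([phantom64, zero_fill(y)], name="ext")
        assert g.reconstruct(y) is phantom64
        assert np.max(np.abs(g.reconstruct(y).data - zero_fill(y).data)) == 0
        with pytest.raises(IndexError):
            g.reconstruct(y)
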