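import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protomae.backbone import ConfigurationError, ImageBatch, patchify
from protomae.mae import (
    MaskSpec,
    MaskedAutoencoder,
    Reconstruction,
    reconstruction_loss,
    sample_mask,
)
from protomae.optim import AdamW

from conftest import MICRO


class TestSampleMask:
    def test_table_scale_mask_counts(self, rng):
        mask = sample_mask(196, 0.75, rng)
        assert mask.n_masked == 147
        assert mask.visible_idx.size == 49

    def test_zero_ratio_masks_nothing(self, rng):
        assert sample_mask(64, 0.0, rng).n_masked == 0

    def test_all_masked_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_mask(8, 1.0, rng)

    @settings(max_examples=50, deadline=None)
    @given(L=st.integers(1, 400), ratio=st.floats(0.0, 1.0))
    def test_mask_count_exactness_property(self, L, ratio):
        expected = int(np.floor(ratio * L + 0.5))
        r = np.random.default_rng(0)
        if expected >= L:
            with pytest.raises(ConfigurationError):
                sample_mask(L, ratio, r)
        else:
            assert sample_mask(L, ratio, r).n_masked == expected

    def test_reproducible_under_fixed_rng(self):
        m1 = sample_mask(64, 0.75, np.random.default_rng(5))
        m2 = sample_mask(64, 0.75, np.random.default_rng(5))
        np.testing.assert_array_equal(m1.masked, m2.masked)

    def test_marginal_mask_frequency_is_uniform(self):
        """Each patch should be masked with frequency ~= ratio (uniform sampling)."""
        r = np.random.default_rng(99)
        counts = np.zeros(16)
        n = 10_000
        for _ in range(n):
            counts += sample_mask(16, 0.5, r).masked
        assert np.all(np.abs(counts / n - 0.5) < 0.02)

    def test_spec_invariant_enforced_on_construction(self):
        with pytest.raises(ConfigurationError):
            MaskSpec(masked=np.array([True, False, False, False]), ratio=0.5)


class TestReconstructionLoss:
    def test_zero_on_equality_in_both_scopes(self, rng):
        img = rng.random((2, 8, 8, 3))
        mask = sample_mask(4, 0.5, rng)
        for scope in ("full_image", "masked_only"):
            assert reconstruction_loss(img, img, mask, scope) == 0.0

    def test_unit_offset_three_channels_gives_three(self, rng):
        """A +1 offset in every channel makes each pixel's squared channel-vector
        norm 3, so the area-normalised sum is exactly 3."""
        target = np.zeros((2, 8, 8, 3))
        recon = np.ones((2, 8, 8, 3))
        mask = sample_mask(4, 0.5, rng)
        assert reconstruction_loss(recon, target, mask, "full_image") == pytest.approx(3.0)
        assert reconstruction_loss(recon, target, mask, "masked_only") == pytest.approx(3.0)

    def test_matches_hand_summed_pixel_oracle(self, rng):
        """Brute-force double loop over pixels on a 2x2 single-channel pair."""
        recon = rng.random((1, 2, 2, 1))
        target = rng.random((1, 2, 2, 1))
        mask = MaskSpec(masked=np.array([False]), ratio=0.0)
        total = 0.0
        for i in range(2):
            for j in range(2):
                total += (recon[0, i, j, 0] - target[0, i, j, 0]) ** 2
        expected = total / 4.0
        assert reconstruction_loss(recon, target, mask, "full_image") == pytest.approx(
            expected, abs=1e-6
        )

    def test_masked_only_ignores_visible_corruption(self, rng):
        img = rng.random((1, 8, 8, 3))
        mask = sample_mask(4, 0.5, rng)  # 4x4 patches on an 8x8 image
        recon = img.copy()
        # corrupt visible-patch pixels arbitrarily
        vis = mask.visible_idx
        grid = 2
        for v in vis:
            r0, c0 = (v // grid) * 4, (v % grid) * 4
            recon[0, r0 : r0 + 4, c0 : c0 + 4] = 77.0
        assert reconstruction_loss(recon, img, mask, "masked_only") == 0.0
        assert reconstruction_loss(recon, img, mask, "full_image") > 0.0

    def test_shape_mismatch_raises(self, rng):
        mask = sample_mask(4, 0.5, rng)
        with pytest.raises(ConfigurationError):
            reconstruction_loss(np.zeros((1, 8, 8, 3)), np.zeros((1, 4, 4, 3)), mask)

    def test_nonnegative_property(self, rng):
        for _ in range(10):
            a, b = rng.random((1, 4, 4, 1)), rng.random((1, 4, 4, 1))
            mask = sample_mask(4, 0.25, rng)
            assert reconstruction_loss(a, b, mask, "full_image") >= 0.0


class TestForwardReconstruct:
    def test_composited_passes_visible_patches_through(self, micro_model, rng):
        cfg = micro_model.config
        images = ImageBatch(rng.random((2, 16, 16, 3), dtype=np.float32))
        mask = sample_mask(cfg.num_patches, 0.75, rng)
        recon = micro_model.forward_reconstruct(images, mask, composited=True)
        assert recon.pixels.shape == images.pixels.shape
        pt_in = patchify(images, cfg).patches
        pt_out = patchify(np.clip(recon.pixels, 0, 1), cfg).patches
        np.testing.assert_allclose(
            pt_out[:, mask.visible_idx], pt_in[:, mask.visible_idx], atol=1e-6
        )

    def test_uncomposited_output_shape(self, micro_model, rng):
        images = ImageBatch(rng.random((1, 16, 16, 3), dtype=np.float32))
        mask = sample_mask(micro_model.config.num_patches, 0.5, rng)
        recon = micro_model.forward_reconstruct(images, mask, composited=False)
        assert recon.pixels.shape == (1, 16, 16, 3)
        assert recon.composited is False

    def test_fresh_model_has_positive_loss_on_noise(self, micro_model, rng):
        images = ImageBatch(rng.random((2, 16, 16, 3), dtype=np.float32))
        mask = sample_mask(micro_model.config.num_patches, 0.75, rng)
        recon = micro_model.forward_reconstruct(images, mask)
        assert reconstruction_loss(recon, images, mask, "full_image") > 0.0

    def test_mask_model_mismatch_raises(self, micro_model, rng):
        images = rng.random((1, 16, 16, 3), dtype=np.float32)
        bad_mask = sample_mask(64, 0.75, rng)  # model has 16 patches
        with pytest.raises(ConfigurationError):
            micro_model.forward_reconstruct(images, bad_mask)

    def test_training_loss_agrees_with_image_space_loss(self, micro_model, rng):
        """The differentiable patch-space loss must equal the public
        image-space formula on the composited reconstruction."""
        cfg = micro_model.config
        images = ImageBatch(rng.random((3, 16, 16, 3), dtype=np.float32))
        mask = sample_mask(cfg.num_patches, 0.5, rng)
        patches = patchify(images, cfg).patches
        recon = micro_model.forward_reconstruct(images, mask, composited=True)
        for scope in ("full_image", "masked_only"):
            t_loss = float(micro_model.training_loss(patches, mask, scope).data)
            i_loss = reconstruction_loss(recon, images, mask, scope)
            assert t_loss == pytest.approx(i_loss, rel=1e-4)


class TestGradientSanity:
    def test_one_small_step_does_not_increase_loss(self):
        """Averaged over 20 seeds, a single small-lr step on a fixed
        (image, mask) pair reduces the loss on that pair."""
        deltas = []
        for seed in range(20):
            model = MaskedAutoencoder(MICRO, seed=seed)
            r = np.random.default_rng(seed)
            patches = r.random((1, MICRO.num_patches, MICRO.patch_dim)).astype(np.float32)
            mask = sample_mask(MICRO.num_patches, 0.5, r)
            opt = AdamW(model.params, lr=1e-4)
            loss0 = model.training_loss(patches, mask)
            opt.zero_grad()
            loss0.backward()
            opt.step()
            loss1 = float(model.training_loss(patches, mask).data)
            deltas.append(loss1 - float(loss0.data))
        assert np.mean(deltas) < 0.0


def test_reconstruction_grid_dump(tmp_path, micro_model, rng):
    from protomae.mae import save_reconstruction_grid

    images = ImageBatch(rng.random((2, 16, 16, 3), dtype=np.float32))
    mask = sample_mask(16, 0.75, rng)
    recon = micro_model.forward_reconstruct(images, mask)
    out = tmp_path / "grid.png"
    save_reconstruction_grid(images, mask, recon, out)
    assert out.exists() and out.stat().st_size > 0
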