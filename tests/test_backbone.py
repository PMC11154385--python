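import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protomae.backbone import (
    ConfigurationError,
    ImageBatch,
    ModelConfig,
    PRESETS,
    ViTEncoder,
    load_checkpoint,
    patchify,
    save_checkpoint,
    unpatchify,
)

from conftest import MICRO


class TestConfig:
    def test_large_preset_patch_arithmetic(self):
        cfg = PRESETS["vit-large-mae"]
        assert cfg.num_patches == 196
        assert cfg.patch_dim == 768
        assert (cfg.encoder_layers, cfg.decoder_layers, cfg.encoder_heads) == (24, 8, 16)

    def test_small_config_patch_arithmetic(self):
        cfg = ModelConfig(image_size=32, patch_size=4)
        assert cfg.num_patches == 64
        assert cfg.patch_dim == 48

    @pytest.mark.parametrize("bad", [
        dict(image_size=30, patch_size=4),
        dict(image_size=32, patch_size=0),
        dict(image_size=32, patch_size=4, encoder_layers=-1),
        dict(image_size=32, patch_size=4, pooling="max"),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ModelConfig(**bad)


class TestPatchify:
    def test_large_image_shape_contract(self, rng):
        cfg = PRESETS["vit-large-mae"]
        images = ImageBatch(rng.random((2, 224, 224, 3), dtype=np.float32))
        seq = patchify(images, cfg)
        assert seq.patches.shape == (2, 196, 768)

    def test_round_trip_identity(self, rng):
        cfg = ModelConfig(image_size=32, patch_size=4)
        images = ImageBatch(rng.random((3, 32, 32, 3), dtype=np.float32))
        back = unpatchify(patchify(images, cfg), cfg)
        np.testing.assert_array_equal(back.pixels, images.pixels)

    @settings(max_examples=25, deadline=None)
    @given(
        grid=st.integers(1, 6), patch=st.integers(1, 5),
        channels=st.integers(1, 4), batch=st.integers(1, 3),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_round_trip_property(self, grid, patch, channels, batch, seed):
        cfg = ModelConfig(image_size=grid * patch, patch_size=patch, channels=channels)
        r = np.random.default_rng(seed)
        images = ImageBatch(r.random((batch, grid * patch, grid * patch, channels),
                                     dtype=np.float32))
        back = unpatchify(patchify(images, cfg), cfg)
        np.testing.assert_array_equal(back.pixels, images.pixels)

    def test_single_patch_config_is_reshape(self, rng):
        cfg = ModelConfig(image_size=4, patch_size=4)
        images = ImageBatch(rng.random((1, 4, 4, 3), dtype=np.float32))
        seq = patchify(images, cfg)
        assert seq.patches.shape == (1, 1, 48)
        np.testing.assert_array_equal(
            seq.patches[0, 0], images.pixels[0].reshape(-1)
        )

    def test_all_zero_patches_give_zero_image(self):
        cfg = ModelConfig(image_size=8, patch_size=4)
        img = unpatchify(np.zeros((1, 4, 48), dtype=np.float32), cfg)
        assert not img.pixels.any()

    def test_row_major_channels_fastest_order(self):
        # pixel (0, 0) of patch (row 1, col 0) sits at image row 4, col 0
        cfg = ModelConfig(image_size=8, patch_size=4)
        px = np.zeros((1, 8, 8, 3), dtype=np.float32)
        px[0, 4, 0, 1] = 1.0
        seq = patchify(ImageBatch(px), cfg)
        assert seq.patches[0, 2, 1] == 1.0  # patch index 2 = second row, first col

    def test_dimension_mismatch_raises(self, rng):
        cfg = ModelConfig(image_size=32, patch_size=4)
        with pytest.raises(ConfigurationError):
            patchify(ImageBatch(rng.random((1, 16, 16, 3), dtype=np.float32)), cfg)
        with pytest.raises(ConfigurationError):
            unpatchify(np.zeros((1, 10, 48), dtype=np.float32), cfg)


class TestImageBatch:
    def test_rejects_out_of_range_and_nonfinite(self):
        with pytest.raises(ConfigurationError):
            ImageBatch(np.full((1, 2, 2, 3), 1.5))
        with pytest.raises(ConfigurationError):
            ImageBatch(np.full((1, 2, 2, 3), np.nan))


class TestEncoder:
    def test_all_visible_token_count(self, micro_model, rng):
        cfg = micro_model.config
        patches = rng.random((2, cfg.num_patches, cfg.patch_dim), dtype=np.float32)
        tokens = micro_model.encoder.encode(patches)
        assert tokens.data.shape == (2, 1 + cfg.num_patches, cfg.encoder_dim)

    def test_deterministic_forward(self, micro_config, rng):
        patches = rng.random((1, micro_config.num_patches, micro_config.patch_dim),
                             dtype=np.float32)
        enc1 = ViTEncoder(micro_config, np.random.default_rng(0))
        enc2 = ViTEncoder(micro_config, np.random.default_rng(0))
        out1 = enc1.encode(patches).data
        out2 = enc2.encode(patches).data
        np.testing.assert_array_equal(out1, out2)

    def test_empty_visible_set_raises(self, micro_model, rng):
        cfg = micro_model.config
        patches = rng.random((1, cfg.num_patches, cfg.patch_dim), dtype=np.float32)
        with pytest.raises(ConfigurationError):
            micro_model.encoder.encode(patches, np.array([], dtype=int))

    def test_duplicate_visible_indices_raise(self, micro_model, rng):
        cfg = micro_model.config
        patches = rng.random((1, cfg.num_patches, cfg.patch_dim), dtype=np.float32)
        with pytest.raises(ConfigurationError):
            micro_model.encoder.encode(patches, np.array([0, 0, 1]))

    def test_permuting_visible_indices_permutes_tokens(self, micro_model, rng):
        """Positional codes ride with original grid indices, so reordering the
        visible set only reorders the output tokens."""
        cfg = micro_model.config
        patches = rng.random((2, cfg.num_patches, cfg.patch_dim), dtype=np.float32)
        idx = np.array([3, 0, 9, 5])
        perm = np.array([2, 0, 3, 1])
        out_a = micro_model.encoder.encode(patches, idx).data
        out_b = micro_model.encoder.encode(patches, idx[perm]).data
        # token 0 is the class token; patch tokens follow visible order
        np.testing.assert_allclose(
            out_a[:, 1:][:, perm], out_b[:, 1:], rtol=1e-5, atol=1e-6
        )
        np.testing.assert_allclose(out_a[:, 0], out_b[:, 0], rtol=1e-5, atol=1e-6)


class TestEmbedImage:
    def test_identical_images_identical_embeddings(self, micro_model, rng):
        img = rng.random((1, 16, 16, 3), dtype=np.float32)
        batch = np.concatenate([img, img], axis=0)
        emb = micro_model.encoder.embed_image(batch)
        np.testing.assert_array_equal(emb[0], emb[1])

    def test_embedding_length_is_encoder_dim(self, micro_model, rng):
        emb = micro_model.encoder.embed_image(rng.random((3, 16, 16, 3), dtype=np.float32))
        assert emb.shape == (3, micro_model.config.encoder_dim)
        assert np.all(np.isfinite(emb))

    def test_batch_composition_invariance(self, micro_model, rng):
        imgs = rng.random((4, 16, 16, 3), dtype=np.float32)
        solo = micro_model.encoder.embed_image(imgs[1:2])[0]
        batched = micro_model.encoder.embed_image(imgs)[1]
        np.testing.assert_allclose(solo, batched, rtol=1e-5, atol=1e-7)

    def test_cls_pooling_differs_from_mean(self, rng):
        import dataclasses

        cfg_cls = dataclasses.replace(MICRO, pooling="cls")
        from protomae.mae import MaskedAutoencoder

        m_mean = MaskedAutoencoder(MICRO, seed=7)
        m_cls = MaskedAutoencoder(cfg_cls, seed=7)
        imgs = rng.random((2, 16, 16, 3), dtype=np.float32)
        assert not np.allclose(
            m_mean.encoder.embed_image(imgs), m_cls.encoder.embed_image(imgs)
        )


class TestCheckpoint:
    def test_save_load_round_trip(self, micro_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_checkpoint(path, micro_model.params, micro_model.config)
        weights, config = load_checkpoint(path)
        assert config == micro_model.config
        np.testing.assert_array_equal(
            weights["enc.cls"], micro_model.params["enc.cls"].data
        )

    def test_mismatched_sidecar_rejected(self, micro_model, tmp_path):
        import dataclasses, json

        path = tmp_path / "model.npz"
        save_checkpoint(path, micro_model.params, micro_model.config)
        wrong = dataclasses.replace(micro_model.config, encoder_dim=32)
        (tmp_path / "model.npz.json").write_text(json.dumps(wrong.to_dict()))
        with pytest.raises(ConfigurationError):
            load_checkpoint(path)


class TestConfigSwitches:
    def test_learned_positions_encode_and_train(self, rng):
        import dataclasses

        from protomae.mae import MaskedAutoencoder, sample_mask
        from protomae.optim import AdamW

        cfg = dataclasses.replace(MICRO, learned_positions=True)
        model = MaskedAutoencoder(cfg, seed=3)
        assert "enc.pos" in model.params
        patches = rng.random((2, cfg.num_patches, cfg.patch_dim), dtype=np.float32)
        mask = sample_mask(cfg.num_patches, 0.5, rng)
        opt = AdamW(model.params, lr=1e-3)
        loss = model.training_loss(patches, mask)
        loss.backward()
        assert model.params["enc.pos"].grad is not None
        opt.step()

    def test_standardize_keeps_batch_invariance(self, rng):
        import dataclasses

        from protomae.mae import MaskedAutoencoder

        cfg = dataclasses.replace(MICRO, standardize=True)
        model = MaskedAutoencoder(cfg, seed=3)
        imgs = rng.random((3, 16, 16, 3), dtype=np.float32)
        solo = model.encoder.embed_image(imgs[2:3])[0]
        batched = model.encoder.embed_image(imgs)[2]
        np.testing.assert_allclose(solo, batched, rtol=1e-5, atol=1e-6)
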