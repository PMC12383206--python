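"""SPADE modulation, mask resizing, conditional LDM training and synthesis."""

import numpy as np
import pytest

from cardiacdiff.autoencoder import AETrainConfig, toy_ae_config, train_autoencoder
from cardiacdiff.backbone import (SpadeHead, build_denoiser, resize_mask_to,
                                  spade_modulate, toy_config)
from cardiacdiff.conditional import (null_condition, synthesize_images,
                                     train_conditional_ldm)
from cardiacdiff.diffusion import make_schedule
from cardiacdiff.mask_ddpm import TrainConfig, encode_mask
from cardiacdiff.nn import Tensor
from cardiacdiff.nn.layers import group_norm


class TestSpade:
    def test_zero_heads_equal_group_norm(self):
        """Zero-initialised γ/β heads leave normalised features unchanged."""
        rng = np.random.default_rng(0)
        head = SpadeHead(4, 8, norm_groups=4, rng=rng)
        feats = rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
        mask = encode_mask(np.zeros((8, 8), dtype=np.uint8))
        out = spade_modulate(Tensor(feats), np.stack([mask, mask]), head)
        ref = group_norm(Tensor(feats), 4)
        assert np.array_equal(out.numpy(), ref.numpy())

    def test_constant_features_shifted_by_beta(self):
        """When GN output is zero (constant features), out = β exactly."""
        rng = np.random.default_rng(1)
        head = SpadeHead(4, 4, norm_groups=2, rng=rng)
        b = 0.37
        head.to_beta.bias.data[:] = b
        feats = np.full((1, 4, 8, 8), 2.5, dtype=np.float32)
        mask = encode_mask(np.zeros((8, 8), dtype=np.uint8))[None]
        out = spade_modulate(Tensor(feats), mask, head).numpy()
        assert np.allclose(out, b, atol=1e-5)

    def test_resolution_mismatch_rejected(self):
        head = SpadeHead(4, 4, norm_groups=2, rng=np.random.default_rng(0))
        feats = Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            spade_modulate(feats, np.zeros((1, 4, 4, 4), dtype=np.float32), head)

    def test_conditional_equals_unconditional_at_init(self):
        """With zero-initialised SPADE heads, the conditional backbone is the
        same function as its unconditional twin at initialisation."""
        uncond = build_denoiser(toy_config(conditional=False), seed=9)
        cond = build_denoiser(toy_config(conditional=True), seed=9)
        x = np.random.default_rng(3).standard_normal((2, 4, 32, 32)).astype(np.float32)
        m = np.zeros((32, 32), dtype=np.uint8)
        m[10:20, 10:20] = 1
        c = np.stack([encode_mask(m)] * 2)
        a = uncond(x, np.array([4, 9])).numpy()
        b = cond(x, np.array([4, 9]), c).numpy()
        assert np.array_equal(a, b)


class TestResizeMask:
    def test_upscale_replicates_blocks(self):
        m = np.arange(4.0).reshape(1, 2, 2)
        out = resize_mask_to(m, (4, 4))
        assert np.array_equal(out[0], m[0].repeat(2, 0).repeat(2, 1))

    def test_downscale_takes_top_left(self):
        m = np.arange(16.0).reshape(1, 4, 4)
        out = resize_mask_to(m, (2, 2))
        assert np.array_equal(out[0], m[0][::2, ::2])

    def test_one_hotness_preserved(self):
        m = encode_mask(np.random.default_rng(0).integers(0, 4, (8, 8)).astype(np.uint8))
        for target in ((16, 16), (4, 4), (2, 2)):
            out = resize_mask_to(m, target)
            assert np.all(np.sum(out == 1.0, axis=0) == 1)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            resize_mask_to(np.zeros((1, 4, 4)), (12, 12))


@pytest.fixture(scope="module")
def tiny_ldm(toy_dataset):
    imgs = [p.image for p in toy_dataset.train[:8]]
    pairs = [(p.image, p.mask) for p in toy_dataset.train[:8]]
    acfg = toy_ae_config(channels=(4, 8), n_downsample=1, latent_channels=2,
                         norm_groups=2)
    ae, _ = train_autoencoder(imgs, acfg, AETrainConfig(steps=80, batch_size=4), seed=0)
    sched = make_schedule(T=50)
    bcfg = toy_config(channels=(4, 8), attention_levels=(2,), norm_groups=2,
                      conditional=True, in_channels=2, out_channels=2)
    ldm, hist = train_conditional_ldm(pairs, ae, bcfg, sched,
                                      TrainConfig(steps=100, batch_size=4), seed=0)
    return ae, ldm, hist, pairs


class TestConditionalLdm:
    def test_loss_decreases(self, tiny_ldm):
        _, _, hist, _ = tiny_ldm
        assert np.mean(hist[-25:]) < np.mean(hist[:25])

    def test_training_deterministic(self, toy_dataset, tiny_ldm):
        ae, ldm, hist, pairs = tiny_ldm
        sched = make_schedule(T=50)
        bcfg = toy_config(channels=(4, 8), attention_levels=(2,), norm_groups=2,
                          conditional=True, in_channels=2, out_channels=2)
        _, h2 = train_conditional_ldm(pairs, ae, bcfg, sched,
                                      TrainConfig(steps=100, batch_size=4), seed=0)
        assert hist == h2

    def test_untrained_autoencoder_rejected(self, toy_dataset):
        from cardiacdiff.autoencoder import build_autoencoder
        ae = build_autoencoder(toy_ae_config(channels=(4, 8), n_downsample=1,
                                             latent_channels=2, norm_groups=2))
        pairs = [(p.image, p.mask) for p in toy_dataset.train[:2]]
        bcfg = toy_config(channels=(4, 8), attention_levels=(2,), norm_groups=2,
                          conditional=True, in_channels=2, out_channels=2)
        with pytest.raises(ValueError):
            train_conditional_ldm(pairs, ae, bcfg, make_schedule(T=10), seed=0)

    def test_synthesis_contract_and_determinism(self, tiny_ldm, toy_dataset):
        ae, ldm, _, _ = tiny_ldm
        masks = [p.mask for p in toy_dataset.val]
        a = synthesize_images(ldm, ae, masks, guidance_w=1.5, n_steps=5, seed=7)
        b = synthesize_images(ldm, ae, masks, guidance_w=1.5, n_steps=5, seed=7)
        assert len(a) == len(masks)
        for ia, ib in zip(a, b):
            assert ia.shape == masks[0].shape
            assert np.array_equal(ia, ib)
            assert np.all(ia >= -1.0) and np.all(ia <= 1.0)

    def test_negative_guidance_rejected(self, tiny_ldm, toy_dataset):
        ae, ldm, _, _ = tiny_ldm
        with pytest.raises(ValueError):
            synthesize_images(ldm, ae, [toy_dataset.val[0].mask], guidance_w=-1.0,
                              n_steps=2, seed=0)

    def test_null_condition_is_all_background(self):
        null = null_condition(8)
        assert np.all(null[0] == 1.0) and np.all(null[1:] == -1.0)
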