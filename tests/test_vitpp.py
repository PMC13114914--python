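"""Patch transformer: tokenization, PLAR, thresholding, masks, training."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurotwin import synthgen, vitpp
from neurotwin.vitpp import (AttentionTensor, ViTConfig, ViTppModel,
                             adaptive_threshold, attention_entropy,
                             center_crop, classification_loss, dice_score,
                             extract_patches, mask_to_volume, plar_loss,
                             reassemble_patches, reconstruct_mask,
                             threshold_from_stats, tokenize, total_loss)


class TestTokenize:
    def test_sixteen_patches_from_64_image(self, rng):
        grid = tokenize(rng.uniform(size=(64, 64)), 16)
        assert grid.n_patches == 16
        assert grid.grid_shape == (4, 4)

    def test_indivisible_image_rejected(self, rng):
        with pytest.raises(ValueError):
            tokenize(rng.uniform(size=(600, 600)), 16)

    def test_roundtrip_is_exact(self, rng):
        img = rng.uniform(size=(48, 80))
        assert np.array_equal(
            reassemble_patches(extract_patches(img, 16), (48, 80), 16), img)

    def test_center_crop_makes_divisible(self, rng):
        img = rng.uniform(size=(600, 600))
        cropped = center_crop(img, 16)
        assert cropped.shape == (592, 592)
        grid = tokenize(cropped, 16)
        assert grid.n_patches == 37 * 37

    def test_row_major_ordering(self):
        img = np.arange(32 * 32, dtype=float).reshape(32, 32)
        patches = extract_patches(img, 16)
        assert patches[0][0] == img[0, 0]
        assert patches[1][0] == img[0, 16]
        assert patches[2][0] == img[16, 0]

    def test_model_embedding_has_configured_width(self, rng):
        model = ViTppModel(ViTConfig(dim=32, heads=4))
        grid = tokenize(rng.uniform(size=(64, 64)), 16, model=model)
        assert grid.tokens.shape == (16, 32)


class TestEncode:
    def test_attention_rows_sum_to_one(self, rng):
        model = ViTppModel(ViTConfig(layers=2, heads=2, dim=16, seed=0))
        _, attn = model.forward(rng.uniform(size=(64, 64)))
        assert attn.values.shape == (2, 2, 16, 16)
        assert np.allclose(attn.values.sum(axis=-1), 1.0, atol=1e-5)
        assert np.all(attn.values >= 0)

    def test_single_patch_attention_is_trivially_one(self, rng):
        model = ViTppModel(ViTConfig(layers=2, heads=2, dim=16, seed=0))
        _, attn = model.forward(rng.uniform(size=(16, 16)))
        assert np.allclose(attn.values, 1.0)

    def test_indivisible_head_config_rejected(self):
        with pytest.raises(ValueError):
            ViTConfig(dim=30, heads=4)

    def test_unnormalized_attention_rejected(self):
        with pytest.raises(ValueError):
            AttentionTensor(np.full((1, 1, 3, 3), 0.5))


class TestPLAR:
    def test_uniform_attention_reaches_maximum_entropy(self):
        a = np.full((1, 1, 4, 4), 0.25)
        assert plar_loss(a) == pytest.approx(-np.log(4), abs=1e-6)

    def test_one_hot_attention_has_zero_entropy(self):
        a = np.zeros((1, 1, 4, 4))
        a[..., np.arange(4), np.arange(4)] = 1.0
        assert plar_loss(a) == pytest.approx(0.0, abs=1e-7)

    def test_row_entropy_closed_form(self):
        row = np.array([[0.5, 0.25, 0.25]] * 3)[None, None]
        # H = 1.5 ln 2 per row
        assert plar_loss(row) == pytest.approx(-1.5 * np.log(2), abs=1e-6)

    def test_equals_naive_triple_loop_reference(self, rng):
        L, H, N = 3, 2, 5
        logits = rng.normal(size=(L, H, N, N))
        a = np.exp(logits)
        a /= a.sum(axis=-1, keepdims=True)
        eps = 1e-8
        total = 0.0
        for l in range(L):
            for h in range(H):
                for i in range(N):
                    total += -(a[l, h, i] * np.log(a[l, h, i] + eps)).sum()
        expected = -total / (L * H * N)
        assert abs(plar_loss(a) - expected) <= 1e-9

    @given(st.integers(0, 10 ** 6))
    def test_bounded_between_neg_log_n_and_zero(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        a = rng.dirichlet(np.ones(n), size=(2, 2, n))
        val = plar_loss(a)
        assert -np.log(n) - 1e-9 <= val <= 1e-9

    def test_malformed_rows_raise_contract_error(self):
        with pytest.raises(ValueError):
            plar_loss(np.full((1, 1, 2, 2), 0.3))


class TestLosses:
    def test_confident_correct_predictions_near_zero(self):
        p = np.array([0.999, 0.001])
        y = np.array([1, 0])
        assert classification_loss(p, y) < 0.01

    def test_uninformative_half_is_ln_two(self):
        assert classification_loss(np.full(8, 0.5),
                                   np.array([0, 1] * 4)) == pytest.approx(
            np.log(2))

    def test_point_eight_closed_form(self):
        assert classification_loss(np.array([0.8]),
                                   np.array([1])) == pytest.approx(
            -np.log(0.8))

    def test_saturated_probability_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            val = classification_loss(np.array([1.0]), np.array([1]))
        assert np.isfinite(val)

    def test_total_loss_arithmetic_and_linearity(self):
        assert total_loss(0.5, -1.0, 0.0).l_total == pytest.approx(0.5)
        assert total_loss(0.5, -1.0, 0.6).l_total == pytest.approx(-0.1)
        l1 = total_loss(1.0, -0.5, 0.2).l_total
        l2 = total_loss(1.0, -0.5, 0.4).l_total
        l3 = total_loss(1.0, -0.5, 0.6).l_total
        assert l2 - l1 == pytest.approx(l3 - l2)

    def test_lambda_outside_range_rejected(self):
        with pytest.raises(ValueError):
            total_loss(0.5, -1.0, 1.5)


class TestAdaptiveThreshold:
    def test_high_noise_worked_example(self):
        assert threshold_from_stats(0.32, 0.12, 1.5) == pytest.approx(0.5)

    def test_clean_scan_worked_example(self):
        assert threshold_from_stats(0.20, 0.06, 1.5) == pytest.approx(0.29)

    def test_zero_spread_gives_mean(self):
        assert threshold_from_stats(0.4, 0.0, 1.5) == pytest.approx(0.4)

    def test_identical_probabilities_degenerate_empty_mask(self):
        pmap = adaptive_threshold(np.full(8, 0.3))
        assert pmap.degenerate
        assert pmap.threshold == pytest.approx(0.3)
        assert pmap.mask.sum() == 0

    def test_threshold_strictly_increasing_in_k(self, rng):
        p = rng.uniform(size=32)
        thetas = [adaptive_threshold(p, k=k).threshold
                  for k in (1.0, 1.3, 1.5, 1.8, 2.5)]
        assert np.all(np.diff(thetas) > 0)

    def test_strict_inequality_at_threshold(self):
        p = np.array([0.1, 0.1, 0.1, 0.1, 0.9])
        pmap = adaptive_threshold(p, k=1.5)
        at_theta = np.isclose(p, pmap.threshold)
        assert not pmap.mask[at_theta].any() if at_theta.any() else True
        assert pmap.mask[-1] == 1

    def test_fewer_false_positives_than_fixed_half_on_noisy_maps(self, rng):
        """On simulated noisy scans (inflated background probabilities)
        the adaptive rule beats the fixed 0.5 threshold on false
        positives without losing recall."""
        fp_adaptive = fp_fixed = 0
        recall_adaptive = recall_fixed = 0
        for _ in range(50):
            n_tumor = 3
            bg = np.clip(rng.normal(0.45, 0.08, size=29), 0, 1)
            tumor = np.clip(rng.normal(0.93, 0.03, size=n_tumor), 0, 1)
            p = np.concatenate([bg, tumor])
            truth = np.concatenate([np.zeros(29), np.ones(n_tumor)])
            # tumors occupy ~10 % of patches here, so identify the
            # background set at the matching percentile
            pmap = adaptive_threshold(p, k=1.5, background_percentile=90.0)
            fixed = (p > 0.5).astype(int)
            fp_adaptive += int(((pmap.mask == 1) & (truth == 0)).sum())
            fp_fixed += int(((fixed == 1) & (truth == 0)).sum())
            recall_adaptive += int(((pmap.mask == 1) & (truth == 1)).sum())
            recall_fixed += int(((fixed == 1) & (truth == 1)).sum())
        assert fp_adaptive < fp_fixed
        assert recall_adaptive >= recall_fixed

    def test_needs_at_least_two_patches(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.array([0.5]))


class TestMaskAndVolume:
    def test_all_zero_labels_give_empty_mask(self):
        assert reconstruct_mask(np.zeros(16), (4, 4)).sum() == 0

    def test_row_major_index_oracle(self):
        labels = np.zeros(16)
        labels[5] = 1
        mask = reconstruct_mask(labels, (4, 4))
        assert mask[1, 1] == 1
        assert mask.sum() == 1

    def test_flatten_roundtrip_identity(self, rng):
        mask = rng.integers(0, 2, size=(4, 4))
        assert np.array_equal(reconstruct_mask(mask.reshape(-1), (4, 4)),
                              mask)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_mask(np.zeros(15), (4, 4))

    def test_single_patch_volume(self):
        mask = np.zeros((4, 4))
        mask[0, 0] = 1
        # 16x16 px at 1 mm/px, 10 mm slice = 2560 mm^3 = 2.56 cc
        assert mask_to_volume([mask], 16, 1.0, 10.0) == pytest.approx(2.56)

    def test_empty_masks_give_zero(self):
        assert mask_to_volume([np.zeros((4, 4))] * 3) == 0.0

    def test_volume_linear_in_slice_thickness(self, rng):
        masks = [rng.integers(0, 2, size=(4, 4)) for _ in range(3)]
        v1 = mask_to_volume(masks, 16, 1.0, 5.0)
        v2 = mask_to_volume(masks, 16, 1.0, 10.0)
        assert v2 == pytest.approx(2 * v1)

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError):
            mask_to_volume([np.zeros((4, 4)), np.zeros((2, 2))])

    def test_dice_conventions(self):
        assert dice_score(np.zeros((2, 2)), np.zeros((2, 2))) == 1.0
        assert dice_score(np.ones((2, 2)), np.ones((2, 2))) == 1.0
        assert dice_score(np.ones((2, 2)), np.zeros((2, 2))) == 0.0


class TestTrainingAndSaliency:
    def test_loss_drops_over_training(self, trained_vit):
        _, history = trained_vit
        assert history["loss"][-1] < history["loss"][0]

    def test_heldout_slices_classified_well(self, trained_vit,
                                            small_phantom_split):
        model, _ = trained_vit
        _, test = small_phantom_split
        metrics = model.evaluate(test)
        assert metrics["slice_accuracy"] >= 0.9

    def test_single_class_dataset_rejected(self):
        phantoms = [synthgen.generate_phantom(
            synthgen.SynthPhantomSpec(tumor_count=0, seed=i))
            for i in range(4)]
        model = ViTppModel(ViTConfig(layers=1, heads=2, dim=16, epochs=1))
        with pytest.raises(ValueError):
            model.fit(phantoms)

    def test_training_is_deterministic_under_seed(self):
        phantoms = synthgen.generate_phantom_dataset(20, seed=5)
        losses = []
        for _ in range(2):
            cfg = ViTConfig(layers=1, heads=2, dim=16, epochs=3, seed=7)
            _, h = vitpp.train_vitpp(phantoms, cfg)
            losses.append(h["loss"])
        assert losses[0] == losses[1]

    def test_saliency_flat_on_constant_image(self, trained_vit):
        model, _ = trained_vit
        sal = model.saliency(np.full((64, 64), 0.25))
        assert sal.shape == (4, 4)
        assert np.allclose(sal, sal.flat[0])

    def test_saliency_bounded_and_tumor_contrasted(self, trained_vit,
                                                   small_phantom_split):
        model, _ = trained_vit
        _, test = small_phantom_split
        contrasts = []
        for ph in test:
            if not ph.patch_labels.any():
                continue
            sal = model.saliency(ph.image)
            assert sal.min() >= 0.0 and sal.max() <= 1.0
            tumor = sal[ph.patch_labels.astype(bool)].mean()
            bg = sal[~ph.patch_labels.astype(bool)].mean()
            contrasts.append(tumor - bg)
        assert np.mean(contrasts) > 0

    def test_untrained_saliency_warns_but_computes(self, rng):
        model = ViTppModel(ViTConfig(layers=1, heads=2, dim=16))
        with pytest.warns(RuntimeWarning):
            sal = model.saliency(rng.uniform(size=(64, 64)))
        assert sal.shape == (4, 4)

    def test_structural_embedding_is_64_dim(self, trained_vit, rng):
        model, _ = trained_vit
        emb = model.structural_embedding(rng.uniform(size=(64, 64)))
        assert emb.shape == (64,)
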