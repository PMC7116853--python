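"""Domain adaptation: augmentation consistency, adversarial terms, symmetry
plane estimation and pseudo-healthy synthesis."""

import numpy as np
import pytest

from jointseg import (ArchConfig, AugmentationRanges, HeteroUNet,
                      adversarial_da_losses, augmentation_da_loss,
                      estimate_symmetry_plane, generate_phantom,
                      make_pseudo_healthy,
                      sample_augmentation, wmh_scenario)
from jointseg.autodiff import Tensor
from jointseg.domain_adapt import SymmetryPlane, _mirror_ncc
from jointseg.nn import Discriminator
from jointseg.objective import tissue_loss


class TestAugmentation:
    def test_zero_amplitudes_are_identity(self):
        zero = AugmentationRanges(bias_amplitude=(0, 0), smooth_sigma=(0, 0),
                                  ghost_alpha=(0, 0))
        t = sample_augmentation(0, zero)
        assert t.is_identity()
        img = np.random.default_rng(0).random((16, 16)).astype(np.float32)
        assert np.array_equal(t.apply(img), img)

    def test_same_psi_twice_is_identical(self):
        t = sample_augmentation(3)
        img = np.random.default_rng(1).random((16, 16)).astype(np.float32)
        assert np.array_equal(t.apply(img), t.apply(img))
        assert sample_augmentation(3) == sample_augmentation(3)

    def test_nonzero_amplitude_changes_image(self):
        ranges = AugmentationRanges(bias_amplitude=(0.2, 0.3))
        t = sample_augmentation(4, ranges)
        img = np.random.default_rng(2).random((16, 16)).astype(np.float32) + 1
        assert not np.array_equal(t.apply(img), img)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            sample_augmentation(0, AugmentationRanges(bias_amplitude=(0.5, 0.1)))


@pytest.fixture
def tiny_model(taxonomy):
    arch = ArchConfig(num_modalities=2, num_classes=taxonomy.num_classes,
                      levels=2, base_channels=4, ndim=2)
    return HeteroUNet(arch, seed=2)


class TestAugmentationDALoss:
    def test_identity_transform_gives_zero(self, tiny_model, taxonomy,
                                           training_weights):
        zero = AugmentationRanges(bias_amplitude=(0, 0), smooth_sigma=(0, 0),
                                  ghost_alpha=(0, 0))
        t = sample_augmentation(0, zero)
        x = np.random.default_rng(3).random((2, 2, 16, 16)).astype(np.float32)
        loss = augmentation_da_loss(tiny_model, x, t, training_weights)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-7)

    def test_matches_independent_recomputation(self, tiny_model, taxonomy,
                                               training_weights):
        t = sample_augmentation(5)
        x = np.random.default_rng(4).random((2, 2, 16, 16)).astype(np.float32)
        loss = float(augmentation_da_loss(tiny_model, x, t,
                                          training_weights).data)
        assert loss >= 0
        # recompute from two standalone forward passes
        mask = [True, False]
        x_aug = x.copy()
        for b in range(2):
            x_aug[b, 0] = t.apply(x[b, 0])
        p = tiny_model.forward(x, mask)
        pa = tiny_model.forward(x_aug, mask)
        expected = np.mean([
            float(tissue_loss(np.asarray(p.data[b], dtype=np.float64),
                              np.asarray(pa.data[b], dtype=np.float64),
                              training_weights))
            for b in range(2)])
        assert loss == pytest.approx(expected, rel=1e-4)


class TestAdversarialLosses:
    def test_chance_discriminator_yields_log2(self):
        half = lambda f: Tensor(np.full(f.shape[0] if hasattr(f, "shape")
                                        else 2, 0.5))
        f = np.zeros((2, 4, 4, 4), dtype=np.float32)
        seg_term, disc_term = adversarial_da_losses(half, f, f)
        assert float(disc_term.data) == pytest.approx(2 * np.log(2), rel=1e-6)
        assert float(seg_term.data) == pytest.approx(2 * np.log(2), rel=1e-6)

    def test_confident_correct_discriminator_limits(self):
        """A perfect discriminator has vanishing classification loss; the
        segmenter's confusion term blows up (clamped by the probability
        floor)."""
        perfect = lambda f: Tensor(np.array([1.0 if f.data.sum() > 0 else 0.0]
                                            if isinstance(f, Tensor)
                                            else [float(np.sum(f) > 0)]))
        f_lesion = np.ones((1, 2, 4, 4), dtype=np.float32)
        f_control = -np.ones((1, 2, 4, 4), dtype=np.float32)
        seg_term, disc_term = adversarial_da_losses(perfect, f_control,
                                                    f_lesion)
        assert float(disc_term.data) == pytest.approx(0.0, abs=1e-5)
        assert float(seg_term.data) > 25  # -2·log(clamp) ≈ 32

    def test_segmenter_gradient_reaches_features(self):
        disc = Discriminator(4, ndim=2, seed=1)
        rng = np.random.default_rng(5)
        fc = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32),
                    requires_grad=True)
        fl = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32),
                    requires_grad=True)
        seg_term, _ = adversarial_da_losses(disc, fc, fl)
        seg_term.backward()
        assert fc.grad is not None and np.abs(fc.grad).max() > 0
        assert fl.grad is not None and np.abs(fl.grad).max() > 0

    def test_discriminator_trains_toward_separation(self):
        """A few gradient steps on separable features drop the
        classification loss below its chance value log 2 per term."""
        from jointseg.autodiff import Adam

        disc = Discriminator(2, ndim=2, seed=0)
        opt = Adam(disc.parameters(), lr=1e-2)
        rng = np.random.default_rng(6)
        fc = (rng.normal(size=(4, 2, 8, 8)) - 1.0).astype(np.float32)
        fl = (rng.normal(size=(4, 2, 8, 8)) + 1.0).astype(np.float32)
        losses = []
        for _ in range(30):
            _, disc_term = adversarial_da_losses(disc, fc, fl)
            opt.zero_grad()
            disc_term.backward()
            opt.step()
            losses.append(float(disc_term.data))
        assert losses[-1] < losses[0]
        assert losses[-1] < 2 * np.log(2)


def _symmetric_image(seed=0, shape=(48, 48)):
    cfg = wmh_scenario(seed=seed, grid_shape=shape)
    img, _ = generate_phantom(cfg, 1, with_lesions=False)
    t1 = img.channels[0]
    return 0.5 * (t1 + np.flip(t1, axis=-1))  # exactly mirror-symmetric


class TestSymmetryPlane:
    def test_recovers_central_plane(self):
        plane = estimate_symmetry_plane(_symmetric_image())
        assert abs(plane.offset) <= 0.5
        assert abs(plane.angle_deg) <= 1.0

    def test_translation_equivariance(self):
        img = _symmetric_image(seed=3)
        t = 3
        shifted = np.roll(img, t, axis=-1)
        plane = estimate_symmetry_plane(shifted)
        assert plane.offset == pytest.approx(t, abs=0.5)

    def test_returned_plane_not_worse_than_initial_guess(self):
        img = np.roll(_symmetric_image(seed=4), 2, axis=-1)
        fg = img > 0.1 * img.max()
        plane = estimate_symmetry_plane(img)
        assert (_mirror_ncc(img, plane, fg)
                >= _mirror_ncc(img, SymmetryPlane(0.0, 0.0), fg) - 1e-9)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            estimate_symmetry_plane(np.zeros((16, 16)))


class TestPseudoHealthy:
    def _phantom(self, seed=2):
        cfg = wmh_scenario(seed=seed)
        return generate_phantom(cfg, 4, with_lesions=True), cfg

    def test_output_is_lesion_free_and_mirror_symmetric(self, taxonomy):
        (img, lab), cfg = self._phantom()
        plane = SymmetryPlane(0.0, 0.0)
        ps_img, ps_lab = make_pseudo_healthy(img.channels[0], lab.labels,
                                             plane, taxonomy)
        assert set(np.unique(ps_lab)) <= {0, *taxonomy.tissue_classes}
        assert np.array_equal(ps_lab, np.flip(ps_lab, axis=-1))
        sym_err = np.abs(ps_img - np.flip(ps_img, axis=-1))
        assert np.percentile(sym_err, 99) < 0.05  # up to interpolation

    def test_healthy_half_is_preserved(self, taxonomy):
        (img, lab), cfg = self._phantom(seed=5)
        plane = SymmetryPlane(0.0, 0.0)
        ps_img, _ = make_pseudo_healthy(img.channels[0], lab.labels, plane,
                                        taxonomy)
        lesion_cols = np.nonzero(
            np.isin(lab.labels, taxonomy.lesion_classes))[-1]
        mid = (lab.labels.shape[-1] - 1) / 2
        healthy = (slice(None), slice(0, int(mid))) \
            if lesion_cols.mean() > mid else \
            (slice(None), slice(int(np.ceil(mid)) + 1, None))
        assert np.allclose(ps_img[healthy], img.channels[0][healthy])

    def test_lesion_free_input_keeps_kept_half(self, taxonomy):
        cfg = wmh_scenario(seed=6)
        img, lab = generate_phantom(cfg, 1, with_lesions=False)
        ps_img, ps_lab = make_pseudo_healthy(img.channels[0], lab.labels,
                                             SymmetryPlane(0.0, 0.0),
                                             taxonomy)
        w = lab.labels.shape[-1]
        kept = (slice(None), slice(w // 2 + 1, None))  # healthy side default
        assert np.allclose(ps_img[kept], img.channels[0][kept])

    def test_bilateral_lesions_refused(self, taxonomy):
        labels = np.zeros((16, 16), dtype=int)
        labels[:, :] = 3
        labels[8, 2] = 5
        labels[8, 13] = 5
        img = np.random.default_rng(0).random((16, 16)).astype(np.float32)
        with pytest.raises(ValueError):
            make_pseudo_healthy(img, labels, SymmetryPlane(0.0, 0.0),
                                taxonomy)

    def test_multichannel_image_supported(self, taxonomy):
        (img, lab), _ = self._phantom(seed=7)
        ps_img, _ = make_pseudo_healthy(img.channels, lab.labels,
                                        SymmetryPlane(0.0, 0.0), taxonomy)
        assert ps_img.shape == img.channels.shape
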