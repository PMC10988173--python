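"""Augmentation group, consistency loss, schedule, sampler, training loop."""

import numpy as np
import pytest

import blindpick.autodiff as ad
from blindpick.backbone import NetworkOutputs
from blindpick.noise import PriorStats
from blindpick.training import (DIHEDRAL, EarlyStopper, TrainConfig,
                                TrainScene, Transform, apply_transform,
                                consistency_loss, lr_schedule, sample_patches,
                                total_loss, train, transform_coords)


def tagged_array(n=4):
    return np.arange(n * n, dtype=float).reshape(n, n)


class TestDihedralGroup:
    def test_eight_distinct_elements(self):
        a = tagged_array()
        images = [apply_transform(a, t).tobytes() for t in DIHEDRAL]
        assert len(set(images)) == 8

    def test_inverse_restores_identity(self):
        a = tagged_array()
        for t in DIHEDRAL:
            back = apply_transform(apply_transform(a, t), t.inverse())
            np.testing.assert_array_equal(back, a)

    def test_rot90_four_times_is_identity(self):
        a = tagged_array()
        r = Transform(k=1)
        out = a
        for _ in range(4):
            out = apply_transform(out, r)
        np.testing.assert_array_equal(out, a)

    def test_composition_table_closed(self):
        """compose() must reproduce sequential application for all 64 pairs."""
        a = tagged_array()
        reprs = {apply_transform(a, t).tobytes(): t for t in DIHEDRAL}
        for t1 in DIHEDRAL:
            for t2 in DIHEDRAL:
                seq = apply_transform(apply_transform(a, t2), t1)
                comp = apply_transform(a, t1.compose(t2))
                np.testing.assert_array_equal(seq, comp)
                assert seq.tobytes() in reprs

    def test_non_square_rotation_rejected(self):
        with pytest.raises(ValueError):
            apply_transform(np.zeros((4, 6)), Transform(k=1))

    def test_coords_follow_the_image(self):
        n = 8
        img = np.zeros((n, n))
        img[2, 5] = 1.0
        for t in DIHEDRAL:
            moved = apply_transform(img, t)
            (r, c), = transform_coords([(2, 5)], n, t)
            assert moved[r, c] == 1.0


class TestConsistencyLoss:
    @staticmethod
    def _outputs(logits, denoised=None):
        z = ad.Tensor(np.asarray(logits, dtype=float))
        return NetworkOutputs(
            prior=PriorStats(mu=z, sigma=z), heatmap_logits=z,
            denoised=None if denoised is None
            else ad.Tensor(np.asarray(denoised, dtype=float)))

    def test_identity_transform_identical_outputs(self):
        o = self._outputs(np.random.default_rng(0).normal(size=(1, 4, 4)),
                          np.zeros((1, 4, 4)))
        val = consistency_loss(o, o, Transform())
        assert float(val.data) == pytest.approx(0.0)

    def test_equivariant_outputs_give_zero_for_every_t(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(1, 6, 6))
        den = rng.normal(size=(1, 6, 6))
        for t in DIHEDRAL:
            o_plain = self._outputs(base, den)
            o_aug = self._outputs(apply_transform(base, t),
                                  apply_transform(den, t))
            val = consistency_loss(o_plain, o_aug, t)
            assert float(val.data) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_one_differing_pixel(self):
        # logits chosen so sigmoid gap is exactly d on one pixel of a 2x2 map
        a = np.zeros((1, 2, 2))
        b = np.zeros((1, 2, 2))
        b[0, 0, 0] = 2.0       # sigmoid(2) - sigmoid(0)
        d = 1 / (1 + np.exp(-2.0)) - 0.5
        den_a = np.zeros((1, 2, 2))
        den_b = np.zeros((1, 2, 2))
        den_b[0, 1, 1] = 0.3
        o1 = self._outputs(a, den_a)
        o2 = self._outputs(b, den_b)
        val = float(consistency_loss(o1, o2, Transform()).data)
        assert val == pytest.approx(d ** 2 / 4 + 0.3 ** 2 / 4, rel=1e-9)


class TestTotalLoss:
    def _cfg(self, **kw):
        return TrainConfig(**kw)

    def test_weighted_sum(self):
        cfg = self._cfg(lambda_denoise=1.0, lambda_detect=1.0, lambda_cons=1.0)
        val = total_loss(ad.Tensor(np.float64(1.0)), ad.Tensor(np.float64(2.0)),
                         ad.Tensor(np.float64(3.0)), cfg)
        assert float(val.data) == pytest.approx(6.0)

    def test_denoise_only_ignores_detect(self):
        cfg = self._cfg(mode="denoise_only")
        val = total_loss(ad.Tensor(np.float64(1.0)),
                         ad.Tensor(np.float64(1e9)),
                         ad.Tensor(np.float64(0.0)), cfg)
        assert float(val.data) == pytest.approx(cfg.lambda_denoise * 1.0)

    def test_detect_only_ignores_denoise(self):
        cfg = self._cfg(mode="detect_only")
        val = total_loss(ad.Tensor(np.float64(1e9)),
                         ad.Tensor(np.float64(2.0)),
                         ad.Tensor(np.float64(0.0)), cfg)
        assert float(val.data) == pytest.approx(cfg.lambda_detect * 2.0)

    def test_nan_term_aborts_with_name(self):
        cfg = self._cfg()
        with pytest.raises(FloatingPointError, match="detect"):
            total_loss(ad.Tensor(np.float64(1.0)),
                       ad.Tensor(np.float64(np.nan)),
                       ad.Tensor(np.float64(0.0)), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(mode="joint", lambda_detect=0.0)
        with pytest.raises(ValueError):
            TrainConfig(lambda_cons=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(patch_size=30)


class TestSampler:
    def _scenes(self, rng_seed=0, n_scenes=2, n_labeled=3, size=128):
        rng = np.random.default_rng(rng_seed)
        scenes = []
        for i in range(n_scenes):
            coords = [(int(r), int(c)) for r, c in
                      zip(rng.integers(10, size - 10, n_labeled),
                          rng.integers(10, size - 10, n_labeled))]
            scenes.append(TrainScene(image=rng.normal(size=(size, size)),
                                     labeled_coords=coords, radius_px=6))
        return scenes

    def test_single_particle_always_included(self):
        scenes = [TrainScene(image=np.zeros((100, 100)),
                             labeled_coords=[(50, 50)], radius_px=6)]
        cfg = TrainConfig(batch_size=8, patch_size=32)
        for (i, (r0, c0), coords) in sample_patches(scenes, cfg, 3):
            assert coords == [(50 - r0, 50 - c0)]

    def test_coords_within_patch(self):
        scenes = self._scenes()
        cfg = TrainConfig(batch_size=16, patch_size=48)
        for (_, _, coords) in sample_patches(scenes, cfg, 11):
            for (r, c) in coords:
                assert 0 <= r < 48 and 0 <= c < 48

    def test_determinism_per_seed(self):
        scenes = self._scenes()
        cfg = TrainConfig(batch_size=4, patch_size=48)
        assert sample_patches(scenes, cfg, 5) == sample_patches(scenes, cfg, 5)

    def test_inclusion_frequency_uniform(self):
        """With well-separated labels, inclusion counts are multinomial-uniform."""
        rng = np.random.default_rng(2)
        coords = [(r, c) for r in (40, 120, 200) for c in (40, 120, 200)]
        scenes = [TrainScene(image=np.zeros((240, 240)),
                             labeled_coords=coords, radius_px=6)]
        cfg = TrainConfig(batch_size=1, patch_size=32)
        counts = {rc: 0 for rc in coords}
        n_draws = 1000
        for s in range(n_draws):
            (i, (r0, c0), cs) = sample_patches(scenes, cfg, s)[0]
            assert len(cs) == 1
            counts[(cs[0][0] + r0, cs[0][1] + c0)] += 1
        p = 1 / len(coords)
        sd = np.sqrt(n_draws * p * (1 - p))
        for v in counts.values():
            assert abs(v - n_draws * p) <= 3 * sd

    def test_no_labels_raises(self):
        scenes = [TrainScene(image=np.zeros((64, 64)), labeled_coords=[],
                             radius_px=6)]
        with pytest.raises(ValueError):
            sample_patches(scenes, TrainConfig(), 0)


class TestSchedule:
    def test_starts_at_zero(self):
        cfg = TrainConfig(max_iters=1000, warmup_frac=0.1, lr_peak=5e-4)
        assert lr_schedule(0, cfg) == 0.0

    def test_peak_at_warmup_end(self):
        cfg = TrainConfig(max_iters=1000, warmup_frac=0.1, lr_peak=5e-4)
        assert lr_schedule(100, cfg) == pytest.approx(5e-4)

    def test_cosine_tail_nearly_zero(self):
        cfg = TrainConfig(max_iters=1000, warmup_frac=0.1, lr_peak=5e-4)
        assert lr_schedule(999, cfg) < 0.01 * 5e-4

    def test_monotone_warmup(self):
        cfg = TrainConfig(max_iters=500, warmup_frac=0.2, lr_peak=1e-3)
        lrs = [lr_schedule(i, cfg) for i in range(100)]
        assert np.all(np.diff(lrs) > 0)


class TestEarlyStopper:
    def test_constant_loss_stops_after_two_windows(self):
        s = EarlyStopper(window=10, tol=0.01)
        fired_at = None
        for i in range(100):
            if s.update(5.0):
                fired_at = i
                break
        assert fired_at == 19     # first index where two full windows exist

    def test_decreasing_loss_does_not_stop(self):
        s = EarlyStopper(window=10, tol=0.01)
        assert not any(s.update(100.0 / (i + 1)) for i in range(60))


class TestTrainLoop:
    @staticmethod
    def _tiny_scenes(snr=0.5, seed=0):
        from blindpick.synthetic import (ParticleSpec, corrupt_gaussian,
                                         make_clean_micrograph,
                                         make_sparse_labels, sigma_for_snr)
        spec = ParticleSpec(radius_px=4.0)
        scenes = []
        for i in range(2):
            clean = make_clean_micrograph((64, 64), spec, 6, min_dist=12,
                                          seed=seed + i)
            sigma = sigma_for_snr(clean, snr)
            noisy = corrupt_gaussian(clean.image, sigma, seed=100 + i)
            labels = make_sparse_labels(clean.coords, 0.5, seed=200 + i)
            scenes.append(TrainScene(image=noisy, labeled_coords=labels,
                                     radius_px=4.0, clean=clean.image))
        return scenes

    @staticmethod
    def _fast_cfg(**kw):
        base = dict(max_iters=3, batch_size=2, patch_size=32, depth=2,
                    base_channels=8, K=128, pi=0.05, seed=1,
                    early_stop_window=50)
        base.update(kw)
        return TrainConfig(**base)

    def test_same_seed_identical_histories(self):
        scenes = self._tiny_scenes()
        cfg = self._fast_cfg()
        h1 = train(scenes, cfg).history
        h2 = train(scenes, cfg).history
        np.testing.assert_array_equal(h1["total"].values, h2["total"].values)

    def test_history_records_every_term(self):
        scenes = self._tiny_scenes()
        res = train(scenes, self._fast_cfg())
        assert set(res.history.columns) >= {"iter", "lr", "total", "denoise",
                                            "detect", "consistency"}
        assert len(res.history) == 3
        assert np.isfinite(res.history["total"]).all()

    def test_denoise_only_freezes_detection_head(self):
        scenes = self._tiny_scenes()
        cfg = self._fast_cfg(mode="denoise_only", max_iters=4)
        res = train(scenes, cfg)
        fresh = train(scenes, self._fast_cfg(mode="denoise_only", max_iters=1))
        # detection-head weights must be untouched by training
        det0 = [p.data.tobytes() for p in fresh.model.detection_params()]
        det1 = [p.data.tobytes() for p in res.model.detection_params()]
        assert det0 == det1
        # while trunk weights did move
        tr0 = [p.data.tobytes() for p in fresh.model.trunk_params()]
        tr1 = [p.data.tobytes() for p in res.model.trunk_params()]
        assert tr0 != tr1

    def test_denoise_only_works_without_labels(self):
        rng = np.random.default_rng(0)
        scenes = [TrainScene(image=rng.normal(5.0, 2.0, size=(48, 48)),
                             labeled_coords=[], radius_px=4.0)]
        cfg = self._fast_cfg(mode="denoise_only", patch_size=32, max_iters=2)
        res = train(scenes, cfg)
        assert len(res.history) == 2

    def test_detect_without_labels_raises(self):
        scenes = [TrainScene(image=np.zeros((64, 64)), labeled_coords=[],
                             radius_px=4.0)]
        with pytest.raises(ValueError):
            train(scenes, self._fast_cfg())

    def test_early_stop_reason_reported(self):
        scenes = self._tiny_scenes()
        cfg = self._fast_cfg(max_iters=30, early_stop_window=3,
                             early_stop_tol=1e9)   # any change counts as small
        res = train(scenes, cfg)
        assert res.stop_reason == "early_stop"
        assert len(res.history) == 6
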