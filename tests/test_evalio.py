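"""NMS, matching, PSNR, FSC, prior heuristic, I/O round-trips."""

import math

import numpy as np
import pytest

from blindpick.evalio import (Micrograph, ParticleSet, bin_image,
                              estimate_prior, fsc, fsc_resolution,
                              match_precision_recall, nms, psnr, read_coords,
                              read_micrograph, write_coords, write_micrograph)


def brute_force_nms(heatmap, radius, threshold):
    """Literal greedy definition: all supra-threshold pixels, score order."""
    hm = np.asarray(heatmap, dtype=float)
    cands = [(-hm[r, c], r, c) for r in range(hm.shape[0])
             for c in range(hm.shape[1]) if hm[r, c] >= threshold]
    cands.sort()
    kept = []
    for (negs, r, c) in cands:
        if all((r - kr) ** 2 + (c - kc) ** 2 > radius ** 2
               for (kr, kc) in kept):
            kept.append((r, c))
    return kept


class TestNMS:
    def test_single_peak(self):
        hm = np.zeros((16, 16))
        hm[5, 7] = 0.9
        out = nms(hm, radius=3, threshold=0.5)
        assert out.particles == [(7, 5, 0.9)]

    def test_close_pair_keeps_higher(self):
        hm = np.zeros((16, 16))
        hm[5, 5] = 0.8
        hm[5, 7] = 0.9
        out = nms(hm, radius=3, threshold=0.5)
        assert out.particles == [(7, 5, 0.9)]

    def test_matches_brute_force_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            hm = np.zeros((40, 40))
            n = int(rng.integers(5, 50))
            rr = rng.integers(0, 40, n)
            cc = rng.integers(0, 40, n)
            hm[rr, cc] = rng.uniform(0.3, 1.0, n)
            out = nms(hm, radius=4, threshold=0.4)
            oracle = brute_force_nms(hm, 4, 0.4)
            assert [(y, x) for (x, y, _) in out.particles] == oracle

    def test_scores_descending(self):
        rng = np.random.default_rng(0)
        hm = np.clip(rng.uniform(size=(32, 32)), 0, 0.99)
        out = nms(hm, radius=5, threshold=0.5)
        scores = [s for (_, _, s) in out.particles]
        assert scores == sorted(scores, reverse=True)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            nms(np.zeros((4, 4)), radius=0.5, threshold=0.5)
        with pytest.raises(ValueError):
            nms(np.zeros((4, 4)), radius=2, threshold=1.5)


def brute_force_match(pred, truth, radius):
    """Greedy score-ordered one-to-one matching, literal definition."""
    taken = set()
    tp = 0
    for (x, y, s) in sorted(pred, key=lambda p: -p[2]):
        best, bestd = None, None
        for j, (r, c) in enumerate(truth):
            if j in taken:
                continue
            d = math.hypot(r - y, c - x)
            if d <= radius and (bestd is None or d < bestd):
                best, bestd = j, d
        if best is not None:
            taken.add(best)
            tp += 1
    return tp


class TestMatching:
    def test_perfect_match(self):
        truth = [(5, 5), (10, 12)]
        pred = ParticleSet(particles=[(5, 5, 0.9), (12, 10, 0.8)])
        rep = match_precision_recall(pred, truth, 3)
        assert rep.precision == 1.0 and rep.recall == 1.0 and rep.f1 == 1.0

    def test_empty_predictions_convention(self):
        rep = match_precision_recall(ParticleSet(particles=[]), [(1, 1)], 3)
        assert rep.precision == 0.0 and rep.recall == 0.0

    def test_hand_worked_example(self):
        pred = ParticleSet(particles=[(0, 0, 0.9), (10, 10, 0.8),
                                      (40, 40, 0.7)])
        truth = [(1, 1), (50, 50)]
        rep = match_precision_recall(pred, truth, 3)
        assert (rep.tp, rep.fp, rep.fn) == (1, 2, 1)
        assert rep.precision == pytest.approx(1 / 3)
        assert rep.recall == pytest.approx(1 / 2)

    def test_counts_always_consistent(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            npred, ntruth = int(rng.integers(0, 15)), int(rng.integers(0, 15))
            pred = ParticleSet(particles=[
                (float(x), float(y), float(s)) for x, y, s in
                zip(rng.uniform(0, 30, npred), rng.uniform(0, 30, npred),
                    rng.uniform(0.1, 1, npred))])
            truth = [(float(r), float(c)) for r, c in
                     zip(rng.uniform(0, 30, ntruth), rng.uniform(0, 30, ntruth))]
            rep = match_precision_recall(pred, truth, 4.0)
            assert rep.tp + rep.fn == len(truth)
            assert rep.tp + rep.fp == len(pred.particles)
            assert rep.tp == brute_force_match(pred.particles, truth, 4.0)


class TestPSNR:
    def test_identical_images_sentinel(self):
        a = np.random.default_rng(0).uniform(size=(8, 8))
        assert psnr(a, a) == math.inf

    def test_mse_equal_to_range_squared_is_zero_db(self):
        ref = np.zeros((4, 4))
        ref[0, 0] = 1.0       # range 1
        test = ref + 1.0      # MSE 1
        assert psnr(test, ref) == pytest.approx(0.0)

    def test_constant_offset_twenty_db(self):
        ref = np.zeros((10, 10))
        ref[::2, :] = 1.0
        assert psnr(ref + 0.1, ref) == pytest.approx(20.0)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.ones((4, 4)), np.ones((4, 4)))


class TestFSC:
    def test_self_correlation_is_one(self):
        v = np.random.default_rng(0).normal(size=(32, 32, 32))
        _, vals = fsc(v, v)
        np.testing.assert_allclose(vals, 1.0, atol=1e-6)

    def test_anticorrelation_is_minus_one(self):
        v = np.random.default_rng(1).normal(size=(32, 32, 32))
        _, vals = fsc(v, -v)
        np.testing.assert_allclose(vals, -1.0, atol=1e-6)

    def test_independent_noise_decorrelated(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(64, 64, 64))
        b = rng.normal(size=(64, 64, 64))
        radii, vals = fsc(a, b)
        # shells with many voxels: skip the DC/low shells
        assert np.all(np.abs(vals[4:]) < 0.1)

    def test_resolution_cutoff(self):
        # a curve crossing 0.143 between shells maps to the interpolated freq
        radii = np.array([0.1, 0.2, 0.3])
        vals = np.array([0.9, 0.5, 0.1])
        res = fsc_resolution(radii, vals, voxel_size=1.0)
        f = 0.2 + 0.1 * (0.5 - 0.143) / (0.5 - 0.1)
        assert res == pytest.approx(1.0 / f)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fsc(np.zeros((8, 8, 8)), np.zeros((8, 8, 4)))


class TestPrior:
    def test_direct_arithmetic(self):
        assert estimate_prior(200, 100, 1024 ** 2) == \
            pytest.approx(200 * 100 / 1024 ** 2)

    def test_single_pixel(self):
        assert estimate_prior(1, 1, 4096) == pytest.approx(1 / 4096)

    def test_clipping_engages(self):
        assert estimate_prior(1000, 1000, 1000) == 0.49

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            estimate_prior(0, 10, 100)


class TestIO:
    def test_mrc_roundtrip_bitexact(self, tmp_path):
        data = np.random.default_rng(0).normal(size=(128, 128)) \
            .astype(np.float32)
        mg = Micrograph(data, pixel_size=1.37)
        path = tmp_path / "img.mrc"
        write_micrograph(mg, path)
        back = read_micrograph(path)
        np.testing.assert_array_equal(back.data.astype(np.float32), data)
        assert back.pixel_size == pytest.approx(1.37, rel=1e-6)

    def test_tiff_roundtrip(self, tmp_path):
        data = np.random.default_rng(1).normal(size=(32, 48)).astype(np.float32)
        path = tmp_path / "img.tif"
        write_micrograph(Micrograph(data), path)
        np.testing.assert_allclose(read_micrograph(path).data, data)

    def test_non_mrc_rejected(self, tmp_path):
        path = tmp_path / "bogus.mrc"
        path.write_bytes(b"\x00" * 2048)
        with pytest.raises(ValueError, match="MAP"):
            read_micrograph(path)

    def test_coords_roundtrip_with_header(self, tmp_path):
        ps = ParticleSet(particles=[(3, 7, 0.9), (10, 2, 0.5)])
        path = tmp_path / "picks.coords"
        write_coords(ps, path)
        back = read_coords(path)
        assert back == [(7.0, 3.0), (2.0, 10.0)]   # (row, col) pairs

    def test_box_center_conversion(self, tmp_path):
        path = tmp_path / "p.box"
        path.write_text("10\t20\t8\t8\n")
        assert read_coords(path) == [(24.0, 14.0)]  # (row=y, col=x)

    def test_empty_coordinate_file(self, tmp_path):
        path = tmp_path / "empty.coords"
        path.write_text("")
        assert read_coords(path) == []


class TestBin:
    def test_factor_one_identity(self):
        a = np.random.default_rng(0).normal(size=(5, 7))
        np.testing.assert_array_equal(bin_image(a, 1), a)

    def test_constant_block(self):
        a = np.full((4, 4), 3.3)
        np.testing.assert_allclose(bin_image(a, 2), np.full((2, 2), 3.3))

    def test_mean_preserved_on_cropped_region(self):
        a = np.random.default_rng(1).normal(size=(17, 13))
        out = bin_image(a, 4)
        assert out.mean() == pytest.approx(a[:16, :12].mean(), abs=1e-12)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            bin_image(np.zeros((4, 4)), 0)
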