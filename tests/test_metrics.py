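import numpy as np
import pytest
from scipy import stats

from dbtpre.metrics import (contrast, extract_profiles, glcm, glcm_features,
                            gumbel_fit, homogeneity, max_adjacent_variation,
                            mscn, pearson_r, piqe, plotting_positions,
                            streak_statistic)
from dbtpre.metrics.piqe import BLOCK_NOISE


def _breast_like(shape=(128, 128)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    disc = np.clip(1 - ((yy - shape[0] / 2) / (0.45 * shape[0])) ** 2
                   - (xx / (0.85 * shape[1])) ** 2, 0, None)
    return disc + 0.05 * disc * np.sin(xx / 5.0)


class TestMSCN:
    def test_constant_image_maps_to_zero(self):
        assert np.allclose(mscn(np.full((40, 40), 3.0)), 0.0, atol=1e-12)

    def test_affine_invariance_with_rescaled_constant(self, rng):
        img = rng.random((48, 48))
        a, b = 12.5, -3.0
        ref = mscn(img, c=0.5)
        scaled = mscn(a * img + b, c=0.5 * a)
        assert np.allclose(ref, scaled, atol=1e-10)

    def test_interior_pixel_windowed_loop_oracle(self):
        img = np.add.outer(np.arange(40.0), np.arange(40.0) ** 1.5 / 10)
        out = mscn(img)
        # brute-force local Gaussian stats at one interior pixel
        sigma, rad = 7.0 / 6.0, 3
        offs = np.arange(-rad, rad + 1)
        k1 = np.exp(-0.5 * (offs / sigma) ** 2)
        k1 /= k1.sum()
        k2 = np.outer(k1, k1)
        r, c = 20, 20
        win = img[r - rad : r + rad + 1, c - rad : c + rad + 1]
        mu = (k2 * win).sum()
        var = max((k2 * win * win).sum() - mu * mu, 0.0)
        expected = (img[r, c] - mu) / (np.sqrt(var) + 1.0)
        assert out[r, c] == pytest.approx(expected, abs=1e-10)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            mscn(np.zeros((16, 16)))


class TestPIQE:
    def test_score_bounded(self, rng):
        for img in (rng.random((64, 64)), _breast_like((64, 64)),
                    np.add.outer(np.arange(64.0), np.arange(64.0))):
            assert 0.0 <= piqe(img).score <= 100.0

    def test_noise_strictly_raises_score(self, rng):
        base = _breast_like()
        noisy = base + rng.normal(0, 0.2 * base.max(), base.shape)
        assert piqe(noisy).score > piqe(base).score

    def test_iid_noise_blocks_labeled_noise(self, rng):
        res = piqe(rng.normal(size=(128, 128)))
        active = res.activity_map.sum()
        labeled = (res.block_class_map == BLOCK_NOISE).sum()
        assert active > 0
        assert labeled / active >= 0.5

    def test_score_monotone_in_noise_level(self, rng):
        base = _breast_like()
        scores = [piqe(base + rng.normal(0, s * base.max(), base.shape)).score
                  for s in (0.0, 0.1, 0.3)]
        assert scores[0] < scores[1] <= scores[2]

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            piqe(np.zeros((8, 8)))


class TestGLCM:
    def test_constant_image_single_diagonal_entry(self):
        T = glcm(np.full((8, 8), 5.0), levels=16)
        assert T[0, 0] == pytest.approx(1.0)
        assert T.sum() == pytest.approx(1.0)

    def test_matrix_normalized_and_symmetric(self, rng):
        T = glcm(rng.random((32, 32)), levels=32)
        assert T.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(T, T.T, atol=1e-12)

    def test_three_by_three_pair_enumeration_oracle(self):
        img = np.array([[0, 1, 1], [2, 0, 1], [0, 2, 2]], dtype=np.int32)
        T = glcm(img, levels=3)
        # enumerate all 8-neighbor ordered pairs by brute force
        counts = np.zeros((3, 3))
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1),
                   (0, -1), (-1, 0), (-1, -1), (-1, 1)]
        for i in range(3):
            for j in range(3):
                for di, dj in offsets:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < 3 and 0 <= nj < 3:
                        counts[img[i, j], img[ni, nj]] += 1
        assert np.allclose(T, counts / counts.sum(), atol=1e-12)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((0, 0)))


class TestTextureFeatures:
    def test_constant_image_extremes(self):
        T = glcm(np.full((8, 8), 1.0), levels=8)
        assert homogeneity(T) == pytest.approx(1.0)
        assert contrast(T) == pytest.approx(0.0)

    def test_adjacent_mass_values(self):
        T1 = np.array([[0.0, 0.5], [0.5, 0.0]])  # all mass at |i-j|=1
        assert homogeneity(T1) == pytest.approx(0.5)
        T2 = np.zeros((3, 3))
        T2[0, 2] = T2[2, 0] = 0.5  # all mass at |i-j|=2
        assert contrast(T2) == pytest.approx(4.0)

    def test_loop_oracles(self, rng):
        T = rng.random((6, 6))
        T = (T + T.T) / 2
        T /= T.sum()
        h = sum(T[i, j] / (1 + abs(i - j)) for i in range(6) for j in range(6))
        c = sum((i - j) ** 2 * T[i, j] for i in range(6) for j in range(6))
        assert homogeneity(T) == pytest.approx(h, abs=1e-12)
        assert contrast(T) == pytest.approx(c, abs=1e-12)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            homogeneity(np.ones((3, 3)))
        with pytest.raises(ValueError):
            contrast(np.ones((3, 3)))

    def test_noise_moves_features_monotonically(self, rng):
        base = _breast_like((96, 96))
        homs, cons = [], []
        for s in (0.0, 0.05, 0.15):
            f = glcm_features(base + rng.normal(0, s * base.max(), base.shape),
                              levels=64)
            homs.append(f.homogeneity)
            cons.append(f.contrast)
        assert homs[0] > homs[1] > homs[2]
        assert cons[0] < cons[1] < cons[2]


class TestProfiles:
    def test_constant_window(self):
        prof = extract_profiles(np.ones((64, 64)), (2, 3), width=30, length=24)
        assert prof.shape == (24, 30)
        assert np.all(prof == 1.0)

    def test_transpose_oracle(self, rng):
        img = rng.random((64, 80))
        a = extract_profiles(img, (5, 7), width=30, length=24, sweep_axis=1)
        b = extract_profiles(img.T, (7, 5), width=30, length=24, sweep_axis=0)
        assert np.array_equal(a, b)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            extract_profiles(np.ones((32, 32)), (10, 10), width=30, length=24)


class TestMaxAdjacentVariation:
    def test_examples(self):
        assert max_adjacent_variation(np.ones(10)) == 0.0
        assert max_adjacent_variation([0, 1, 3, 2]) == 2.0

    def test_loop_oracle(self, rng):
        p = rng.normal(size=50)
        oracle = max(abs(p[k + 1] - p[k]) for k in range(49))
        assert max_adjacent_variation(p) == pytest.approx(oracle, abs=1e-15)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            max_adjacent_variation([1.0])


class TestGumbel:
    def test_first_plotting_position(self):
        q = plotting_positions(29)
        assert q[0] == pytest.approx(0.5 / 29)
        assert np.all(np.diff(q) > 0)
        assert np.all((q > 0) & (q < 1))

    def test_exact_quantile_line_recovery(self):
        u = -np.log(-np.log(plotting_positions(29)))
        maxima = 2.0 + 0.5 * u
        fit = gumbel_fit(maxima)
        assert fit.location == pytest.approx(2.0, abs=1e-9)
        assert fit.scale == pytest.approx(0.5, abs=1e-9)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        locs, rs = [], []
        for _ in range(500):
            sample = stats.gumbel_r.rvs(loc=0.05, scale=0.01, size=29,
                                        random_state=rng)
            fit = gumbel_fit(sample)
            locs.append(fit.location)
            rs.append(fit.pearson_r)
        assert np.mean(locs) == pytest.approx(0.05, rel=0.10)
        assert np.mean(rs) > 0.9

    def test_too_few_maxima_rejected(self):
        with pytest.raises(ValueError):
            gumbel_fit([1.0, 2.0])

    def test_streak_statistic_on_ripple_vs_smooth(self, rng):
        smooth = np.add.outer(np.linspace(0, 1, 64), np.linspace(0, 1, 64))
        ripple = smooth + 0.2 * np.sin(np.arange(64) * 2.0)[None, :]
        s_fit = streak_statistic(smooth + rng.normal(0, 1e-4, smooth.shape),
                                 (10, 10))
        r_fit = streak_statistic(ripple + rng.normal(0, 1e-4, smooth.shape),
                                 (10, 10))
        assert r_fit.mean_max > s_fit.mean_max
        assert len(r_fit.maxima) == 29


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.random(20)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        xm, ym = x.mean(), y.mean()
        oracle = (np.sum((x - xm) * (y - ym))
                  / np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)))
        r, p = pearson_r(x, y)
        assert r == pytest.approx(oracle, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))
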