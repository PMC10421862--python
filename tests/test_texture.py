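import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_glcm
from deltarad import texture as tx


class TestGLCM:
    def test_matches_brute_force_oracle_on_random_slices(self):
        rng = np.random.default_rng(42)
        offsets = tx.DEFAULT_OFFSETS
        for _ in range(30):
            h, w = rng.integers(3, 9, size=2)
            sl = rng.normal(50, 20, size=(h, w))
            region = rng.random((h, w)) < 0.7
            if region.sum() < 2:
                continue
            g = tx.compute_glcm(sl, region, levels=8, offsets=offsets)
            for k, off in enumerate(offsets):
                oracle = brute_force_glcm(sl, region, 8, off)
                np.testing.assert_allclose(g.probabilities[k], oracle,
                                           atol=1e-12)

    def test_two_by_two_worked_example(self):
        g = tx.compute_glcm(np.array([[1, 1], [1, 2]]), np.ones((2, 2)),
                            levels=2, offsets=((0, 1),))
        expected = np.array([[0.5, 0.25], [0.25, 0.0]])
        np.testing.assert_allclose(g.probabilities[0], expected)

    def test_vertical_stripes_horizontal_offset_all_off_diagonal(self):
        sl = np.tile([0.0, 10.0], (4, 3))
        g = tx.compute_glcm(sl, np.ones_like(sl), levels=2, offsets=((0, 1),))
        assert np.trace(g.probabilities[0]) == 0.0
        assert g.probabilities[0].sum() == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        sl = rng.normal(size=(6, 6))
        g = tx.compute_glcm(sl, np.ones((6, 6)), levels=4)
        np.testing.assert_allclose(g.probabilities.sum(axis=(1, 2)),
                                   np.ones(len(g.offsets)))

    def test_too_small_region_flagged_missing(self):
        g = tx.compute_glcm(np.ones((3, 3)), np.eye(3) * 0, levels=4)
        assert g.missing


class TestHaralick:
    def test_constant_region_closed_forms(self):
        g = tx.compute_glcm(np.full((5, 5), 42.0), np.ones((5, 5)), levels=8)
        f = tx.haralick_features(g)
        assert f["entropy"] == 0.0
        assert f["asm"] == 1.0
        assert f["contrast"] == 0.0

    def test_uniform_glcm_entropy_maximal(self):
        for ng in (2, 4, 8):
            g = tx.GLCMMatrix(np.full((1, ng, ng), 1.0 / ng ** 2), ng, ((0, 1),))
            f = tx.haralick_features(g)
            assert f["entropy"] == pytest.approx(2 * np.log2(ng))
            assert f["asm"] == pytest.approx(1.0 / ng ** 2)

    def test_entropy_nonnegative_and_bounded_by_uniform(self):
        rng = np.random.default_rng(3)
        ng = 6
        for _ in range(20):
            P = rng.random((ng, ng))
            P = P + P.T
            P /= P.sum()
            f = tx.haralick_features(tx.GLCMMatrix(P[None], ng, ((0, 1),)))
            assert 0.0 <= f["entropy"] <= 2 * np.log2(ng) + 1e-9

    def test_missing_glcm_gives_nan_features(self):
        g = tx.GLCMMatrix(np.zeros((1, 4, 4)), 4, ((0, 1),), missing=True)
        assert all(np.isnan(v) for v in tx.haralick_features(g).values())

    def test_per_pixel_map_agrees_with_region_glcm_when_window_covers_it(self):
        """A window larger than the region reproduces the region-level values."""
        rng = np.random.default_rng(5)
        sl = rng.normal(50, 15, size=(5, 5))
        region = np.ones((5, 5), bool)
        offs = ((0, 1),)
        maps = tx.haralick_maps(sl, region, levels=8, offsets=offs, window=11)
        g = tx.compute_glcm(sl, region, levels=8, offsets=offs)
        P = g.probabilities[0]
        ii, jj = np.nonzero(P)
        expected = tx._haralick_sparse(ii, jj, P[ii, jj], 8)
        center = maps["entropy"][2, 2]
        assert center == pytest.approx(expected[tx.HARALICK_NAMES.index("entropy")])


class TestLaws:
    def test_kernel_count_and_l5l5_sum(self):
        kernels = tx.laws_kernels()
        assert len(kernels) == 25
        assert kernels["L5L5"].sum() == 256.0

    def test_zero_sum_kernels_null_on_constant_image(self):
        sl = np.full((12, 12), 7.0)
        maps = tx.laws_response_maps(sl)
        for name, m in maps.items():
            if name != "L5L5":
                np.testing.assert_allclose(m, 0.0, atol=1e-9)

    def test_laplacian_variant_zero_on_constant_image(self):
        maps = tx.laws_laplacian_maps(np.full((12, 12), 7.0))
        assert len(maps) == 25
        for m in maps.values():
            np.testing.assert_allclose(m, 0.0, atol=1e-9)

    def test_log_and_laws_commute_in_interior(self):
        rng = np.random.default_rng(6)
        sl = rng.normal(size=(32, 32))
        a = tx.laws_laplacian_maps(sl)["E5S5"]
        b = tx._conv_reflect(tx.laws_response_maps(sl)["E5S5"],
                             tx.log_kernel(1.0))
        np.testing.assert_allclose(a[8:-8, 8:-8], b[8:-8, 8:-8], atol=1e-6)


class TestGabor:
    def test_bank_size(self):
        assert len(tx.gabor_bank()) == 48

    def test_constant_image_zero_response(self):
        maps = tx.gabor_response_maps(np.full((16, 16), 55.0))
        assert len(maps) == 48
        for m in maps.values():
            np.testing.assert_allclose(m, 0.0, atol=1e-6)

    def test_rotating_grating_permutes_orientation_channels(self):
        x = np.arange(48)
        grating = np.tile(np.sin(2 * np.pi * x / 8), (48, 1))
        maps = tx.gabor_response_maps(grating)
        rot = tx.gabor_response_maps(np.rot90(grating).copy())
        inner = slice(16, 32)
        r0 = maps["o0_w8"][inner, inner].mean()
        r4 = rot["o4_w8"][inner, inner].mean()   # theta + pi/2 channel
        assert r0 == pytest.approx(r4, rel=0.05)
        # the aligned channel dominates the orthogonal one
        assert r0 > 3 * maps["o4_w8"][inner, inner].mean()


class TestSummaries:
    def test_hand_arithmetic_example(self):
        st = tx.five_stats(np.array([1.0, 2.0, 3.0]))
        assert st["mean"] == 2.0
        assert st["median"] == 2.0
        assert st["sd"] == pytest.approx(1.0)

    def test_constant_pool_conventions(self):
        st = tx.five_stats(np.full(10, 4.2))
        assert st == {"mean": pytest.approx(4.2), "median": pytest.approx(4.2),
                      "sd": 0.0, "skewness": 0.0, "kurtosis": 0.0}

    def test_moment_definitions_match_scipy(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=200)
        st = tx.five_stats(v)
        assert st["sd"] == pytest.approx(v.std(ddof=1))
        assert st["skewness"] == pytest.approx(stats.skew(v, bias=True))
        assert st["kurtosis"] == pytest.approx(
            stats.kurtosis(v, fisher=True, bias=True))

    def test_empty_pool_all_nan(self):
        st = tx.five_stats(np.array([]))
        assert all(np.isnan(v) for v in st.values())


class TestFullExtraction:
    def test_feature_count_identity(self):
        names = tx.filter_names()
        assert len(names) == 13 + 25 + 25 + 48 == 111
        assert len(names) * len(tx.STAT_NAMES) == 555

    def test_extraction_counts_and_determinism(self, phantom, region_pair):
        volume, _ = phantom
        f1 = tx.extract_texture_features(volume, region_pair)
        stats_keys = [k for k in f1 if not k.startswith("_")]
        assert sum(k.endswith("_tumor") for k in stats_keys) == 555
        assert sum(k.endswith("_rim") for k in stats_keys) == 555
        assert len(stats_keys) == 1110
        f2 = tx.extract_texture_features(volume, region_pair)
        assert f1 == f2

    def test_higher_heterogeneity_raises_tumor_entropy(self, tiny_config):
        """Rising internal heterogeneity elevates intratumoral Haralick entropy."""
        import dataclasses

        from deltarad.regions import extract_peritumoral_rim
        from deltarad.synthetic import generate_phantom

        lo = dataclasses.replace(tiny_config, texture_amp_range=(2.0, 2.0),
                                 texture_delta_sd=1e-9)
        hi = dataclasses.replace(tiny_config, texture_amp_range=(20.0, 20.0),
                                 texture_delta_sd=1e-9)
        means = []
        for cfg in (lo, hi):
            vals = []
            for i in range(2):
                vol, mask = generate_phantom(cfg, i, "pre")
                pair = extract_peritumoral_rim(vol, mask)
                feats = tx.extract_texture_features(vol, pair)
                vals.append(feats["haralick_entropy_mean_tumor"])
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_translation_equivariance_of_filter_responses(self):
        rng = np.random.default_rng(9)
        sl = rng.normal(50, 10, size=(40, 40))
        shifted = np.roll(sl, (3, 0), axis=(0, 1))
        for fam in (tx.laws_response_maps, tx.laws_laplacian_maps):
            a, b = fam(sl)["E5L5"], fam(shifted)["E5L5"]
            np.testing.assert_allclose(np.roll(a, (3, 0), axis=(0, 1))[12:-12, 12:-12],
                                       b[12:-12, 12:-12], atol=1e-8)
        ga = tx.gabor_response_maps(sl)["o2_w4"]
        gb = tx.gabor_response_maps(shifted)["o2_w4"]
        np.testing.assert_allclose(np.roll(ga, (3, 0), axis=(0, 1))[12:-12, 12:-12],
                                   gb[12:-12, 12:-12], atol=1e-6)
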