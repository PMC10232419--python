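import numpy as np
import pytest

from bsscatter.correction import (
    CorrectionConfig,
    binarize_otsu,
    downsample,
    estimate_scatter,
    extract_samples,
    otsu_threshold,
    upsample,
)
from bsscatter.geometry import AcquisitionGeometry, BeamStopperSpec, project_bs_mask
from bsscatter.simulate import ScatterModelParams, default_chest_phantom, simulate_acquisition


def brute_force_otsu(img):
    """Exhaustive 256-bin between-class-variance maximisation.

    Returns the best threshold, a function evaluating the between-class
    variance of the split induced by an arbitrary threshold, and the
    maximal variance found.
    """
    hist, edges = np.histogram(img.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2

    def var_at(i):
        w0, w1 = hist[:i].sum(), hist[i:].sum()
        if w0 == 0 or w1 == 0:
            return -np.inf
        m0 = (hist[:i] * centers[:i]).sum() / w0
        m1 = (hist[i:] * centers[i:]).sum() / w1
        return w0 * w1 * (m0 - m1) ** 2

    best, best_t = -np.inf, centers[0]
    for i in range(1, 256):
        v = var_at(i)
        if v > best:
            best, best_t = v, centers[i - 1]

    def var_of_split(threshold):
        return var_at(int(np.searchsorted(centers, threshold, side="right")))

    return best_t, var_of_split, best


class TestDownsample:
    def test_identity_factor(self, rng):
        img = rng.normal(size=(13, 17))
        np.testing.assert_array_equal(downsample(img, 1), img)

    def test_constant_block(self):
        out = downsample(np.full((8, 8), 5.0), 8)
        assert out.shape == (1, 1) and out[0, 0] == 5.0

    def test_checkerboard_block_mean(self):
        board = np.indices((16, 16)).sum(axis=0) % 2
        np.testing.assert_array_equal(downsample(board, 8), np.full((2, 2), 0.5))

    def test_partial_trailing_blocks_average_available(self):
        img = np.arange(10, dtype=float)[None, :].repeat(4, axis=0)
        out = downsample(img, 4)
        # last block has two columns: mean of 8 and 9
        np.testing.assert_allclose(out[0], [1.5, 5.5, 8.5])

    def test_mean_preservation(self, rng):
        img = rng.uniform(size=(24, 32))
        assert downsample(img, 8).mean() == pytest.approx(img.mean(), rel=1e-12)

    def test_oversized_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.ones((4, 4)), 5)


class TestUpsample:
    def test_constant_preserved(self):
        out = upsample(np.full((4, 4), 2.5), (32, 32))
        np.testing.assert_allclose(out, 2.5, rtol=1e-12)

    def test_single_pixel_uniform_fill(self):
        np.testing.assert_array_equal(upsample(np.array([[3.0]]), (5, 7)), 3.0)

    def test_bandlimited_roundtrip(self, rng):
        # a field much smoother than the block size survives the
        # downsample/upsample roundtrip to ~1% RMS
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.normal(size=(128, 128)), 32.0, mode="nearest")
        img -= img.mean()
        round_ = upsample(downsample(img, 8), img.shape)
        err = (round_ - img)[8:-8, 8:-8]  # away from boundary extrapolation
        rms = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(img**2))
        assert rms < 0.01

    def test_shrinking_rejected(self):
        with pytest.raises(ValueError):
            upsample(np.ones((8, 8)), (4, 4))


class TestOtsu:
    def test_bimodal_threshold_separates_classes(self):
        img = np.concatenate([np.full(40, 10.0), np.full(60, 200.0)]).reshape(10, 10)
        t = otsu_threshold(img)
        assert 10.0 < t < 200.0
        mask = binarize_otsu(img)
        np.testing.assert_array_equal(mask, img == 200.0)

    def test_matches_brute_force_on_random_images(self, rng):
        # the chosen split must achieve the exhaustive-search maximum of the
        # between-class variance (thresholds may differ only on exact
        # floating-point ties between adjacent splits)
        for _ in range(100):
            img = rng.uniform(0, rng.uniform(1, 100), size=(32, 32))
            t = otsu_threshold(img)
            t_ref, var_of_split, var_max = brute_force_otsu(img)
            assert var_of_split(t) >= var_max * (1 - 1e-9)

    def test_inverted_image_complementary_mask(self, rng):
        img = np.where(rng.uniform(size=(20, 20)) > 0.5, 5.0, 1.0)
        np.testing.assert_array_equal(binarize_otsu(img), ~binarize_otsu(-img))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.ones((8, 8)))


def lattice_geom(n=160, pixel=1.0):
    """Plate at the detector (m=1): 40 px pitch, 20 px hole diameter."""
    return AcquisitionGeometry(
        sdd_mm=1000.0,
        sample_to_detector_mm=0.0,
        bs_to_source_mm=1000.0,
        focal_spot_mm=0.0,
        detector_rows=n,
        detector_cols=n,
        pixel_mm=pixel,
    )


@pytest.fixture()
def lattice_mask():
    g = lattice_geom()
    bs = BeamStopperSpec(hole_diameter_mm=20.0, hole_pitch_mm=40.0)
    return g, bs, project_bs_mask(g, bs) > 0.5


class TestExtractSamples:
    def test_constant_image_constant_samples(self, lattice_mask):
        g, bs, mask = lattice_mask
        s = extract_samples(np.full(mask.shape, 7.0), mask, g, bs)
        assert len(s.subset("hole")) >= 9
        assert len(s.subset("shadow")) >= 6
        np.testing.assert_allclose(s.values, 7.0)

    def test_image_equal_mask_separates_exactly(self, lattice_mask):
        g, bs, mask = lattice_mask
        s = extract_samples(mask.astype(float), mask, g, bs)
        np.testing.assert_allclose(s.subset("hole").values, 1.0)
        np.testing.assert_allclose(s.subset("shadow").values, 0.0)

    def test_circles_inside_image(self, lattice_mask):
        g, bs, mask = lattice_mask
        s = extract_samples(mask.astype(float), mask, g, bs)
        r = s.circle_radius_px
        assert np.all(s.rows - r >= -0.5) and np.all(s.rows + r <= mask.shape[0] - 0.5)
        assert np.all(s.cols - r >= -0.5) and np.all(s.cols + r <= mask.shape[1] - 0.5)

    def test_sample_radius_below_hole_radius(self, lattice_mask):
        g, bs, mask = lattice_mask
        s = extract_samples(mask.astype(float), mask, g, bs, radius_fraction=0.6)
        assert s.circle_radius_px < 10.0  # projected hole radius in px

    def test_shadow_samples_match_reduced_scatter(self, desk_acq, desk_geom, desk_bs):
        # in a noiseless simulation the shadow disks carry the ideal reduced
        # scatter with no primary leakage
        bs_img = desk_acq.bs_projection.data
        mask = binarize_otsu(bs_img)
        s = extract_samples(bs_img, mask, desk_geom, desk_bs).subset("shadow")
        from bsscatter.correction import _disk_mean

        ref = np.array(
            [
                _disk_mean(desk_acq.scatter_reduced_gt.data, r, c, s.circle_radius_px)
                for r, c in zip(s.rows, s.cols)
            ]
        )
        assert np.max(np.abs(s.values - ref) / ref) < 0.005

    def test_mismatched_shapes_rejected(self, lattice_mask):
        g, bs, mask = lattice_mask
        with pytest.raises(ValueError):
            extract_samples(np.ones((10, 10)), mask, g, bs)


class TestEstimateScatter:
    def test_zero_scatter_identity_limit(self, desk_geom, desk_bs):
        ph = default_chest_phantom(desk_geom)
        acq = simulate_acquisition(ph, desk_geom, desk_bs, ScatterModelParams(amplitude=0.0))
        res = estimate_scatter(
            acq.full_field.data,
            acq.bs_projection.data,
            desk_geom,
            desk_bs,
            CorrectionConfig(downsample_factor=1),
        )
        assert np.max(np.abs(res.scatter_estimate)) < 1e-6
        np.testing.assert_allclose(res.corrected, acq.full_field.data, atol=1e-6)

    def test_constant_scatter_recovered_exactly(self, lattice_mask):
        # spatially constant true scatter s0 and reduced scatter s0': the
        # algebra of the five steps returns exactly s0
        g, bs, mask = lattice_mask
        s0, s0p = 0.4, 0.1
        primary = np.full(mask.shape, 1.0)
        i_ff = primary + s0
        i_bs = np.where(mask, primary + s0p, s0p)
        res = estimate_scatter(i_ff, i_bs, g, bs, CorrectionConfig(downsample_factor=1, loess_span=0.3))
        np.testing.assert_allclose(res.scatter_estimate, s0, rtol=1e-9)
        np.testing.assert_allclose(res.corrected, primary, atol=1e-8)

    def test_quadratic_scatter_end_to_end_exact(self, lattice_mask):
        # globally quadratic scatter fields propagate exactly through the
        # LOESS steps (quadratic reproduction survives the whole chain);
        # a harmonic quadratic makes the circle means exact by symmetry
        g, bs, mask = lattice_mask
        n = mask.shape[0]
        rr, cc = np.mgrid[0:n, 0:n] / n
        scatter = 0.3 + 0.1 * rr - 0.05 * cc + 0.2 * rr * cc + 0.1 * (rr**2 - cc**2)
        reduced = 0.25 * scatter
        primary = np.full(mask.shape, 1.0)
        i_ff = primary + scatter
        i_bs = np.where(mask, primary, 0.0) + reduced
        res = estimate_scatter(i_ff, i_bs, g, bs, CorrectionConfig(downsample_factor=1, loess_span=0.9))
        rel = np.abs(res.scatter_estimate - scatter) / scatter
        assert rel.max() < 1e-6

    def test_quadratic_scatter_curvature_bound(self, lattice_mask):
        # non-harmonic quadratics pick up the circle-mean curvature bias,
        # bounded by (1 + s'/s) * (r^2 / 8) * |laplacian|
        g, bs, mask = lattice_mask
        n = mask.shape[0]
        rr, cc = np.mgrid[0:n, 0:n] / n
        scatter = 0.3 + 0.1 * rr - 0.05 * cc + 0.2 * rr * cc + 0.1 * cc**2
        i_ff = 1.0 + scatter
        i_bs = np.where(mask, 1.0, 0.0) + 0.25 * scatter
        res = estimate_scatter(i_ff, i_bs, g, bs, CorrectionConfig(downsample_factor=1, loess_span=0.9))
        r_px = res.samples.circle_radius_px
        bound = 1.25 * (r_px**2 / 8.0) * (0.2 / n**2) / scatter.min()
        rel = np.abs(res.scatter_estimate - scatter) / scatter
        assert rel.max() < 2.0 * bound

    def test_conservation_pre_clamp(self, desk_correction, desk_acq):
        lhs = desk_correction.corrected_raw + desk_correction.scatter_estimate_raw
        np.testing.assert_allclose(lhs, desk_acq.full_field.data, rtol=0, atol=1e-9)

    def test_scatter_estimate_nonnegative(self, desk_correction):
        assert desk_correction.scatter_estimate.min() >= 0.0

    def test_scatter_estimate_low_frequency(self, lattice_mask):
        # with a downsampled fit, the upsampled map keeps >=99% of its
        # spectral energy below the block Nyquist
        g, bs, mask = lattice_mask
        n = mask.shape[0]
        rr, cc = np.mgrid[0:n, 0:n] / n
        scatter = 0.4 + 0.2 * np.cos(2 * np.pi * rr) * np.cos(2 * np.pi * cc)
        primary = np.full(mask.shape, 1.0)
        i_ff = primary + scatter
        i_bs = np.where(mask, primary, 0.0) + 0.25 * scatter
        f = 4
        res = estimate_scatter(i_ff, i_bs, g, bs, CorrectionConfig(downsample_factor=f, loess_span=0.5))
        spec = np.abs(np.fft.fft2(res.scatter_estimate - res.scatter_estimate.mean())) ** 2
        fr = np.fft.fftfreq(n)
        fy, fx = np.meshgrid(fr, fr, indexing="ij")
        below = (np.abs(fy) <= 0.5 / f) & (np.abs(fx) <= 0.5 / f)
        assert spec[below].sum() / spec.sum() >= 0.99

    def test_radius_fraction_stability(self, desk_acq, desk_geom, desk_bs):
        # shrinking the penumbra-exclusion radius changes the noiseless
        # scatter estimate only marginally
        kw = dict(downsample_factor=1)
        a = estimate_scatter(desk_acq.full_field.data, desk_acq.bs_projection.data,
                             desk_geom, desk_bs, CorrectionConfig(radius_fraction=0.6, **kw))
        b = estimate_scatter(desk_acq.full_field.data, desk_acq.bs_projection.data,
                             desk_geom, desk_bs, CorrectionConfig(radius_fraction=0.3, **kw))
        denom = np.sqrt(np.mean(a.scatter_estimate**2))
        drift = np.sqrt(np.mean((a.scatter_estimate - b.scatter_estimate) ** 2)) / denom
        assert drift < 0.02

    def test_shape_mismatch_rejected(self, desk_geom, desk_bs):
        with pytest.raises(ValueError):
            estimate_scatter(np.ones((10, 10)), np.ones((12, 10)), desk_geom, desk_bs)
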