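"""Otsu segmentation, region statistics and FWHM measurement.

The Otsu oracle is an exhaustive search over histogram thresholds,
independent of skimage; region means are recomputed by explicit pixel
iteration; FWHM oracle values come from fine-grid (<=1 nm) numerical
convolution of a disk with a Gaussian, computed offline with scipy on a
continuous grid and frozen here.
"""

import numpy as np
import pytest

from endoph import (
    CONFOCAL,
    STED,
    ImagePair,
    background_stats,
    measure_fwhm,
    otsu_threshold,
    region_stats,
    render_image_pair,
    segment_endosomes,
)

from conftest import single_endosome_scene

# fine-grid convolution oracle (1 nm / 0.5 nm grids):
FWHM_DISK40_PSF250 = 251.1  # nm
FWHM_DISK40_PSF50 = 55.9    # nm


def _otsu_brute_force(image, nbins=256):
    """Exhaustive-search oracle: best class-boundary edge of the 256-bin
    histogram by direct evaluation of every candidate cut (plain loops,
    independent of the vectorised implementation)."""
    counts, edges = np.histogram(np.asarray(image).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_edge = -np.inf, None
    for i in range(1, nbins):
        lo_c, hi_c = counts[:i], counts[i:]
        w0, w1 = lo_c.sum(), hi_c.sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float((lo_c * centers[:i]).sum()) / w0
        mu1 = float((hi_c * centers[i:]).sum()) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_edge = var, edges[i]
    return best_edge


class TestOtsu:
    def test_two_value_image(self):
        img = np.array([[10, 200], [10, 200], [10, 10]], dtype=np.uint8)
        thr = otsu_threshold(img)
        assert 10 < thr < 200

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """The returned threshold equals the exhaustive-search argmax of the
        between-class variance over every candidate histogram cut."""
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        assert otsu_threshold(img) == pytest.approx(_otsu_brute_force(img),
                                                    rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_agrees_with_skimage(self, seed):
        """Independent cross-check: the induced foreground partition matches
        skimage's Otsu (which assigns its returned value to the background)."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(100 + seed)
        img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        ours = img >= otsu_threshold(img)
        theirs = img > threshold_otsu(img, nbins=256)
        assert np.array_equal(ours, theirs)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 200, size=(16, 16)).astype(np.uint16)
        thr = otsu_threshold(img)
        assert otsu_threshold(img + 37) == pytest.approx(thr + 37, abs=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 7, dtype=np.uint8))


class TestSegmentEndosomes:
    def test_min_size_filter(self):
        """Components of sizes 3, 5 and 8 px above threshold: only the two
        with >= 5 px survive."""
        img = np.zeros((32, 32), dtype=np.uint8)
        img[2, 2:5] = 200          # 3 px -> dropped
        img[10, 10:15] = 200       # 5 px -> kept
        img[20:22, 20:24] = 200    # 8 px -> kept
        regions = segment_endosomes(img, threshold=100)
        assert len(regions) == 2
        assert np.all(regions.table["area_px"] >= 5)

    def test_square_centroid(self):
        img = np.zeros((21, 21), dtype=np.uint8)
        img[9:12, 9:12] = 255  # 9-px square centred at (10, 10)
        regions = segment_endosomes(img)
        assert len(regions) == 1
        row = regions.table.iloc[0]
        assert (row["cx"], row["cy"]) == (10.0, 10.0)

    def test_truth_count_and_centroids_on_synthetic_scene(
        self, small_pair, small_regions, small_scene
    ):
        """Well-separated synthetic endosomes: region count equals truth count
        and centroids match ground truth within 1 px."""
        _, truth = small_pair
        assert len(small_regions) == len(truth)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(small_regions.centroids()).query(
            truth[["x_px", "y_px"]].to_numpy()
        )
        assert d.max() <= 1.0

    def test_labels_consecutive(self, small_regions):
        labels = small_regions.table["label"].to_numpy()
        assert np.array_equal(labels, np.arange(1, len(labels) + 1))
        assert set(np.unique(small_regions.label_map)) == set([0, *labels])

    def test_affine_intensity_invariance(self, small_pair):
        """An order-preserving affine intensity map leaves the mask unchanged."""
        pair, _ = small_pair
        a = segment_endosomes(pair.dye)
        scaled = (pair.dye.astype(np.uint32) * 3 + 11).astype(np.uint32)
        b = segment_endosomes(scaled)
        assert np.array_equal(a.mask, b.mask)

    def test_empty_result_warns(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[0, 0] = 10  # single pixel above threshold < min_size
        with pytest.warns(UserWarning):
            regions = segment_endosomes(img, threshold=5)
        assert len(regions) == 0


class TestRegionStats:
    def test_mean_by_explicit_pixel_iteration(self, small_pair, small_regions):
        pair, _ = small_pair
        table = small_regions.table
        for _, row in table.iterrows():
            sel = small_regions.label_map == row["label"]
            expected_fp = pair.fp[sel].astype(float).mean()
            expected_dye = pair.dye[sel].astype(float).mean()
            assert row["mean_ch1"] == pytest.approx(expected_fp, rel=1e-12)
            assert row["mean_ch2"] == pytest.approx(expected_dye, rel=1e-12)

    def test_constant_region_and_channel_ratio(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[2:5, 2:5] = 200
        dye = np.full((10, 10), 30, dtype=np.uint16)
        fp = (dye * 2).astype(np.uint16)
        pair = ImagePair(fp=fp, dye=dye, pixel_size_nm=20.0)
        regions = segment_endosomes(labels, threshold=100)
        tab = region_stats(regions, pair)
        assert tab["mean_ch2"].iloc[0] == 30.0
        assert tab["mean_ch1"].iloc[0] / tab["mean_ch2"].iloc[0] == 2.0

    def test_dimension_mismatch_rejected(self, small_regions):
        bad = ImagePair(
            fp=np.zeros((8, 8), dtype=np.uint16),
            dye=np.zeros((8, 8), dtype=np.uint16),
            pixel_size_nm=20.0,
        )
        with pytest.raises(ValueError):
            region_stats(small_regions, bad)


class TestBackgroundStats:
    def test_uniform_background_recovered(self):
        img = np.full((64, 64), 23, dtype=np.uint16)
        img[30:33, 30:33] = 500
        pair = ImagePair(fp=img, dye=img, pixel_size_nm=20.0)
        regions = segment_endosomes(img)
        bg = background_stats(pair, regions, n_rois=10, roi_size=5, seed=1)
        assert bg["mean_dye"] == 23.0

    def test_endosome_to_background_contrast(self, small_pair, small_regions):
        """At default generator settings the dye-channel endosome mean is
        ~9-fold above 30 random background ROIs."""
        pair, _ = small_pair
        bg = background_stats(pair, small_regions, n_rois=30, roi_size=10, seed=2)
        fold = small_regions.table["mean_ch2"].mean() / bg["mean_dye"]
        assert 7.0 < fold < 11.0

    def test_infeasible_placement_raises(self):
        img = np.full((16, 16), 50, dtype=np.uint16)
        img[0, 0] = 0
        pair = ImagePair(fp=img, dye=img, pixel_size_nm=20.0)
        regions = segment_endosomes(img, threshold=10)  # nearly all foreground
        with pytest.raises(RuntimeError):
            background_stats(pair, regions, n_rois=5, roi_size=8, seed=0,
                             max_tries=100)


class TestMeasureFWHM:
    def test_gaussian_spot(self):
        """A sigma-50-nm Gaussian spot has FWHM 2.355 * 50 = 117.7 nm."""
        px = 20.0
        n = 64
        ax = (np.arange(n) - n // 2) * px
        X, Y = np.meshgrid(ax, ax)
        img = 1000.0 * np.exp(-(X**2 + Y**2) / (2 * 50.0**2))
        w = measure_fwhm(img, (n // 2, n // 2), px, expected_fwhm_nm=120)
        assert w == pytest.approx(117.7, abs=px)

    @pytest.mark.parametrize(
        "optics, oracle, tol_px",
        [(CONFOCAL, FWHM_DISK40_PSF250, 1.0), (STED, FWHM_DISK40_PSF50, 1.0)],
    )
    def test_blurred_disk_matches_convolution_oracle(self, optics, oracle,
                                                     tol_px, srphi1):
        """A 40-nm endosome rendered through the PSF measures the FWHM given
        by the fine-grid convolution oracle (within one pixel)."""
        scene = single_endosome_scene(40.0, 7.0, optics)
        pair, _ = render_image_pair(scene, srphi1, optics, noise=False)
        c = scene.field_px // 2
        w = measure_fwhm(pair.dye, (c, c), optics.pixel_size_nm,
                         expected_fwhm_nm=optics.psf_fwhm_nm)
        assert w == pytest.approx(oracle, abs=tol_px * optics.pixel_size_nm)

    def test_sted_resolves_sub_100nm(self, srphi1):
        """STED imaging reveals endosomes below 100 nm apparent size."""
        scene = single_endosome_scene(40.0, 7.0, STED)
        pair, _ = render_image_pair(scene, srphi1, STED, noise=False)
        c = scene.field_px // 2
        w = measure_fwhm(pair.dye, (c, c), STED.pixel_size_nm,
                         expected_fwhm_nm=STED.psf_fwhm_nm)
        assert w < 100.0

    def test_unresolved_profile_raises(self):
        img = np.full((32, 32), 100.0)
        img[16, 16] = 101.0  # ramp never falls below half max of a flat field
        img += np.linspace(0, 50, 32)[None, :]
        with pytest.raises(ValueError):
            measure_fwhm(img, (31, 16), 20.0, axis="x", expected_fwhm_nm=200)

    def test_centroid_outside_image_rejected(self):
        with pytest.raises(ValueError):
            measure_fwhm(np.zeros((8, 8)), (20, 2), 20.0)
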