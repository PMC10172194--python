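"""Peak alignment, deisotoping, normalization, pLSA, segmentation, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, silhouette_score

from conftest import toy_cube
from spatomix import phantom
from spatomix.msi import (
    align_peaks,
    fit_plsa,
    pca_scores,
    remove_isotopes,
    segment_pixels,
    tic_normalize,
)


class TestAlignPeaks:
    def test_peaks_within_tolerance_merge(self):
        aligned, maps = align_peaks(
            [(np.array([100.000]), np.array([1.0])),
             (np.array([100.005]), np.array([1.0]))],
            mz_tolerance_da=0.01,
        )
        assert len(aligned) == 1
        assert maps[0][0] == maps[1][0] == 0

    def test_peaks_beyond_tolerance_stay_separate(self):
        aligned, _ = align_peaks(
            [(np.array([100.000]), np.array([1.0])),
             (np.array([100.020]), np.array([1.0]))],
            mz_tolerance_da=0.01,
        )
        assert len(aligned) == 2

    def test_single_spectrum_identity_mapping(self):
        mz = np.array([100.0, 150.0, 200.0])
        aligned, maps = align_peaks([(mz, np.ones(3))], mz_tolerance_da=0.01)
        assert np.allclose(aligned, mz)
        assert np.array_equal(maps[0], [0, 1, 2])

    def test_idempotence_on_aligned_lists(self):
        mz = np.array([100.0, 100.5, 101.2, 250.0])
        once, _ = align_peaks([(mz, np.ones(4))], 0.01)
        twice, maps = align_peaks([(once, np.ones(4))], 0.01)
        assert np.allclose(once, twice)
        assert np.array_equal(maps[0], np.arange(4))

    def test_intensity_weighted_cluster_mean(self):
        aligned, _ = align_peaks(
            [(np.array([100.000]), np.array([3.0])),
             (np.array([100.006]), np.array([1.0]))],
            0.01,
        )
        assert aligned[0] == pytest.approx(100.0015)

    def test_wide_chain_split_at_largest_gap(self):
        # consecutive gaps 0.006 each: chain spans 0.012 > tol, split once
        mz = np.array([100.000, 100.006, 100.012])
        aligned, _ = align_peaks([(mz, np.ones(3))], 0.01)
        assert len(aligned) == 2

    def test_empty_input(self):
        aligned, maps = align_peaks([(np.array([]), np.array([]))], 0.01)
        assert aligned.size == 0 and maps[0].size == 0


class TestRemoveIsotopes:
    def test_weaker_peak_one_c13_up_removed(self):
        keep = remove_isotopes([200.000, 201.0033], [10.0, 3.0])
        assert keep.tolist() == [True, False]

    def test_stronger_peak_above_parent_survives(self):
        keep = remove_isotopes([200.000, 201.0033], [3.0, 10.0])
        assert keep.tolist() == [True, True]

    def test_single_peak_unchanged(self):
        assert remove_isotopes([200.0], [5.0]).tolist() == [True]

    def test_most_intense_peak_never_removed(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(100, 900, 50))
        inten = rng.uniform(1, 100, 50)
        keep = remove_isotopes(mz, inten)
        assert keep[np.argmax(inten)]


class TestTicNormalize:
    def test_uniform_tic_is_fixed_point(self):
        cube = toy_cube(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        out = tic_normalize(cube)
        assert np.allclose(out.intensities, cube.intensities)

    def test_pixel_at_twice_median_is_halved(self):
        cube = toy_cube(np.array([[2.0, 2.0], [2.0, 2.0], [4.0, 4.0]]))
        out = tic_normalize(cube)
        assert np.allclose(out.intensities[2], [2.0, 2.0])

    def test_tic_constant_after_normalization(self):
        rng = np.random.default_rng(1)
        cube = toy_cube(rng.uniform(0.1, 5.0, size=(20, 6)))
        out = tic_normalize(cube)
        tics = out.intensities.sum(axis=1)
        assert np.allclose(tics, tics[0])

    def test_all_zero_cube_raises(self):
        with pytest.raises(ValueError, match="invalid-input"):
            tic_normalize(toy_cube(np.zeros((3, 2))))

    def test_zero_pixels_flagged_and_left_zero(self):
        cube = toy_cube(np.array([[1.0, 1.0], [0.0, 0.0], [2.0, 2.0]]))
        out = tic_normalize(cube)
        assert out.meta["zero_pixels"] == [1]
        assert np.all(out.intensities[1] == 0)


class TestPlsa:
    def test_rank1_matrix_fits_exactly_with_one_component(self):
        r = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([0.5, 1.0, 1.5])
        cube = toy_cube(np.outer(r, c))
        model = fit_plsa(cube, K=1, seed=0)
        recon = (model.theta_pixel * model.pi_k) @ model.phi_peak.T
        # K=1 factorizes the (pseudo-count) matrix as the outer product of
        # its marginals, exactly, in one M-step
        from spatomix.msi import to_pseudocounts

        pseudo = to_pseudocounts(cube)
        assert np.allclose(recon, pseudo / pseudo.sum(), atol=1e-12)
        assert len(model.loglik_trace) <= 4

    def test_block_diagonal_components_separate_exactly(self):
        block = np.array(
            [
                [5.0, 5.0, 0.0, 0.0],
                [4.0, 6.0, 0.0, 0.0],
                [0.0, 0.0, 3.0, 7.0],
                [0.0, 0.0, 6.0, 4.0],
            ]
        )
        model = fit_plsa(toy_cube(block), K=2, seed=0)
        # exact solution: each component's peak distribution is the column
        # marginal of one block, with zero mass on the other block
        marginals = np.array([[0.45, 0.55, 0.0, 0.0], [0.0, 0.0, 0.45, 0.55]])
        cos = np.zeros((2, 2))
        for a in range(2):
            for k in range(2):
                phi = model.phi_peak[:, k]
                cos[a, k] = marginals[a] @ phi / (
                    np.linalg.norm(marginals[a]) * np.linalg.norm(phi)
                )
        rows, cols = linear_sum_assignment(-cos)
        assert np.all(cos[rows, cols] > 1.0 - 1e-6)
        # support confined to one block each
        offblock = min(
            model.phi_peak[2:, 0].sum() + model.phi_peak[:2, 1].sum(),
            model.phi_peak[:2, 0].sum() + model.phi_peak[2:, 1].sum(),
        )
        assert offblock < 1e-6

    def test_loglik_nondecreasing_on_random_cube(self):
        rng = np.random.default_rng(3)
        cube = toy_cube(rng.uniform(0.0, 10.0, size=(30, 8)))
        model = fit_plsa(cube, K=3, seed=3, max_iter=60)
        diffs = np.diff(model.loglik_trace)
        assert np.all(diffs >= -1e-6 * np.abs(model.loglik_trace[:-1]))

    def test_distributions_normalized_to_1e9(self):
        rng = np.random.default_rng(4)
        cube = toy_cube(rng.uniform(0.0, 10.0, size=(25, 6)))
        model = fit_plsa(cube, K=4, seed=4, max_iter=30)
        assert abs(model.pi_k.sum() - 1) < 1e-9
        assert np.abs(model.theta_pixel.sum(axis=0) - 1).max() < 1e-9
        assert np.abs(model.phi_peak.sum(axis=0) - 1).max() < 1e-9

    def test_k_larger_than_matrix_raises(self):
        with pytest.raises(ValueError, match="invalid-argument"):
            fit_plsa(toy_cube(np.ones((3, 2))), K=5, seed=0)

    def test_archetype_recovery_on_three_region_cube(
        self, small_cube, three_region_programs
    ):
        model = fit_plsa(small_cube, K=3, seed=0)
        feats = small_cube.feature_ids()
        progs = three_region_programs
        cos = np.zeros((3, 3))
        for r in range(3):
            elevated = set(
                progs[(progs["region_id"] == r)]["feature_id"]
            )
            vec = np.array([80.0 if f in elevated else 20.0 for f in feats])
            for k in range(3):
                phi = model.phi_peak[:, k]
                cos[r, k] = vec @ phi / (np.linalg.norm(vec) * np.linalg.norm(phi))
        rows, cols = linear_sum_assignment(-cos)
        assert len(set(cols)) == 3
        assert np.all(cos[rows, cols] >= 0.8)


class TestSegmentation:
    def test_noiseless_three_region_cube_perfect_ari(
        self, small_region_image, three_region_programs
    ):
        cube = phantom.simulate_msi_cube(
            small_region_image, 100.0, three_region_programs,
            noise_sd=0.0, lognormal_sigma=0.0, baseline=0.0, seed=0,
        )
        seg = segment_pixels(cube, 3, seed=0)
        assert adjusted_rand_score(cube.meta["true_region"], seg.labels) == 1.0

    def test_default_noise_ari_above_0_8(self, small_cube):
        seg = segment_pixels(small_cube, 3, seed=0)
        assert adjusted_rand_score(small_cube.meta["true_region"], seg.labels) >= 0.8

    def test_k_equals_pixels_gives_singletons(self):
        rng = np.random.default_rng(5)
        cube = toy_cube(rng.uniform(1.0, 2.0, size=(6, 3)))
        seg = segment_pixels(cube, 6, seed=0)
        assert len(set(seg.labels.tolist())) == 6

    def test_too_many_clusters_raise(self):
        with pytest.raises(ValueError, match="invalid-argument"):
            segment_pixels(toy_cube(np.ones((4, 2))), 10, seed=0)


class TestPca:
    def test_points_on_a_line_explained_by_pc1(self):
        t = np.linspace(0, 1, 20)
        pts = np.column_stack([2 * t + 1, -3 * t + 4])
        _, _, evr = pca_scores(pts, 2)
        assert evr[0] == pytest.approx(1.0)

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(40, 5))
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        _, _, evr_a = pca_scores(x, 5)
        _, _, evr_b = pca_scores(x @ q, 5)
        assert np.allclose(evr_a, evr_b, atol=1e-10)

    def test_constant_matrix_gives_zero_scores(self):
        scores, _, evr = pca_scores(np.full((5, 3), 2.0), 2)
        assert np.all(scores == 0) and np.all(evr == 0)

    def test_region_profiles_separate_in_pc_space(self, small_cube):
        truth = np.array(small_cube.meta["true_region"])
        scores, _, _ = pca_scores(small_cube.intensities, 2)
        assert silhouette_score(scores, truth) > 0


@settings(deadline=None, derandomize=True)
@given(
    hst.lists(hst.floats(min_value=90.0, max_value=110.0), min_size=1, max_size=20)
)
def test_alignment_output_within_tolerance_everywhere(mzs):
    """Aligned peak lists never contain two peaks closer than one gap rule allows."""
    mz = np.sort(np.asarray(mzs))
    aligned, maps = align_peaks([(mz, np.ones(len(mz)))], 0.01)
    # every original peak maps to a cluster center within the tolerance span
    assert np.all(np.abs(aligned[maps[0]] - mz) <= 0.01 + 1e-12)
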