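"""Smoothing, grayscale rescale, region extraction, whole-brain normalization."""

import math

import numpy as np
import pytest

from metcovnet import (
    DataError,
    ParameterError,
    VolumeImage,
    build_group_covariance,
    normalize_region_matrix,
    normalize_subject_signals,
    partial_correlation,
    render_subject_volumes,
    rescale_grayscale,
    sample_region_matrix,
    smooth_volume,
    volumes_to_region_matrix,
)
from metcovnet.parcellation import (
    AtlasParcellation,
    RegionMatrix,
    brain_statistics,
    extract_region_means,
)


class TestSmoothVolume:
    def test_constant_volume_unchanged(self):
        vol = VolumeImage(np.full((8, 8, 8), 3.7))
        out = smooth_volume(vol, (10, 10, 10))
        assert np.allclose(out.values, 3.7, atol=1e-10)

    def test_impulse_peak_matches_discrete_kernel(self):
        # independent evaluation of the separable truncated Gaussian kernel
        vol = VolumeImage(np.zeros((21, 21, 21)), voxel_size_mm=(2, 2, 2))
        vol.values[10, 10, 10] = 1.0
        fwhm = 10.0
        sigma = fwhm / (2.0 * math.sqrt(8 * math.log(2)))  # in voxels
        radius = int(4.0 * sigma + 0.5)  # scipy's default truncation
        x = np.arange(-radius, radius + 1)
        k1d = np.exp(-0.5 * (x / sigma) ** 2)
        k1d /= k1d.sum()
        expected_peak = k1d[radius] ** 3
        out = smooth_volume(vol, (fwhm, fwhm, fwhm))
        assert out.values[10, 10, 10] == pytest.approx(expected_peak, rel=1e-10)

    def test_interior_mass_conserved(self):
        vol = VolumeImage(np.zeros((31, 31, 31)), voxel_size_mm=(2, 2, 2))
        vol.values[15, 15, 15] = 1.0
        out = smooth_volume(vol, (10, 10, 10))
        assert out.values.sum() == pytest.approx(1.0, rel=1e-6)

    def test_invalid_fwhm(self):
        vol = VolumeImage(np.zeros((4, 4, 4)))
        with pytest.raises(ParameterError):
            smooth_volume(vol, (0, 10, 10))


class TestRescaleGrayscale:
    def test_linear_map(self):
        vol = VolumeImage(np.array([0.0, 5.0, 10.0]).reshape(3, 1, 1))
        out = rescale_grayscale(vol)
        assert np.allclose(out.values.ravel(), [0.0, 127.5, 255.0])

    def test_constant_maps_to_lo(self):
        vol = VolumeImage(np.full((2, 2, 2), 9.0))
        assert np.all(rescale_grayscale(vol, lo=5.0).values == 5.0)

    def test_identity_when_already_full_range(self, rng):
        vals = rng.uniform(0, 255, (4, 4, 4))
        vals[0, 0, 0], vals[1, 1, 1] = 0.0, 255.0
        vol = VolumeImage(vals)
        assert np.allclose(rescale_grayscale(vol).values, vals)

    def test_monotone(self, rng):
        vals = rng.normal(size=(5, 5, 5))
        out = rescale_grayscale(VolumeImage(vals)).values
        order = np.argsort(vals.ravel())
        assert (np.diff(out.ravel()[order]) >= 0).all()

    def test_bad_range(self):
        with pytest.raises(ParameterError):
            rescale_grayscale(VolumeImage(np.zeros((2, 2, 2))), lo=1.0, hi=1.0)


def _mini_atlas():
    labels = np.zeros((2, 2, 2), dtype=np.int32)
    labels[0] = 1  # 4 voxels
    labels[1] = 2  # 4 voxels
    return AtlasParcellation(labels=labels, region_ids=[1, 2])


class TestExtractRegionMeans:
    def test_arithmetic(self):
        atlas = _mini_atlas()
        vals = np.zeros((2, 2, 2))
        vals[0] = np.array([[1.0, 2.0], [3.0, 4.0]])
        vals[1] = 7.0
        means = extract_region_means(VolumeImage(vals), atlas)
        assert means == pytest.approx([2.5, 7.0])

    def test_constant_volume(self):
        atlas = _mini_atlas()
        means = extract_region_means(VolumeImage(np.full((2, 2, 2), 3.0)), atlas)
        assert np.allclose(means, 3.0)

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            extract_region_means(VolumeImage(np.zeros((3, 3, 3))), _mini_atlas())


class TestNormalizeSubjectSignals:
    def test_arithmetic(self):
        out = normalize_subject_signals(np.array([8.0, 10.0, 12.0]), 10.0, 2.0)
        assert np.allclose(out, [-1.0, 0.0, 1.0])

    def test_all_zero_when_means_equal_brain_mean(self):
        assert np.allclose(normalize_subject_signals(np.full(5, 4.0), 4.0, 1.3), 0.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(DataError):
            normalize_subject_signals(np.ones(3), 1.0, 0.0)


class TestPipelineInvariances:
    def test_scale_invariance_of_normalized_vector(self, toy_atlas, base_spec):
        """Multiplying a volume by k > 0 leaves the normalized region vector unchanged."""
        rm = sample_region_matrix(base_spec, 4, seed=6)
        vol = render_subject_volumes(rm, toy_atlas, noise_sd=0.3, seed=1)[0]
        scaled = VolumeImage(vol.values * 3.7, vol.voxel_size_mm, vol.affine)
        def normalized(v):
            means = extract_region_means(v, toy_atlas)
            mu, sd = brain_statistics(v, toy_atlas)
            return normalize_subject_signals(means, mu, sd)
        assert np.allclose(normalized(vol), normalized(scaled), atol=1e-10)

    def test_round_trip_network_equality(self, toy_atlas, base_spec):
        """Noise-free render -> extract -> normalize matches the direct table path."""
        rm = sample_region_matrix(base_spec, 12, seed=9)
        vols = render_subject_volumes(rm, toy_atlas, noise_sd=0.0, seed=0)
        via_volumes = volumes_to_region_matrix(vols, toy_atlas, normalize=True)
        direct = normalize_region_matrix(rm, region_weights=toy_atlas.region_sizes())
        assert np.allclose(via_volumes.values, direct.values, atol=1e-10)
        net_a = partial_correlation(via_volumes.values, 0.5)
        net_b = partial_correlation(direct.values, 0.5)
        assert np.allclose(net_a, net_b, atol=1e-10)

    def test_reference_region_scaling(self, toy_atlas, base_spec):
        rm = sample_region_matrix(base_spec, 4, seed=2)
        vols = render_subject_volumes(rm, toy_atlas, noise_sd=0.0, seed=0)
        out = volumes_to_region_matrix(vols, toy_atlas, reference_region=1, normalize=False)
        assert np.allclose(out.values[:, 0], 1.0)  # reference region mean is 1


class TestRegionMatrixIO:
    def test_tsv_round_trip(self, tmp_path, base_spec):
        rm = sample_region_matrix(base_spec, 5, seed=4)
        path = tmp_path / "cohort.tsv"
        rm.to_tsv(path)
        back = RegionMatrix.from_tsv(path)
        assert back.subject_ids == rm.subject_ids
        assert back.region_ids == rm.region_ids
        assert np.allclose(back.values, rm.values)

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            RegionMatrix(np.array([[1.0, np.nan]]), ["s"], [1, 2])


def test_normalize_region_matrix_weighted_matches_population_stats():
    spec = build_group_covariance(10, 2, 0.0, 0.2, seed=1)
    rm = sample_region_matrix(spec, 6, seed=1)
    w = np.arange(1, 11, dtype=float)
    out = normalize_region_matrix(rm, region_weights=w)
    wn = w / w.sum()
    assert np.allclose((out.values * wn).sum(axis=1), 0.0, atol=1e-12)
    assert np.allclose((out.values**2 * wn).sum(axis=1), 1.0, atol=1e-12)
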