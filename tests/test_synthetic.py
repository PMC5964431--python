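"""Covariance construction, cohort sampling, toy atlas and volume rendering."""

import numpy as np
import pytest

from metcovnet import (
    ParameterError,
    betweenness_normalized,
    binarize_matrix,
    build_group_covariance,
    make_toy_atlas,
    partial_correlation,
    render_subject_volumes,
    sample_region_matrix,
    strengthen_pair,
)
from metcovnet.parcellation import AtlasParcellation, RegionMatrix, extract_region_means


class TestBuildGroupCovariance:
    def test_zero_strength_gives_loaded_identity(self):
        spec = build_group_covariance(4, 2, 0.0, 0.0, seed=0, diagonal_load=0.5)
        assert np.allclose(spec.matrix, np.eye(4) * 1.5)

    def test_ring_lattice_support_is_cycle(self):
        # k=2 without rewiring: off-diagonal support is exactly the 6-cycle
        spec = build_group_covariance(6, 2, 0.0, 0.3, seed=0)
        expected = np.zeros((6, 6))
        for i in range(6):
            expected[i, (i + 1) % 6] = expected[(i + 1) % 6, i] = 0.3
        off = spec.matrix - np.diag(np.diag(spec.matrix))
        assert np.allclose(off, expected)

    def test_weaken_zeroes_incident_entries(self):
        spec = build_group_covariance(
            6, 2, 0.0, 0.3, planted_alterations=[(3, "weaken", 0.0)], seed=0
        )
        i = 2  # region id 3 is 1-based
        off = spec.matrix - np.diag(np.diag(spec.matrix))
        assert np.all(off[i, :] == 0) and np.all(off[:, i] == 0)

    def test_strengthen_adds_dispersed_ties(self):
        from metcovnet.synthetic import _strengthen_partners

        base = build_group_covariance(8, 2, 0.0, 0.1, seed=0)
        alt = build_group_covariance(
            8, 2, 0.0, 0.1, planted_alterations=[(5, "strengthen", 0.25)], seed=0
        )
        i = 4
        partners = _strengthen_partners(i, 8)
        assert partners and i not in partners
        delta = alt.matrix[i] - base.matrix[i]
        assert np.allclose(delta[partners], 0.25)
        untouched = [j for j in range(8) if j not in partners and j != i]
        assert np.allclose(delta[untouched], 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_always_positive_definite(self, seed):
        spec = build_group_covariance(
            30, 6, 0.1, 0.4, planted_alterations=[(7, "strengthen", 0.9)], seed=seed
        )
        assert spec.min_eigenvalue() > 0

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            build_group_covariance(10, 3, 0.0, 0.1, seed=0)  # odd degree
        with pytest.raises(ParameterError):
            build_group_covariance(3, 2, 0.0, 0.1, seed=0)  # too few regions
        with pytest.raises(ParameterError):
            build_group_covariance(10, 2, 0.0, -0.1, seed=0)  # negative strength


class TestStrengthenPair:
    def test_pairwise_increase_and_pd(self, base_spec):
        alt = strengthen_pair(base_spec, 10, 50, 1.0)
        assert alt.matrix[9, 49] == pytest.approx(base_spec.matrix[9, 49] + 1.0)
        assert alt.min_eigenvalue() > 0

    def test_same_region_rejected(self, base_spec):
        with pytest.raises(ParameterError):
            strengthen_pair(base_spec, 4, 4, 0.5)


class TestSampleRegionMatrix:
    def test_shape_and_scale(self, base_spec):
        rm = sample_region_matrix(base_spec, 22, seed=0)
        assert rm.values.shape == (22, 90)
        assert abs(rm.values.mean() - 100.0) < 1.0

    def test_deterministic(self, base_spec):
        a = sample_region_matrix(base_spec, 10, seed=42)
        b = sample_region_matrix(base_spec, 10, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_independent_regions_uncorrelated_at_large_n(self):
        spec = build_group_covariance(10, 2, 0.0, 0.0, seed=0)
        rm = sample_region_matrix(spec, 5000, seed=1)
        corr = np.corrcoef(rm.values, rowvar=False)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() <= 0.05


class TestToyAtlas:
    def test_partition_contract(self, toy_atlas):
        labels = toy_atlas.labels
        present = np.unique(labels[labels > 0])
        assert np.array_equal(present, np.arange(1, 91))
        assert (toy_atlas.region_sizes() >= 1).all()

    def test_union_covers_mask(self, toy_atlas):
        # mask is defined by nonzero labels, so check against the ellipsoid
        from metcovnet.synthetic import _ellipsoid_mask

        mask = _ellipsoid_mask((24, 24, 24))
        assert np.array_equal(toy_atlas.labels > 0, mask)

    def test_deterministic(self):
        a = make_toy_atlas((12, 12, 12), 10, seed=9)
        b = make_toy_atlas((12, 12, 12), 10, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_too_small_grid(self):
        with pytest.raises(ParameterError):
            make_toy_atlas((3, 3, 3), 90, seed=0)


def _two_region_atlas():
    labels = np.zeros((5, 5, 8), dtype=np.int32)
    labels[:, :, :4] = 1
    labels[:, :, 4:] = 2
    return AtlasParcellation(labels=labels, region_ids=[1, 2])


class TestRenderSubjectVolumes:
    def test_noise_free_round_trip(self, base_spec, toy_atlas):
        rm = sample_region_matrix(base_spec, 5, seed=3)
        vols = render_subject_volumes(rm, toy_atlas, noise_sd=0.0, seed=0)
        assert len(vols) == 5 and vols[0].shape == (24, 24, 24)
        recovered = np.vstack([extract_region_means(v, toy_atlas) for v in vols])
        assert np.allclose(recovered, rm.values)

    def test_noise_standard_error(self):
        # 100-voxel regions with unit noise: SE = 0.1, so the region mean is
        # within +/-0.4 (4 SE) of the true value virtually always
        atlas = _two_region_atlas()
        hits = 0
        for seed in range(100):
            rm = RegionMatrix(np.array([[5.0, -3.0]]), ["s"], [1, 2])
            vol = render_subject_volumes(rm, atlas, noise_sd=1.0, seed=seed)[0]
            means = extract_region_means(vol, atlas)
            hits += abs(means[0] - 5.0) <= 0.4
        assert hits >= 95

    def test_region_count_mismatch(self, toy_atlas):
        rm = RegionMatrix(np.zeros((4, 5)), list("abcd"), [1, 2, 3, 4, 5])
        with pytest.raises(ParameterError):
            render_subject_volumes(rm, toy_atlas)


def _bi_rank(spec, region_idx, seed, n_subjects=110, shrinkage=0.1):
    rm = sample_region_matrix(spec, n_subjects, seed=seed)
    X = rm.values - rm.values.mean(axis=1, keepdims=True)
    X /= rm.values.std(axis=1, keepdims=True)
    A = binarize_matrix(partial_correlation(X, shrinkage), 0.21)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, bi = betweenness_normalized(A)
    return (bi < bi[region_idx]).sum()  # rank: how many regions it beats


def test_strengthen_alteration_raises_bi_rank(base_spec):
    """Planting a strengthened region raises its betweenness rank (majority of seeds).

    Checked at a cohort size where the network estimate carries the planted
    structure (the partial-correlation estimate at very small n is noise
    dominated for any positive-definite single-region alteration).
    """
    altered = build_group_covariance(
        planted_alterations=[(45, "strengthen", 0.5)], seed=11
    )
    wins = sum(
        _bi_rank(altered, 44, s) > _bi_rank(base_spec, 44, s) for s in range(20)
    )
    assert wins > 10
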