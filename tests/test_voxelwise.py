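"""Voxel-wise GLM and permutation FWE inference."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from glioloc.imaging import LesionMask, flip_lateral
from glioloc.stats import partial_r, pearson_r, two_sample_t
from glioloc.voxelwise import (
    VoxelwiseDesign,
    build_lesion_matrix,
    glm_t_map,
    permutation_fwe,
    run_voxelwise_suite,
    voxelwise_analysis,
)

from conftest import make_mask


def random_lesion_matrix(rng, n, v, p=0.4):
    """Binary matrix with every voxel lesioned in >= 2 subjects."""
    while True:
        y = (rng.random((n, v)) < p).astype(float)
        if (y.sum(0) >= 2).all() and (y.std(0) > 0).all():
            return y


class TestBuildLesionMatrix:
    def test_identical_masks(self, grid10):
        mask = make_mask(grid10, [(1, 1, 1), (2, 2, 2)])
        y, analysis_mask, _ = build_lesion_matrix([mask, mask], min_overlap=2)
        np.testing.assert_array_equal(analysis_mask, mask.bool())
        assert y.shape == (2, 2)

    def test_disjoint_masks_raise(self, grid10):
        a = make_mask(grid10, [(1, 1, 1)])
        b = make_mask(grid10, [(2, 2, 2)])
        with pytest.raises(ValueError, match="empty analysis mask"):
            build_lesion_matrix([a, b], min_overlap=2)

    def test_mask_equals_frequency_threshold_region(self, grid10):
        """Oracle: analysis mask == frequency-map >= min_overlap region."""
        from glioloc.overlap import frequency_map

        rng = np.random.default_rng(2)
        masks = [
            make_mask(grid10, np.argwhere(rng.random((10, 10, 10)) > 0.7), subject_id=f"s{i}")
            for i in range(3)
        ]
        _, analysis_mask, _ = build_lesion_matrix(masks, min_overlap=2)
        fm = frequency_map(masks)
        np.testing.assert_array_equal(analysis_mask, fm.counts >= 2)


class TestGlmReductions:
    def test_group_design_equals_two_sample_t(self):
        rng = np.random.default_rng(0)
        y = random_lesion_matrix(rng, 14, 5)
        g = np.r_[np.ones(7), np.zeros(7)]
        t, df = glm_t_map(y, VoxelwiseDesign(predictor=g))
        for v in range(5):
            ref = two_sample_t(y[g == 1, v], y[g == 0, v])
            assert t[v] == pytest.approx(ref.statistic, rel=1e-9)
        assert df == 12

    def test_continuous_design_equals_pearson_t(self):
        rng = np.random.default_rng(1)
        y = random_lesion_matrix(rng, 15, 4)
        x = rng.random(15)
        t, df = glm_t_map(y, VoxelwiseDesign(predictor=x))
        for v in range(4):
            r = pearson_r(x, y[:, v]).statistic
            t_ref = r * math.sqrt((15 - 2) / (1 - r**2))
            assert t[v] == pytest.approx(t_ref, rel=1e-9)

    def test_nuisance_design_equals_partial_t(self):
        """Oracle: GLM t with nuisance == partial-correlation t-transform."""
        rng = np.random.default_rng(2)
        y = random_lesion_matrix(rng, 20, 4)
        x = rng.random(20)
        z = rng.random(20)
        t, df = glm_t_map(y, VoxelwiseDesign(predictor=x, nuisance=z))
        assert df == 17
        for v in range(4):
            r = partial_r(x, y[:, v], z).statistic
            t_ref = r * math.sqrt(17 / (1 - r**2))
            assert t[v] == pytest.approx(t_ref, rel=1e-8)

    def test_rank_deficient_design_rejected(self):
        x = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="rank"):
            VoxelwiseDesign(predictor=x, nuisance=2 * x - 1).matrix()


class TestPermutationFwe:
    def test_exact_enumeration_matches_brute_force(self):
        """p_fwe for one voxel, two groups equals the full-enumeration p."""
        rng = np.random.default_rng(3)
        n = 8
        y = random_lesion_matrix(rng, n, 1)
        g = np.r_[np.ones(4), np.zeros(4)]
        res = permutation_fwe(y, VoxelwiseDesign(predictor=g), n_perm=1000, seed=0)
        assert res["exact"] and res["n_perm"] == math.comb(8, 4)
        # independent enumeration of the two-sample |t| null
        t_obs = abs(glm_t_map(y, VoxelwiseDesign(predictor=g))[0][0])
        count = 0
        for ones in itertools.combinations(range(n), 4):
            gg = np.zeros(n)
            gg[list(ones)] = 1
            t = abs(glm_t_map(y, VoxelwiseDesign(predictor=gg))[0][0])
            count += t >= t_obs - 1e-12
        assert res["p_fwe"][0] == pytest.approx(count / math.comb(8, 4), abs=1e-12)

    def test_single_permutation_p_values(self):
        rng = np.random.default_rng(4)
        y = random_lesion_matrix(rng, 12, 6)
        x = rng.random(12)
        res = permutation_fwe(y, VoxelwiseDesign(predictor=x), n_perm=1, seed=1)
        assert set(np.unique(res["p_fwe"])) <= {0.5, 1.0}
        assert (res["p_fwe"] >= 1.0 / 2.0).all()

    def test_fwe_floor_and_ceiling(self):
        rng = np.random.default_rng(5)
        y = random_lesion_matrix(rng, 12, 6)
        x = rng.random(12)
        res = permutation_fwe(y, VoxelwiseDesign(predictor=x), n_perm=99, seed=1)
        assert (res["p_fwe"] >= 1.0 / 100.0).all()
        assert (res["p_fwe"] <= 1.0).all()

    def test_bit_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        y = random_lesion_matrix(rng, 20, 10)
        x = rng.random(20)
        design = VoxelwiseDesign(predictor=x, nuisance=rng.random(20))
        a = permutation_fwe(y, design, n_perm=50, seed=42)
        b = permutation_fwe(y, design, n_perm=50, seed=42)
        for key in ("t", "p_unc", "p_fwe"):
            np.testing.assert_array_equal(a[key], b[key])

    def test_invariant_under_group_relabeling(self):
        rng = np.random.default_rng(7)
        y = random_lesion_matrix(rng, 16, 8)
        g = np.r_[np.ones(8), np.zeros(8)]
        a = permutation_fwe(y, VoxelwiseDesign(predictor=g), n_perm=200, seed=3)
        b = permutation_fwe(y, VoxelwiseDesign(predictor=1 - g), n_perm=200, seed=3)
        np.testing.assert_allclose(np.abs(a["t"]), np.abs(b["t"]), rtol=1e-9)
        np.testing.assert_allclose(a["p_fwe"], b["p_fwe"], atol=1e-12)

    def test_null_calibration_smoke(self):
        """Family-wise rejection rate under a true null stays near alpha."""
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 60
        for _ in range(reps):
            y = random_lesion_matrix(rng, 16, 12)
            x = rng.random(16)  # independent of y: the null is true
            res = permutation_fwe(y, VoxelwiseDesign(predictor=x), n_perm=99, seed=int(rng.integers(2**31)))
            rejections += (res["p_fwe"] <= 0.05).any()
        rate = rejections / reps
        # binomial 99% envelope around 0.05 at 60 reps
        assert rate <= 0.05 + 2.6 * math.sqrt(0.05 * 0.95 / reps)


class TestVoxelwiseAnalysis:
    def test_maps_defined_only_inside_analysis_mask(self, grid10):
        rng = np.random.default_rng(9)
        masks = []
        for i in range(10):
            values = np.zeros((10, 10, 10), dtype=np.uint8)
            values[3:7, 3:7, 3:7] = rng.random((4, 4, 4)) > 0.4
            masks.append(LesionMask(grid=grid10, values=values, subject_id=f"s{i}"))
        design = VoxelwiseDesign(predictor=rng.random(10), name="demo")
        res = voxelwise_analysis(masks, design, n_perm=25, seed=0)
        assert np.isnan(res.t_map[~res.analysis_mask]).all()
        assert np.isfinite(res.t_map[res.analysis_mask]).all()
        assert res.n_significant(alpha=1.1) == res.analysis_mask.sum()

    def test_planted_focal_effect_detected(self, grid10):
        """A lesion-predictor co-localization strong enough to survive FWE."""
        rng = np.random.default_rng(10)
        masks, predictor = [], []
        for i in range(20):
            values = np.zeros((10, 10, 10), dtype=np.uint8)
            # background lesion load everywhere
            values[rng.random((10, 10, 10)) > 0.8] = 1
            group = i < 10
            if group:  # planted focus strictly in group 1
                values[4:6, 4:6, 4:6] = 1
            else:
                values[4:6, 4:6, 4:6] = 0
            masks.append(LesionMask(grid=grid10, values=values, subject_id=f"s{i}"))
            predictor.append(float(group))
        design = VoxelwiseDesign(predictor=np.array(predictor), name="planted")
        res = voxelwise_analysis(masks, design, n_perm=199, seed=1)
        planted = np.zeros((10, 10, 10), dtype=bool)
        planted[4:6, 4:6, 4:6] = True
        assert (res.p_fwe[planted & res.analysis_mask] <= 0.05).all()

    def test_flipped_run_is_mirror_of_unflipped_on_mirrored_data(self, grid10):
        rng = np.random.default_rng(11)
        masks = []
        for i in range(8):
            values = np.zeros((10, 10, 10), dtype=np.uint8)
            values[1:4, 2:8, 2:8] = rng.random((3, 6, 6)) > 0.4
            masks.append(LesionMask(grid=grid10, values=values, subject_id=f"s{i}"))
        design = VoxelwiseDesign(predictor=rng.random(8), name="sym")
        res = voxelwise_analysis(masks, design, n_perm=49, seed=5)
        mirrored = [flip_lateral(m, "mirror") for m in masks]
        res_m = voxelwise_analysis(mirrored, design, n_perm=49, seed=5)
        np.testing.assert_allclose(
            res.t_map[res.analysis_mask], np.flip(res_m.t_map, 0)[res.analysis_mask], rtol=1e-9
        )


def test_run_voxelwise_suite_produces_all_analyses(micro_cohort):
    results = run_voxelwise_suite(
        micro_cohort.manifest,
        micro_cohort.core_masks,
        n_perm=19,
        seed=0,
        include_flipped=True,
        include_volume_corrected=False,
    )
    names = {r.name for r in results}
    assert "status_group" in names
    assert "status_group_flipped" in names
    for r in results:
        inside = r.p_fwe[r.analysis_mask]
        assert np.all((inside > 0) & (inside <= 1))
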