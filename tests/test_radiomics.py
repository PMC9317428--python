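"""Radiomics: discretisation, texture matrices and feature families.

The load-bearing check is oracle equivalence: every feature must agree
with the exhaustive-enumeration oracle (tests/oracles.py) on random masked
images; see also test_acceptance.py for the full-panel version.
"""

import numpy as np
import pytest

import oracles
from conftest import random_levels_image
from mpmri.radiomics import (
    DiscretisedROI,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    discretise,
    extract_radiomics,
    first_order_features,
    glcm_cluster_shade,
    glcm_features,
    glrlm_features,
    glszm_features,
    intensity_histogram_features,
    ngtdm_features,
    panel_size,
)
from mpmri.radiomics.features import COARSENESS_CAP


def roi_from(levels, mask, ng):
    return DiscretisedROI(
        levels=np.asarray(levels), mask=np.asarray(mask, bool), ng=ng,
        bin_edges=np.arange(ng + 1, dtype=float),
    )


class TestDiscretise:
    def test_range_endpoints(self):
        vals = np.linspace(0.0, 1.0, 64).reshape(4, 4, 4)
        roi = discretise(vals, np.ones((4, 4, 4), bool), 32)
        assert roi.levels.min() == 1 and roi.levels.max() == 32
        assert roi.levels.flat[0] == 1 and roi.levels.flat[-1] == 32

    def test_constant_map_single_level(self):
        vals = np.full((3, 3, 3), 2.5)
        roi = discretise(vals, np.ones((3, 3, 3), bool), 32)
        assert np.all(roi.levels == 1)
        glcm = build_glcm(roi)
        assert glcm[0, 0] == pytest.approx(1.0)
        assert np.count_nonzero(glcm) == 1

    def test_affine_invariance_of_bin_counts(self):
        rng = np.random.default_rng(0)
        vals = rng.random((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        a = discretise(vals, mask, 16).levels
        b = discretise(3.7 * vals + 11.0, mask, 16).levels
        assert np.array_equal(a, b)


class TestGLCM:
    def test_hand_counted_1x4_image(self):
        levels = np.array([[[1, 1, 1, 2]]])
        roi = roi_from(levels, np.ones_like(levels), 2)
        glcm = build_glcm(roi, directions=((0, 0, 1),))
        assert glcm[0, 0] == pytest.approx(2 / 3)
        assert glcm[0, 1] == pytest.approx(1 / 6)
        assert glcm[1, 0] == pytest.approx(1 / 6)

    def test_cluster_shade_hand_value(self):
        p = np.array([[2 / 3, 1 / 6], [1 / 6, 0.0]])
        assert glcm_cluster_shade(p) == pytest.approx(6 / 81)

    def test_cluster_shade_of_constant_image_is_zero(self):
        assert glcm_cluster_shade(np.array([[1.0]])) == 0.0

    def test_cluster_shade_transpose_symmetry(self):
        rng = np.random.default_rng(1)
        m = rng.random((5, 5))
        p = (m + m.T) / (m + m.T).sum()
        assert glcm_cluster_shade(p) == pytest.approx(glcm_cluster_shade(p.T))

    def test_unnormalised_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalis"):
            glcm_features(np.ones((3, 3)))

    def test_constant_image_energy_and_contrast(self):
        feats = glcm_features(np.array([[1.0]]))
        assert feats["AngularSecondMoment"] == 1.0
        assert feats["Contrast"] == 0.0
        assert feats["Correlation"] == 0.0  # documented degenerate fallback

    def test_cluster_shade_parity_under_level_reflection(self):
        """Reflecting levels i -> ng+1-i flips the sign of the cubed moment."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            levels, mask = random_levels_image(rng, (4, 4, 1), 4)
            roi = roi_from(levels, mask, 4)
            shade = glcm_features(build_glcm(roi))["ClusterShade"]
            refl = roi_from(5 - levels, mask, 4)
            shade_r = glcm_features(build_glcm(refl))["ClusterShade"]
            assert shade == pytest.approx(-shade_r, rel=1e-9, abs=1e-12)

    def test_features_invariant_under_affine_map_rescaling(self):
        rng = np.random.default_rng(3)
        vals = rng.random((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        f1 = glcm_features(build_glcm(discretise(vals, mask, 8)))
        f2 = glcm_features(build_glcm(discretise(5.0 * vals - 2.0, mask, 8)))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12), k

    def test_mask_too_small_raises(self):
        levels = np.array([[[1]]])
        with pytest.raises(ValueError, match="pair"):
            build_glcm(roi_from(levels, np.ones_like(levels), 2))


class TestRunAndZoneMatrices:
    def test_hand_counted_runs_1x4(self):
        levels = np.array([[[1, 1, 2, 2]]])
        roi = roi_from(levels, np.ones_like(levels), 2)
        rlm = build_glrlm(roi, directions=((0, 0, 1),))
        assert rlm[0, 1] == 1 and rlm[1, 1] == 1  # two runs of length 2
        feats = glrlm_features(rlm, n_masked=4, n_directions=1)
        assert feats["RunPercentage"] == pytest.approx(2 / 4)

    def test_run_totals_conserve_voxels_per_direction(self):
        rng = np.random.default_rng(4)
        levels, mask = random_levels_image(rng, (3, 3, 3), 3)
        roi = roi_from(levels, mask, 3)
        rlm = build_glrlm(roi)
        lengths = np.arange(1, rlm.shape[1] + 1)
        assert (rlm * lengths).sum() == pytest.approx(13 * mask.sum())

    def test_zone_totals_conserve_voxels(self):
        rng = np.random.default_rng(5)
        levels, mask = random_levels_image(rng, (4, 4, 1), 3)
        roi = roi_from(levels, mask, 3)
        szm = build_glszm(roi)
        sizes = np.arange(1, szm.shape[1] + 1)
        assert (szm * sizes).sum() == pytest.approx(mask.sum())

    def test_constant_image_single_zone(self):
        levels = np.ones((3, 3, 1), dtype=int)
        roi = roi_from(levels, np.ones_like(levels, bool), 2)
        szm = build_glszm(roi)
        assert szm.sum() == 1 and szm[0, 8] == 1


class TestNGTDM:
    def test_constant_image_coarseness_capped(self):
        levels = np.ones((3, 3, 1), dtype=int)
        roi = roi_from(levels, np.ones_like(levels, bool), 2)
        feats = ngtdm_features(*build_ngtdm(roi))
        assert feats["Coarseness"] == COARSENESS_CAP

    def test_checkerboard_rougher_than_constant(self):
        z = np.indices((4, 4, 1)).sum(axis=0)
        levels = 1 + (z % 2)
        roi = roi_from(levels, np.ones_like(levels, bool), 2)
        feats = ngtdm_features(*build_ngtdm(roi))
        assert feats["Coarseness"] < COARSENESS_CAP
        assert feats["Contrast"] > 0


class TestFirstOrder:
    def test_simple_values(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Range"] == pytest.approx(3.0)
        assert f["Percentile25"] == pytest.approx(1.75)

    def test_constant_map_degenerates(self):
        f = first_order_features(np.full(10, 3.3))
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_gaussian_sample_skewness_near_zero(self):
        rng = np.random.default_rng(6)
        f = first_order_features(rng.standard_normal(100_000))
        assert abs(f["Skewness"]) < 0.05

    def test_histogram_entropy_constant_zero(self):
        f = intensity_histogram_features(np.ones(20, dtype=int), 4)
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0


class TestOracleEquivalence:
    """Production vectorised features vs pure-loop enumeration oracle."""

    @pytest.mark.parametrize("shape,ng,seed", [((4, 4, 1), 4, 0), ((3, 3, 3), 5, 1)])
    def test_all_families_match_oracle(self, shape, ng, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            levels, mask = random_levels_image(rng, shape, ng)
            roi = roi_from(levels, mask, ng)
            lv, mk = levels.tolist(), mask.tolist()
            n_masked = int(mask.sum())

            got = glcm_features(build_glcm(roi))
            want = oracles.glcm_features(oracles.glcm_probabilities(lv, mk), ng)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k

            got = glrlm_features(build_glrlm(roi), n_masked)
            want = oracles.glrlm_features(oracles.glrlm_runs(lv, mk), n_masked)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k

            got = glszm_features(build_glszm(roi), n_masked)
            want = oracles.glszm_features(oracles.glszm_zones(lv, mk), n_masked)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k

            got = ngtdm_features(*build_ngtdm(roi))
            want = oracles.ngtdm_features(*oracles.ngtdm_accumulators(lv, mk, ng))
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k


class TestExtractRadiomics:
    def test_panel_names_and_size(self, noiseless_patient):
        p = noiseless_patient
        vals = np.random.default_rng(7).random(p.mask.shape)
        feats = extract_radiomics({"ADC": vals, "iAUC60": 2 * vals}, p.mask)
        assert "ADC_glcm_ClusterShade" in feats
        assert len(feats) == panel_size() == 211
        assert all(np.isfinite(v) for v in feats.values())

    def test_determinism_identical_inputs(self, noiseless_patient):
        p = noiseless_patient
        vals = np.random.default_rng(8).random(p.mask.shape)
        maps = {"ADC": vals, "iAUC60": 3 * vals}
        assert extract_radiomics(maps, p.mask) == extract_radiomics(maps, p.mask)

    def test_missing_map_raises_by_name(self, noiseless_patient):
        p = noiseless_patient
        with pytest.raises(KeyError, match="iAUC60"):
            extract_radiomics({"ADC": np.random.random(p.mask.shape)}, p.mask)
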