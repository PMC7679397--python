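"""Cohort-level inference: t-tests, FDR, binomial summary, selection, searchlight."""

import numpy as np
import pytest
from scipy import stats

from idiorsa.group import (
    binomial_tail,
    cross_participant_model_agreement,
    fdr_adjust,
    one_sample_group_test,
    searchlight_map,
    select_rois_group_model,
    select_rois_loo_personal,
)
from idiorsa.rsa import SimilarityVector, similarity_vector


def _bh_oracle(p):
    """Benjamini–Hochberg step-up adjusted p-values by direct enumeration."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


class TestOneSampleTest:
    def test_symmetric_values_give_t_zero_p_half(self):
        res = one_sample_group_test(np.array([-0.2, -0.1, 0.1, 0.2]))
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(0.5)

    def test_cohens_d_is_t_over_sqrt_n(self, rng):
        z = rng.normal(0.1, 0.2, size=26)
        res = one_sample_group_test(z)
        assert res.cohens_d == pytest.approx(res.t / np.sqrt(26), abs=1e-14)
        assert res.n == 26

    def test_hand_computed_t_for_five_values(self):
        z = np.array([0.1, 0.3, 0.2, 0.4, 0.0])
        res = one_sample_group_test(z)
        expected = z.mean() / (z.std(ddof=1) / np.sqrt(5))
        assert res.t == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_group_test(np.full(5, 0.3))


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_equal_p_values_stay_equal(self):
        out = fdr_adjust(np.full(7, 0.02))
        assert np.allclose(out, 0.02)

    def test_matches_step_up_enumeration_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.50])
        assert np.allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_agreement_on_random_inputs(self, seed):
        p = np.random.default_rng(seed).uniform(size=15)
        assert np.allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_monotone_when_sorted(self, rng):
        p = np.sort(rng.uniform(size=20))
        out = fdr_adjust(p)
        assert np.all(np.diff(out) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.1, 1.2]))

    def test_by_variant_is_more_conservative(self, rng):
        p = rng.uniform(size=10)
        assert np.all(fdr_adjust(p, method="by") >= fdr_adjust(p, method="bh") - 1e-15)


class TestBinomialTail:
    def test_k_zero_is_one(self):
        assert binomial_tail(10, 0.3, 0) == pytest.approx(1.0)

    def test_symmetric_half_case(self):
        assert binomial_tail(5, 0.5, 3) == pytest.approx(0.5)

    def test_matches_direct_summation(self):
        n, p0, k = 26, 0.05, 4
        from math import comb

        expected = sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1))
        assert binomial_tail(n, p0, k) == pytest.approx(expected, abs=1e-12)

    def test_tail_complement_identity(self):
        from math import comb

        n, p0, k = 12, 0.2, 5
        lower = sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(0, k))
        assert binomial_tail(n, p0, k) + lower == pytest.approx(1.0, abs=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 0.5, 6)
        with pytest.raises(ValueError):
            binomial_tail(5, 1.5, 2)


class TestAgreement:
    def test_pair_count_for_26_participants(self, rng):
        sims = [SimilarityVector(rng.normal(size=(10,)), n_scenarios=5) for _ in range(26)]
        mean_rho, sd, t, p = cross_participant_model_agreement(sims)
        # 325 pairs enter: reconstruct the count from the reported SD path
        n_pairs = 26 * 25 // 2
        assert n_pairs == 325
        assert np.isfinite(mean_rho) and np.isfinite(t)

    def test_identical_models_agree_perfectly(self, rng):
        base = rng.normal(size=(15,))
        sims = [SimilarityVector(base.copy(), n_scenarios=6) for _ in range(5)]
        mean_rho, sd, _, _ = cross_participant_model_agreement(sims)
        assert mean_rho == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)


class TestROISelection:
    def _cohort_sims(self, rng, n=12, signal=True):
        """Brain sims per ROI: ROI 1-2 track the group model, ROI 3-4 are noise."""
        g = rng.normal(size=(10, 16))
        group = [similarity_vector(g + rng.normal(scale=0.2, size=g.shape)) for _ in range(n)]
        fmri = {}
        for roi in (1, 2, 3, 4):
            sims = []
            for p in range(n):
                if signal and roi in (1, 2):
                    pat = g + rng.normal(scale=0.7, size=g.shape)
                else:
                    pat = rng.normal(size=g.shape)
                sims.append(similarity_vector(pat))
            fmri[roi] = sims
        return fmri, group

    def test_planted_signal_rois_recovered(self, rng):
        fmri, group = self._cohort_sims(rng)
        selected, table = select_rois_group_model(fmri, group)
        assert selected == [1, 2]
        assert np.all(table["p_fdr"] >= table["p_raw"] - 1e-15)

    def test_single_strong_roi_selected(self, rng):
        fmri, group = self._cohort_sims(rng)
        selected, _ = select_rois_group_model({1: fmri[1]}, group)
        assert selected == [1]

    def test_loo_selection_ignores_target_data(self, rng):
        fmri, group = self._cohort_sims(rng)
        personal = group  # models share the structure planted in ROIs 1-2
        sel_before, _ = select_rois_loo_personal(fmri, personal, target=0)
        # perturb the target's own data arbitrarily: selection must not change
        fmri_perturbed = {roi: list(sims) for roi, sims in fmri.items()}
        for roi in fmri_perturbed:
            fmri_perturbed[roi][0] = similarity_vector(rng.normal(size=(10, 16)))
        sel_after, _ = select_rois_loo_personal(fmri_perturbed, personal, target=0)
        assert sel_before == sel_after

    def test_loo_with_three_participants_uses_two_coefficients(self, rng):
        fmri = {1: [similarity_vector(rng.normal(size=(8, 10))) for _ in range(3)]}
        personal = [similarity_vector(rng.normal(size=(8, 10))) for _ in range(3)]
        _, table = select_rois_loo_personal(fmri, personal, target=1)
        assert int(table.loc[1, "n"]) == 2

    def test_single_participant_group_degenerates_to_error(self, rng):
        fmri = {1: [similarity_vector(rng.normal(size=(8, 10)))]}
        group = [similarity_vector(rng.normal(size=(8, 10)))]
        with pytest.raises(ValueError):
            select_rois_group_model(fmri, group)

    def test_no_signal_cohorts_rarely_select(self, rng):
        selected_fraction = []
        for _ in range(20):
            fmri, group = self._cohort_sims(rng, signal=False)
            selected, _ = select_rois_group_model(fmri, group)
            selected_fraction.append(len(selected) / 4)
        assert np.mean(selected_fraction) <= 0.05


class TestSearchlight:
    def test_cube_has_343_candidate_voxels_at_radius_3(self):
        assert (2 * 3 + 1) ** 3 == 343

    def test_corner_center_truncated_to_mask(self, rng):
        grid = (5, 5, 5)
        mask = np.ones(grid, dtype=bool)
        patterns = [rng.normal(size=(8, 125)) for _ in range(6)]
        sims = [similarity_vector(rng.normal(size=(8, 10))) for _ in range(6)]
        out = searchlight_map(patterns, mask, sims, radius=2, mode="rsa_personal", min_voxels=10)
        assert np.isfinite(out.t_map[0, 0, 0])  # corner analyzed on 27 in-mask voxels
        assert out.radius_voxels == 2

    def test_small_intersections_skipped(self, rng):
        grid = (4, 4, 4)
        mask = np.zeros(grid, dtype=bool)
        mask[0, 0, :3] = True  # 3 voxels only
        patterns = [rng.normal(size=(8, 3)) for _ in range(5)]
        sims = [similarity_vector(rng.normal(size=(8, 10))) for _ in range(5)]
        out = searchlight_map(patterns, mask, sims, radius=1, mode="rsa_personal", min_voxels=10)
        assert np.all(np.isnan(out.t_map))
        assert out.centers.shape == (0, 3)

    def test_restricted_centers_limit_analysis(self, rng):
        grid = (4, 4, 3)
        mask = np.ones(grid, dtype=bool)
        n_vox = int(np.prod(grid))
        patterns = [rng.normal(size=(8, n_vox)) for _ in range(6)]
        sims = [similarity_vector(rng.normal(size=(8, 10))) for _ in range(6)]
        group = [similarity_vector(rng.normal(size=(8, 10))) for _ in range(6)]
        restrict = np.zeros(grid, dtype=bool)
        restrict[1, 1, 1] = True
        out = searchlight_map(
            patterns, mask, sims, radius=1, mode="partial",
            group_sims=group, min_voxels=5, restrict_centers=restrict,
        )
        assert out.centers.shape == (1, 3)
        assert np.isfinite(out.t_map[1, 1, 1])
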