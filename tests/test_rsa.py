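"""Similarity-space machinery: vectors, fusion, G-1 averages, RSA, partial RSA."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from idiorsa.rsa import (
    SimilarityVector,
    fisher_z,
    fuse_multimodal,
    group_average_loo,
    n_scenarios_from_length,
    partial_rsa,
    partial_rsa_permutation_test,
    rsa_permutation_test,
    rsa_spearman,
    similarity_vector,
    vector_to_matrix,
)


def _pairwise_corr_oracle(patterns):
    """Independent correlation triangle via the covariance formula, pair by pair."""
    s = patterns.shape[0]
    out = []
    for j in range(s - 1):  # squareform order: upper triangle row-major
        for k in range(j + 1, s):
            x, y = patterns[j], patterns[k]
            xc, yc = x - x.mean(), y - y.mean()
            out.append((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    return np.array(out)


def _rank_oracle(v):
    """Average-rank transform written independently of scipy.stats.rankdata."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestSimilarityVector:
    def test_length_is_190_for_20_scenarios(self, rng):
        patterns = rng.normal(size=(20, 30))
        sim = similarity_vector(patterns)
        assert sim.values.shape == (190,)
        assert n_scenarios_from_length(190) == 20

    def test_identical_patterns_hit_the_clipped_maximum(self, rng):
        patterns = rng.normal(size=(4, 10))
        patterns[1] = 2.0 * patterns[0] + 1.0  # perfectly correlated pair
        sim = similarity_vector(patterns)
        assert sim.values[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_matches_pairwise_covariance_oracle(self, rng):
        patterns = rng.normal(size=(4, 6))
        sim = similarity_vector(patterns)
        assert np.allclose(np.tanh(sim.values), _pairwise_corr_oracle(patterns), atol=1e-12)

    def test_zero_variance_row_rejected(self):
        patterns = np.ones((4, 5))
        with pytest.raises(ValueError, match="zero-variance"):
            similarity_vector(patterns)

    def test_invariant_to_per_scenario_affine_rescaling(self, rng):
        patterns = rng.normal(size=(6, 12))
        scales = rng.uniform(0.5, 3.0, size=(6, 1))
        shifts = rng.normal(size=(6, 1))
        a = similarity_vector(patterns)
        b = similarity_vector(patterns * scales + shifts)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_vector_matrix_round_trip(self, rng):
        sim = similarity_vector(rng.normal(size=(5, 8)))
        m = vector_to_matrix(sim.values)
        assert np.allclose(m, m.T)
        back = similarity_vector(rng.normal(size=(5, 8)))  # independent check of shape only
        assert m.shape == (5, 5)
        assert np.allclose(vector_to_matrix(back.values).shape, (5, 5))


class TestFusion:
    def test_duplicated_channel_doubles_the_zscore(self, rng):
        v = SimilarityVector(rng.normal(size=(15,)), n_scenarios=6, source="verbal")
        a = SimilarityVector(v.values.copy(), n_scenarios=6, source="attribute")
        fused = fuse_multimodal(v, a)
        z = (v.values - v.values.mean()) / v.values.std()
        assert np.allclose(fused.values, 2 * z, atol=1e-12)
        assert stats.spearmanr(fused.values, v.values).statistic == pytest.approx(1.0)

    def test_fused_mean_is_zero(self, rng):
        v = SimilarityVector(rng.normal(size=(190,)), n_scenarios=20, source="verbal")
        a = SimilarityVector(rng.normal(size=(190,)), n_scenarios=20, source="attribute")
        assert abs(fuse_multimodal(v, a).values.mean()) < 1e-10

    def test_hand_computed_six_entry_fusion(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        a = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 8.0])
        zv = (v - 3.5) / np.std(v)
        za = (a - 3.0) / np.std(a)
        fused = fuse_multimodal(
            SimilarityVector(v, n_scenarios=4, source="verbal"),
            SimilarityVector(a, n_scenarios=4, source="attribute"),
        )
        assert np.allclose(fused.values, zv + za, atol=1e-12)


class TestGroupAverage:
    def test_identical_participants_average_to_any_individual(self, rng):
        base = SimilarityVector(rng.normal(size=(10,)), n_scenarios=5)
        sims = [SimilarityVector(base.values.copy(), n_scenarios=5) for _ in range(4)]
        g = group_average_loo(sims, exclude=2)
        assert np.allclose(g.values, base.values)

    def test_two_participants_excluding_one_returns_the_other(self, rng):
        sims = [SimilarityVector(rng.normal(size=(6,)), n_scenarios=4) for _ in range(2)]
        assert np.allclose(group_average_loo(sims, exclude=0).values, sims[1].values)

    def test_hand_checked_pointwise_mean_of_retained(self):
        vals = [np.array([1.0, 2.0, 3.0]) * (i + 1) for i in range(5)]
        sims = [SimilarityVector(v, n_scenarios=3) for v in vals]
        g = group_average_loo(sims, exclude=1)
        expected = (vals[0] + vals[2] + vals[3] + vals[4]) / 4
        assert np.allclose(g.values, expected)

    def test_feature_space_variant_averages_features_first(self, rng):
        feats = [rng.normal(size=(5, 7)) for _ in range(3)]
        sims = [similarity_vector(f) for f in feats]
        g = group_average_loo(sims, exclude=0, space="feature", model_features=feats)
        expected = similarity_vector((feats[1] + feats[2]) / 2)
        assert np.allclose(g.values, expected.values)


class TestSpearman:
    def test_monotone_transforms_give_unit_correlation(self, rng):
        a = rng.normal(size=20)
        assert rsa_spearman(a, np.exp(a)) == pytest.approx(1.0)
        assert rsa_spearman(a, -(a**3)) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        b = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 9.0])
        expected = np.corrcoef(_rank_oracle(a), _rank_oracle(b))[0, 1]
        assert rsa_spearman(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_monotone_invariance(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=12), r.normal(size=12)
        assert rsa_spearman(a, b) == pytest.approx(rsa_spearman(b, a), abs=1e-12)
        assert rsa_spearman(np.exp(a), b) == pytest.approx(rsa_spearman(a, b), abs=1e-12)


class TestRSAPermutation:
    def test_self_match_gives_minimal_p(self, rng):
        patterns = rng.normal(size=(20, 30))
        sim = similarity_vector(patterns)
        m = vector_to_matrix(sim.values)
        _, p, _ = rsa_permutation_test(m, sim, n_perm=1000, seed=1)
        assert p <= 0.01

    def test_null_p_values_are_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            brain = similarity_vector(rng.normal(size=(10, 15)))
            model = similarity_vector(rng.normal(size=(10, 15)))
            _, p, _ = rsa_permutation_test(vector_to_matrix(brain.values), model, n_perm=99, seed=rng)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_p_in_unit_interval_and_deterministic_under_seed(self, rng):
        brain = similarity_vector(rng.normal(size=(8, 10)))
        model = similarity_vector(rng.normal(size=(8, 10)))
        m = vector_to_matrix(brain.values)
        _, p1, null1 = rsa_permutation_test(m, model, n_perm=200, seed=42)
        _, p2, null2 = rsa_permutation_test(m, model, n_perm=200, seed=42)
        assert 0.0 <= p1 <= 1.0
        assert p1 == p2
        assert np.array_equal(null1, null2)


class TestPartialRSA:
    def test_matches_closed_form_on_ranks(self, rng):
        x, y, z = rng.normal(size=(3, 10))
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        rxy = np.corrcoef(rx, ry)[0, 1]
        rxz = np.corrcoef(rx, rz)[0, 1]
        ryz = np.corrcoef(ry, rz)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_rsa(x, y, z) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x, y, z = rng.normal(size=(3, 40))
        expected = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z", method="spearman"
        )["r"].iloc[0]
        assert partial_rsa(x, y, z) == pytest.approx(expected, abs=1e-9)

    def test_orthogonal_control_reduces_to_plain_spearman(self):
        """A control whose ranks are uncorrelated with both inputs changes nothing."""
        from itertools import permutations

        x = np.arange(1.0, 9.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        xc, yc = x - x.mean(), y - y.mean()
        z = None
        for perm in permutations(range(8)):
            zc = np.array(perm, dtype=float) - 3.5
            if abs(zc @ xc) < 1e-12 and abs(zc @ yc) < 1e-12:
                z = np.array(perm, dtype=float)
                break
        assert z is not None
        assert partial_rsa(x, y, z) == pytest.approx(rsa_spearman(x, y), abs=1e-6)

    def test_collinear_control_raises(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            partial_rsa(x, y, 2.0 * y + 1.0)  # rank-identical to personal


class TestPartialRSAPermutation:
    def test_regress_residual_addback_identity(self, rng):
        """With the identity shuffle the reconstruction is exactly the ranked input."""
        fmri = rng.normal(size=(190,))
        group = rng.normal(size=(190,))
        rx = stats.rankdata(fmri)
        rz = stats.rankdata(group)
        design = np.column_stack([np.ones(190), rz])
        beta, *_ = np.linalg.lstsq(design, rx, rcond=None)
        fitted = design @ beta
        resid = rx - fitted
        folded = vector_to_matrix(resid)
        identity = np.arange(20)
        restored = folded[np.ix_(identity, identity)][np.triu_indices(20, 1)] + fitted
        assert np.allclose(restored, rx, atol=1e-10)

    def test_identity_shuffle_reproduces_observed_coefficient(self, rng):
        fmri, personal, group = rng.normal(size=(3, 45))
        observed = partial_rsa(fmri, personal, group)
        res = partial_rsa_permutation_test(fmri, personal, group, n_perm=300, seed=5)
        assert res.rho == pytest.approx(observed, abs=1e-12)
        assert res.z == pytest.approx(np.arctanh(observed), abs=1e-12)
        assert 0.0 <= res.p_perm <= 1.0

    def test_null_calibrated_when_personal_is_independent(self, rng):
        """The test must not inherit significance from a pure group-structure signal."""
        ps = []
        for _ in range(200):
            g = rng.normal(size=(12, 8))
            fmri = similarity_vector(np.hstack([g, g]) + rng.normal(scale=1.0, size=(12, 16)))
            personal = similarity_vector(rng.normal(size=(12, 16)))
            group = similarity_vector(np.hstack([g, g]) + rng.normal(scale=0.3, size=(12, 16)))
            res = partial_rsa_permutation_test(fmri, personal, group, n_perm=99, seed=rng)
            ps.append(res.p_perm)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_on_strong_person_specific_component(self, rng):
        g = rng.normal(size=(20, 10))
        personal_part = rng.normal(size=(20, 10))
        brain_patterns = np.hstack([g, personal_part])
        fmri = similarity_vector(brain_patterns)
        personal = similarity_vector(np.hstack([g, personal_part]) + rng.normal(scale=0.05, size=(20, 20)))
        group = similarity_vector(g)
        res = partial_rsa_permutation_test(fmri, personal, group, n_perm=1000, seed=3)
        assert res.p_perm <= 0.01

    def test_deterministic_under_fixed_seed(self, rng):
        fmri, personal, group = rng.normal(size=(3, 45))
        r1 = partial_rsa_permutation_test(fmri, personal, group, n_perm=100, seed=9)
        r2 = partial_rsa_permutation_test(fmri, personal, group, n_perm=100, seed=9)
        assert r1.p_perm == r2.p_perm


def test_fisher_z_clips_extremes():
    assert np.isfinite(fisher_z(1.0))
    assert np.isfinite(fisher_z(-1.0))
    assert fisher_z(0.0) == 0.0
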