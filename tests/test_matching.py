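"""Procrustes eigenmode matching: signed-permutation recovery, group
matching, the pairwise error metric, and bootstrap validation."""

import itertools

import numpy as np
import pytest

import voxgraph as vg
from voxgraph.matching import (
    EigenmodeSet,
    bootstrap_validation,
    group_match,
    procrustes_error,
    procrustes_reorder,
    random_orthonormal_set,
)


def exhaustive_best_assignment(X_ref, X_m):
    """Brute-force oracle: the column permutation maximizing total absolute
    cosine similarity, by enumerating all K! permutations (K <= 6)."""
    cos = X_ref.T @ X_m  # (ref position, source column)
    best, best_perm = -np.inf, None
    for perm in itertools.permutations(range(X_m.shape[1])):
        score = sum(abs(cos[j, perm[j]]) for j in range(len(perm)))
        if score > best:
            best, best_perm = score, np.array(perm)
    return best_perm


class TestProcrustesReorder:
    def test_identity_on_equal_inputs(self):
        x = random_orthonormal_set(50, 8, seed=0).matrix
        perm, signs, out = procrustes_reorder(x, x)
        np.testing.assert_array_equal(perm, np.arange(8))
        assert np.all(signs == 1)
        np.testing.assert_array_equal(out, x)

    def test_recovers_planted_swap_and_flip(self):
        x = random_orthonormal_set(60, 6, seed=1).matrix
        xm = x.copy()
        xm[:, [2, 5]] = xm[:, [5, 2]]
        xm[:, 3] *= -1
        perm, signs, out = procrustes_reorder(x, xm)
        expected = np.arange(6)
        expected[[2, 5]] = [5, 2]
        np.testing.assert_array_equal(perm, expected)
        assert signs[3] == -1 and np.all(np.delete(signs, 3) == 1)
        np.testing.assert_allclose(out, x, atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_noisy_recovery_matches_exhaustive_oracle(self, seed):
        """With perturbation small relative to mode separation, the recovered
        assignment equals both the planted one and the brute-force optimum."""
        rng = np.random.default_rng(seed)
        x = random_orthonormal_set(80, 6, seed=seed).matrix
        planted = rng.permutation(6)
        planted_signs = rng.choice([-1.0, 1.0], 6)
        xm = x[:, planted] * planted_signs + 0.02 * rng.standard_normal((80, 6))
        perm, signs, _ = procrustes_reorder(x, xm)
        # perm[j] says which column of xm lands at position j
        np.testing.assert_array_equal(perm, exhaustive_best_assignment(x, xm))
        # undoing the planted permutation: column planted[j] of x sits at xm
        # column j, so position planted[j] must pick source column j
        np.testing.assert_array_equal(perm[planted], np.arange(6))
        np.testing.assert_array_equal(signs[planted], planted_signs)

    def test_reorder_is_involution_compatible(self):
        """Applying the recovered signed permutation and re-running recovery
        yields the identity."""
        x = random_orthonormal_set(40, 5, seed=6).matrix
        rng = np.random.default_rng(7)
        xm = x[:, rng.permutation(5)] * rng.choice([-1.0, 1.0], 5)
        _, _, out = procrustes_reorder(x, xm)
        perm2, signs2, _ = procrustes_reorder(x, out)
        np.testing.assert_array_equal(perm2, np.arange(5))
        assert np.all(signs2 == 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            procrustes_reorder(np.eye(4), np.eye(3))


class TestGroupMatch:
    def test_identical_subjects_converge_immediately(self):
        x = random_orthonormal_set(30, 5, seed=8)
        res = group_match([x, x, x])
        for perm, signs in zip(res.permutations, res.signs):
            np.testing.assert_array_equal(perm, np.arange(5))
            assert np.all(signs == 1)
        np.testing.assert_allclose(res.group_average, x.matrix, atol=1e-12)

    def test_signed_permutation_pair_fully_aligned(self):
        x = random_orthonormal_set(40, 6, seed=9)
        rng = np.random.default_rng(10)
        xm = EigenmodeSet(x.matrix[:, rng.permutation(6)] * rng.choice([-1.0, 1.0], 6))
        res = group_match([x, xm])
        a, b = (s.matrix for s in res.reordered_sets)
        np.testing.assert_allclose(np.diag(a.T @ b), 1.0, atol=1e-12)

    def test_matching_reduces_cohort_error(self, scheme3):
        """On a perturbed synthetic cohort the post-match pairwise error is
        strictly below the pre-match error."""
        fields = vg.make_cohort(
            dict(shape=(12, 12, 12), seed=1),
            num_subjects=3,
            perturbation_sd=0.05,
            seed=11,
        )
        sets = []
        for f in fields:
            prof = vg.odf_profile(f, scheme3, 2.0)
            g = vg.assemble_graph(prof, f.phantom.anisotropy, f.phantom.mask, scheme3)
            dec = vg.eigendecompose(vg.normalized_laplacian(g), 20, seed=0)
            # scramble deliberately so matching has work to do
            rng = np.random.default_rng(len(sets))
            scrambled = dec.eigenvectors[:, rng.permutation(20)] * rng.choice(
                [-1.0, 1.0], 20
            )
            sets.append(EigenmodeSet(scrambled))
        pre = np.mean(
            [
                procrustes_error(sets[a].matrix, sets[b].matrix)
                for a in range(3)
                for b in range(a + 1, 3)
            ]
        )
        res = group_match(sets)
        post = np.mean(
            [
                procrustes_error(
                    res.reordered_sets[a].matrix, res.reordered_sets[b].matrix
                )
                for a in range(3)
                for b in range(a + 1, 3)
            ]
        )
        assert post < pre

    def test_fixed_iteration_count_honored(self):
        x = random_orthonormal_set(20, 4, seed=12)
        res = group_match([x, x], J=3)
        assert res.iterations_run == 3


class TestProcrustesError:
    def test_zero_for_identical_orthonormal_sets(self):
        x = random_orthonormal_set(30, 8, seed=13).matrix
        assert procrustes_error(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_swapped_columns_closed_form(self):
        x = random_orthonormal_set(30, 2, seed=14).matrix
        swapped = x[:, ::-1]
        assert procrustes_error(x, swapped) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-12
        )

    def test_symmetric_in_arguments(self):
        a = random_orthonormal_set(25, 6, seed=15).matrix
        b = random_orthonormal_set(25, 6, seed=16).matrix
        assert procrustes_error(a, b) == pytest.approx(
            procrustes_error(b, a), rel=1e-12
        )

    def test_nondecreasing_in_k(self):
        a = random_orthonormal_set(200, 20, seed=17).matrix
        b = random_orthonormal_set(200, 20, seed=18).matrix
        assert procrustes_error(a[:, :20], b[:, :20]) >= procrustes_error(
            a[:, :10], b[:, :10]
        )

    def test_zero_norm_column_rejected(self):
        x = random_orthonormal_set(10, 3, seed=19).matrix.copy()
        y = x.copy()
        y[:, 1] = 0.0
        with pytest.raises(ValueError, match="zero-norm"):
            procrustes_error(x, y)


class TestBootstrapValidation:
    def test_identical_subjects_give_zero_error(self):
        x = random_orthonormal_set(30, 10, seed=20)
        stats = bootstrap_validation([x, x, x], K_grid=[3, 6, 10], draws=5, seed=0)
        np.testing.assert_allclose(stats.mu, 0.0, atol=1e-12)
        np.testing.assert_allclose(stats.sigma, 0.0, atol=1e-12)

    def test_null_error_increases_with_k(self):
        null = [random_orthonormal_set(300, 20, seed=30 + i) for i in range(4)]
        stats = bootstrap_validation(null, K_grid=[5, 10, 20], draws=10, seed=1)
        assert np.all(np.diff(stats.mu) > 0)

    def test_deterministic_given_seed(self):
        sets = [random_orthonormal_set(50, 8, seed=40 + i) for i in range(3)]
        a = bootstrap_validation(sets, K_grid=[4, 8], draws=6, seed=2)
        b = bootstrap_validation(sets, K_grid=[4, 8], draws=6, seed=2)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_k_exceeding_modes_rejected(self):
        sets = [random_orthonormal_set(20, 5, seed=50 + i) for i in range(2)]
        with pytest.raises(ValueError, match="K=9"):
            bootstrap_validation(sets, K_grid=[3, 9], draws=2, seed=0)

    def test_higher_perturbation_raises_mu(self, scheme3):
        """Cohorts at two perturbation levels: the rougher cohort shows the
        larger mean Procrustes error at every K."""
        mus = {}
        for sd in (0.01, 0.1):
            fields = vg.make_cohort(
                dict(shape=(12, 12, 12), seed=1),
                num_subjects=3,
                perturbation_sd=sd,
                seed=21,
            )
            sets = []
            for f in fields:
                prof = vg.odf_profile(f, scheme3, 2.0)
                g = vg.assemble_graph(
                    prof, f.phantom.anisotropy, f.phantom.mask, scheme3
                )
                dec = vg.eigendecompose(vg.normalized_laplacian(g), 12, seed=0)
                sets.append(EigenmodeSet(dec.eigenvectors))
            stats = bootstrap_validation(sets, K_grid=[4, 8, 12], draws=6, seed=3)
            mus[sd] = stats.mu
        assert np.all(mus[0.1] > mus[0.01])
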