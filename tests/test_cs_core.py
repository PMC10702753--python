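"""Block transforms, Gaussian acquisition and OMP recovery."""

import numpy as np
import pytest

from blockcs import cs_core
from blockcs.fixtures import generate_sparse_vector


class TestSplitMerge:
    def test_block_count_256(self):
        plane = np.zeros((256, 256))
        assert len(cs_core.split_into_blocks(plane, 8)) == 1024

    def test_single_block_identity(self, rng):
        plane = rng.random((8, 8))
        (block,) = cs_core.split_into_blocks(plane, 8)
        np.testing.assert_array_equal(block, plane)

    def test_row_major_order_against_direct_indexing(self):
        plane = np.arange(256.0).reshape(16, 16)
        blocks = cs_core.split_into_blocks(plane, 8)
        assert len(blocks) == 4
        # row-major block order: top-left, top-right, bottom-left, bottom-right
        expected = [plane[:8, :8], plane[:8, 8:], plane[8:, :8], plane[8:, 8:]]
        for got, want in zip(blocks, expected):
            np.testing.assert_array_equal(got, want)
        np.testing.assert_array_equal(cs_core.merge_blocks(blocks, (16, 16)), plane)

    def test_merge_constant_blocks_quadrants(self):
        blocks = [np.full((8, 8), v) for v in (1.0, 2.0, 3.0, 4.0)]
        plane = cs_core.merge_blocks(blocks, (16, 16))
        assert plane[0, 0] == 1 and plane[0, 15] == 2
        assert plane[15, 0] == 3 and plane[15, 15] == 4

    def test_round_trip_random_plane(self, rng):
        plane = rng.random((64, 64))
        blocks = cs_core.split_into_blocks(plane, 8)
        np.testing.assert_array_equal(cs_core.merge_blocks(blocks, (64, 64)), plane)

    def test_single_block_merge(self, rng):
        block = rng.random((8, 8))
        np.testing.assert_array_equal(cs_core.merge_blocks([block], (8, 8)), block)

    def test_indivisible_dimension_named_in_error(self):
        with pytest.raises(ValueError, match="width 20"):
            cs_core.split_into_blocks(np.zeros((16, 20)), 8)
        with pytest.raises(ValueError, match="height 12"):
            cs_core.split_into_blocks(np.zeros((12, 16)), 8)

    def test_merge_count_mismatch(self):
        with pytest.raises(ValueError):
            cs_core.merge_blocks([np.zeros((8, 8))] * 3, (16, 16))


class TestDCT:
    def test_constant_block_concentrates_in_dc(self):
        coeff = cs_core.forward_dct2(np.full((8, 8), 3.0))
        assert coeff[0, 0] == pytest.approx(8 * 3.0)
        off_dc = coeff.copy()
        off_dc[0, 0] = 0.0
        assert np.abs(off_dc).max() < 1e-12

    def test_dc_only_inverts_to_constant(self):
        coeff = np.zeros((8, 8))
        coeff[0, 0] = 16.0
        np.testing.assert_allclose(
            cs_core.inverse_dct2(coeff), np.full((8, 8), 2.0), atol=1e-12
        )

    def test_zero_coefficients(self):
        np.testing.assert_array_equal(
            cs_core.inverse_dct2(np.zeros((8, 8))), np.zeros((8, 8))
        )

    def test_round_trip(self, rng):
        for _ in range(10):
            block = rng.normal(size=(8, 8)) * 100
            recon = cs_core.inverse_dct2(cs_core.forward_dct2(block))
            assert np.abs(recon - block).max() < 1e-10

    def test_parseval_energy_conservation(self, rng):
        block = rng.normal(size=(8, 8)) * 50
        coeff = cs_core.forward_dct2(block)
        assert np.sum(coeff**2) == pytest.approx(np.sum(block**2), rel=1e-8)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            cs_core.forward_dct2(np.zeros((4, 8)))


class TestVectorize:
    def test_column_major_convention(self):
        block = np.zeros((8, 8))
        block[0, 0] = 1.0
        block[7, 7] = 2.0
        block[3, 1] = 5.0
        v = cs_core.vectorize(block)
        assert v[0] == 1.0
        assert v[63] == 2.0
        assert v[1 * 8 + 3] == 5.0  # (r=3, c=1) -> c*B + r

    def test_round_trip(self, rng):
        block = rng.normal(size=(8, 8))
        np.testing.assert_array_equal(
            cs_core.devectorize(cs_core.vectorize(block), 8), block
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs_core.devectorize(np.zeros(63), 8)


class TestMeasurementMatrix:
    def test_shape_and_determinism(self):
        a1 = cs_core.make_measurement_matrix(32, 64, seed=5)
        a2 = cs_core.make_measurement_matrix(32, 64, seed=5)
        assert a1.shape == (32, 64)
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, cs_core.make_measurement_matrix(32, 64, 6))

    def test_entry_mean_within_clt_bound(self):
        a = cs_core.make_measurement_matrix(32, 64, seed=0)
        sigma = 1.0 / np.sqrt(32)
        assert abs(a.mean()) < 4 * sigma / np.sqrt(32 * 64)

    def test_entry_variance_scale(self):
        a = cs_core.make_measurement_matrix(64, 64, seed=3)
        assert a.var() == pytest.approx(1.0 / 64, rel=0.1)

    @pytest.mark.parametrize("m", [0, -1, 65])
    def test_invalid_measurement_counts(self, m):
        with pytest.raises(ValueError):
            cs_core.make_measurement_matrix(m, 64, seed=0)


class TestAcquire:
    def test_zero_vector(self):
        a = cs_core.make_measurement_matrix(32, 64, seed=0)
        np.testing.assert_array_equal(cs_core.acquire(a, np.zeros(64)), np.zeros(32))

    def test_linearity_and_length(self, rng):
        a = cs_core.make_measurement_matrix(32, 64, seed=0)
        v = rng.normal(size=64)
        y = cs_core.acquire(a, v)
        assert y.shape == (32,)
        np.testing.assert_allclose(cs_core.acquire(a, 2 * v), 2 * y, rtol=1e-12)

    def test_dimension_mismatch(self):
        a = cs_core.make_measurement_matrix(32, 64, seed=0)
        with pytest.raises(ValueError):
            cs_core.acquire(a, np.zeros(32))


class TestOMP:
    def test_zero_measurements(self):
        a = cs_core.make_measurement_matrix(8, 64, seed=0)
        result = cs_core.omp_reconstruct(a, np.zeros(8))
        assert result.iterations == 0
        assert result.support == []
        assert result.residual_norm == 0.0
        np.testing.assert_array_equal(result.estimate, np.zeros(64))

    def test_one_sparse_exact_recovery_vs_exhaustive_search(self):
        """Single-atom signals: OMP must match brute-force atom search."""
        for trial in range(20):
            a = cs_core.make_measurement_matrix(8, 64, seed=trial)
            v = generate_sparse_vector(64, 1, seed=1000 + trial)
            y = a @ v
            # oracle: try every atom, keep the best least-squares fit
            best = min(
                range(64),
                key=lambda j: np.linalg.norm(
                    y - a[:, [j]] @ np.linalg.lstsq(a[:, [j]], y, rcond=None)[0]
                ),
            )
            result = cs_core.omp_reconstruct(a, y)
            assert result.support[0] == best == np.flatnonzero(v)[0]
            assert np.abs(result.estimate - v).max() < 1e-8

    def test_four_sparse_matches_ls_on_true_support(self):
        agree = 0
        for trial in range(20):
            a = cs_core.make_measurement_matrix(32, 64, seed=trial)
            v = generate_sparse_vector(64, 4, seed=2000 + trial)
            y = a @ v
            support = np.flatnonzero(v)
            oracle = np.zeros(64)
            oracle[support] = np.linalg.lstsq(a[:, support], y, rcond=None)[0]
            est = cs_core.omp_reconstruct(a, y).estimate
            if np.linalg.norm(est - oracle) <= 1e-6 * np.linalg.norm(oracle):
                agree += 1
        assert agree == 20

    def test_residual_nonincreasing_and_no_duplicate_atoms(self, rng):
        a = cs_core.make_measurement_matrix(32, 64, seed=9)
        y = a @ rng.normal(size=64)  # dense signal: OMP runs to max_atoms
        result = cs_core.omp_reconstruct(a, y)
        hist = result.residual_history
        assert all(b <= a_ + 1e-9 for a_, b in zip(hist, hist[1:]))
        assert len(set(result.support)) == len(result.support)
        assert len(result.support) <= 32

    def test_nonzeros_confined_to_support(self, rng):
        a = cs_core.make_measurement_matrix(16, 64, seed=2)
        y = a @ generate_sparse_vector(64, 3, seed=3)
        result = cs_core.omp_reconstruct(a, y)
        outside = np.delete(result.estimate, result.support)
        assert np.all(outside == 0.0)

    def test_full_measurement_reproduces_signal(self, rng):
        a = cs_core.make_measurement_matrix(64, 64, seed=4)
        v = rng.normal(size=64)
        est = cs_core.omp_reconstruct(a, a @ v).estimate
        assert np.linalg.norm(est - v) < 1e-6 * np.linalg.norm(v)

    def test_zero_column_skipped(self):
        a = cs_core.make_measurement_matrix(8, 16, seed=5)
        a[:, 3] = 0.0
        v = np.zeros(16)
        v[7] = 2.0
        result = cs_core.omp_reconstruct(a, a @ v)
        assert 3 not in result.support

    def test_length_mismatch_rejected(self):
        a = cs_core.make_measurement_matrix(8, 16, seed=0)
        with pytest.raises(ValueError):
            cs_core.omp_reconstruct(a, np.zeros(9))

    def test_matches_sklearn_omp_on_normalized_dictionaries(self):
        """Independent solver cross-check on unit-norm atom dictionaries."""
        from sklearn.linear_model import OrthogonalMatchingPursuit

        for trial in range(10):
            a = cs_core.make_measurement_matrix(32, 64, seed=trial)
            a /= np.linalg.norm(a, axis=0)
            y = a @ generate_sparse_vector(64, 4, seed=trial + 100)
            sk = OrthogonalMatchingPursuit(
                n_nonzero_coefs=4, fit_intercept=False
            ).fit(a, y)
            mine = cs_core.omp_reconstruct(a, y, max_atoms=4)
            np.testing.assert_allclose(mine.estimate, sk.coef_, atol=1e-8)

    def test_recovery_rate_nondecreasing_in_measurements(self):
        """More measurements never hurt exact recovery of 4-sparse signals."""
        rates = []
        for m in (8, 16, 32, 64):
            hits = 0
            for trial in range(50):
                a = cs_core.make_measurement_matrix(m, 64, seed=trial)
                v = generate_sparse_vector(64, 4, seed=5000 + trial)
                est = cs_core.omp_reconstruct(a, a @ v).estimate
                hits += np.linalg.norm(est - v) < 1e-6 * np.linalg.norm(v)
            rates.append(hits / 50)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 1.0
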