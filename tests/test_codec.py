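import itertools

import numpy as np
import pytest

from spikecodec.codec import (
    build_downsampling_basis,
    build_fixed_basis,
    build_haar_basis,
    build_optimal_basis,
    compress,
    quantize,
    reconstruct,
)
from spikecodec.synthdata import make_surrogate_library


@pytest.fixture(scope="module")
def spike_matrix(rng):
    """Random spike-like matrix: smooth columns with varied shapes."""
    t = np.arange(64)
    cols = []
    for _ in range(200):
        c = rng.uniform(12, 24)
        w = rng.uniform(1.5, 5)
        a = rng.uniform(0.5, 2)
        cols.append(-a * np.exp(-0.5 * ((t - c) / w) ** 2) + 0.3 * a * np.exp(-0.5 * ((t - c - 8) / (2 * w)) ** 2))
    X = np.column_stack(cols) + 0.05 * rng.normal(size=(64, 200))
    return X


class TestOptimalBasis:
    def test_rank_one_matrix_gives_normalized_column(self, rng):
        v = rng.normal(size=16)
        X = np.tile(v[:, None], (1, 7))
        B = build_optimal_basis(X)
        w0 = B.W[:, 0]
        assert np.allclose(np.abs(w0 @ v), np.linalg.norm(v), atol=1e-10)

    def test_orthonormal(self, spike_matrix):
        B = build_optimal_basis(spike_matrix)
        assert np.allclose(B.W.T @ B.W, np.eye(64), atol=1e-10)

    def test_eckart_young_error_at_every_L(self, spike_matrix):
        """Frobenius reconstruction error equals the singular-value tail sum."""
        B = build_optimal_basis(spike_matrix)
        s2 = B.singular_values**2
        total = np.linalg.norm(spike_matrix, "fro") ** 2
        for L in range(1, 65):
            Xhat = reconstruct(compress(spike_matrix, B, L), B)
            err = np.linalg.norm(spike_matrix - Xhat, "fro") ** 2
            expected = s2[L:].sum()
            assert abs(err - expected) <= 1e-8 * total

    def test_error_monotone_in_L(self, spike_matrix):
        B = build_optimal_basis(spike_matrix)
        errs = [
            np.linalg.norm(spike_matrix - reconstruct(compress(spike_matrix, B, L), B), "fro")
            for L in range(1, 65)
        ]
        assert np.all(np.diff(errs) <= 1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            build_optimal_basis(np.empty((64, 0)))

    def test_leading_rows_carry_most_energy(self, rng):
        """For the optimal basis no 8-subset of coefficient rows beats the
        first 8 (checked exhaustively on a small instance)."""
        X = rng.normal(size=(16, 40)) * np.linspace(2, 0.1, 16)[:, None]
        B = build_optimal_basis(X)
        C = B.W.T @ X
        row_energy = np.sum(C**2, axis=1)
        first8 = row_energy[:8].sum()
        for subset in itertools.combinations(range(16), 8):
            assert first8 >= row_energy[list(subset)].sum() - 1e-9

    def test_sign_convention_deterministic(self, spike_matrix):
        a = build_optimal_basis(spike_matrix).W
        b = build_optimal_basis(spike_matrix.copy()).W
        assert np.array_equal(a, b)
        idx = np.argmax(np.abs(a), axis=0)
        assert np.all(a[idx, np.arange(64)] > 0)


class TestFixedBases:
    def test_deterministic_from_frozen_library(self):
        B1 = build_fixed_basis(make_surrogate_library(), "fixed2")
        B2 = build_fixed_basis(make_surrogate_library(), "fixed2")
        assert np.array_equal(B1.W, B2.W)

    def test_independent_of_compressed_data(self, spike_matrix, rng):
        B = build_fixed_basis(make_surrogate_library(), "fixed2")
        W_before = B.W.copy()
        compress(spike_matrix, B, 8)
        compress(rng.normal(size=(64, 30)), B, 4)
        assert np.array_equal(B.W, W_before)

    def test_undersized_library_rejected(self):
        with pytest.raises(ValueError):
            build_fixed_basis(np.ones((64, 10)), "fixed1")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_fixed_basis(np.ones((64, 100)), "optimal")


class TestDownsamplingBasis:
    def test_kept_rows_spacing(self):
        B = build_downsampling_basis(64, 16)
        assert B.downsample_factor == 4
        assert np.array_equal(B.kept_rows, np.arange(0, 64, 4))

    def test_full_L_is_identity(self):
        B = build_downsampling_basis(64, 64)
        E = B.selection_matrix(64)
        assert np.array_equal(E, np.eye(64))

    def test_constant_waveform_recovered_exactly(self):
        B = build_downsampling_basis(64, 16)
        x = np.full((64, 1), 3.14)
        xhat = reconstruct(compress(x, B, 16), B)
        assert np.allclose(xhat, x, atol=1e-10)

    def test_bandlimited_waveform_recovered(self, rng):
        # content strictly below fs/(2D) survives decimation + ideal interpolation
        D = 4
        spec = np.zeros(33, complex)
        spec[1:8] = rng.normal(size=7) + 1j * rng.normal(size=7)
        x = np.fft.irfft(spec, 64)[:, None]
        B = build_downsampling_basis(64, 16)
        xhat = reconstruct(compress(x, B, 16), B)
        assert np.linalg.norm(xhat - x) / np.linalg.norm(x) < 1e-6

    def test_invalid_L_rejected(self):
        with pytest.raises(ValueError):
            build_downsampling_basis(64, 65)


class TestHaarBasis:
    def test_two_point_basis(self):
        B = build_haar_basis(2)
        expected = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        assert np.allclose(B.W.T, expected)

    def test_orthonormal_64(self):
        B = build_haar_basis(64)
        assert np.allclose(B.W.T @ B.W, np.eye(64), atol=1e-12)

    def test_constant_energy_in_scaling_coefficient(self):
        B = build_haar_basis(64)
        c = compress(np.full((64, 1), 2.0), B, 64).C
        assert abs(c[0, 0]) == pytest.approx(16.0)  # 2 * sqrt(64)
        assert np.allclose(c[1:], 0.0, atol=1e-12)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            build_haar_basis(48)


class TestCompressReconstruct:
    @pytest.mark.parametrize("make", [build_optimal_basis, lambda X: build_haar_basis(64)])
    def test_full_L_round_trip(self, make, spike_matrix):
        B = make(spike_matrix)
        Xhat = reconstruct(compress(spike_matrix, B, 64), B)
        assert np.allclose(Xhat, spike_matrix, atol=1e-10)

    def test_parseval_at_full_L(self, spike_matrix):
        B = build_optimal_basis(spike_matrix)
        C = compress(spike_matrix, B, 64).C
        assert np.linalg.norm(C, "fro") == pytest.approx(
            np.linalg.norm(spike_matrix, "fro"), rel=1e-10
        )

    def test_first_basis_column_compresses_to_single_coefficient(self, spike_matrix):
        B = build_optimal_basis(spike_matrix)
        x = 2.5 * B.W[:, :1]
        C = compress(x, B, 8).C
        assert C[0, 0] == pytest.approx(2.5)
        assert np.allclose(C[1:], 0.0, atol=1e-10)

    def test_projection_equivalence(self, rng):
        """compress->reconstruct equals orthogonal projection onto the
        selected basis columns (explicit projector oracle, small M)."""
        X = rng.normal(size=(16, 9))
        B = build_optimal_basis(rng.normal(size=(16, 30)))
        for L in (1, 3, 7, 16):
            W_L = B.W[:, :L]
            proj = W_L @ W_L.T @ X
            assert np.allclose(reconstruct(compress(X, B, L), B), proj, atol=1e-10)

    def test_dimension_mismatch_rejected(self, spike_matrix):
        B = build_haar_basis(32)
        with pytest.raises(ValueError):
            compress(spike_matrix, B, 8)


class TestQuantize:
    def test_high_resolution_error_bound(self, rng):
        C = rng.normal(size=(8, 50))
        from spikecodec.codec import CoefficientSet

        cs = CoefficientSet(C, "optimal", 8)
        q = quantize(cs, bits=24)
        rng_span = C.max() - C.min()
        assert np.max(np.abs(q.C - C)) < 1e-4 * rng_span

    def test_constant_coefficients_passthrough(self):
        from spikecodec.codec import CoefficientSet

        cs = CoefficientSet(np.full((4, 5), 1.5), "haar", 4)
        with pytest.warns(UserWarning):
            q = quantize(cs, bits=10)
        assert np.array_equal(q.C, cs.C)

    def test_ten_bit_quantization_negligible_for_accuracy(self, spike_matrix):
        from spikecodec.evaluation import reconstruction_accuracy

        B = build_optimal_basis(spike_matrix)
        cs = compress(spike_matrix, B, 8)
        ids = np.zeros(spike_matrix.shape[1], int)
        tmpl = spike_matrix.mean(axis=1)[None, :]
        a_exact = reconstruction_accuracy(reconstruct(cs, B), tmpl, ids)
        a_q = reconstruction_accuracy(reconstruct(quantize(cs, 10), B), tmpl, ids)
        assert abs(a_exact - a_q) < 0.005

    def test_too_few_bits_rejected(self):
        from spikecodec.codec import CoefficientSet

        with pytest.raises(ValueError):
            quantize(CoefficientSet(np.ones((2, 2)), "haar", 2), bits=1)
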