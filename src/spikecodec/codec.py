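"""Transform coding of spike waveforms.

A spike matrix ``X`` (M samples x N spikes) is expanded on a basis ``W``
(M x M, basis waveforms in columns) as ``A = W^T X``; the L transmitted
coefficients are selected by a row-selection matrix ``E`` (L x M),
``C = E A``, and the receiver reconstructs ``Xhat = W E^T C``.

Five bases are supported:

* ``optimal``   — SVD of the spike matrix being compressed (reference case);
* ``fixed1``    — SVD of a large library of model-neuron waveforms (tuned to
                  the recording's neuron models but not to the recording);
* ``fixed2``    — SVD of a generic spike library unrelated to the test data;
* ``downsample``— identity basis with every D-th row kept (sample decimation,
                  no antialiasing), reconstruction followed by ideal lowpass
                  interpolation at fs/(2D);
* ``haar``      — orthonormal discrete Haar matrix, coarse scales first.

For the SVD and Haar bases E keeps the first L rows; coefficients of SVD
bases are ordered by decreasing significance so this selection is the natural
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .detection import SpikeMatrix

SVD_KINDS = ("optimal", "fixed1", "fixed2")
BASIS_KINDS = SVD_KINDS + ("downsample", "haar")


@dataclass
class CompressionBasis:
    W: np.ndarray  # M x M, basis waveforms in columns
    kind: str
    interpolation_required: bool = False
    singular_values: np.ndarray | None = None
    downsample_factor: int | None = None
    kept_rows: np.ndarray | None = None  # downsample basis only

    @property
    def M(self) -> int:
        return self.W.shape[0]

    def selection_matrix(self, L: int) -> np.ndarray:
        """L x M row-selection matrix E for keeping L coefficients."""
        M = self.M
        if not 1 <= L <= M:
            raise ValueError(f"L must be in [1, {M}]")
        if self.kind == "downsample":
            rows = self.kept_rows if self.kept_rows is not None else _decimation_rows(M, L)
            E = np.zeros((rows.size, M))
            E[np.arange(rows.size), rows] = 1.0
            return E
        E = np.zeros((L, M))
        E[np.arange(L), np.arange(L)] = 1.0
        return E


@dataclass
class CoefficientSet:
    C: np.ndarray  # L x N
    basis_ref: str
    L: int
    bits_per_coeff: int = 10
    quantized: bool = False
    kept_rows: np.ndarray | None = None

    @property
    def n_spikes(self) -> int:
        return self.C.shape[1]


def _fix_column_signs(W: np.ndarray) -> np.ndarray:
    """Make the largest-|magnitude| element of each column positive (SVD signs
    are arbitrary; fixing them makes bases reproducible)."""
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def _svd_basis(X: np.ndarray, kind: str) -> CompressionBasis:
    M = X.shape[0]
    U, s, _ = np.linalg.svd(X, full_matrices=True)
    sv = np.zeros(M)
    sv[: s.size] = s
    return CompressionBasis(W=_fix_column_signs(U), kind=kind, singular_values=sv)


def build_optimal_basis(X: SpikeMatrix | np.ndarray) -> CompressionBasis:
    """SVD basis of the spike matrix itself, ordered by singular value."""
    A = X.waveforms if isinstance(X, SpikeMatrix) else np.asarray(X, float)
    if A.ndim != 2 or A.shape[1] == 0:
        raise ValueError("need a non-empty M x N spike matrix")
    return _svd_basis(A, "optimal")


def build_fixed_basis(library: np.ndarray, kind: str) -> CompressionBasis:
    """SVD basis of a pre-computed waveform library (``fixed1``/``fixed2``)."""
    if kind not in ("fixed1", "fixed2"):
        raise ValueError("kind must be 'fixed1' or 'fixed2'")
    library = np.asarray(library, float)
    M, K = library.shape
    if K < M:
        raise ValueError(f"library must have at least M={M} waveforms (got {K})")
    return _svd_basis(library, kind)


def _decimation_rows(M: int, L: int) -> np.ndarray:
    D = int(round(M / L))
    return np.arange(0, M, max(D, 1))


def build_downsampling_basis(M: int, L: int) -> CompressionBasis:
    """Identity basis with every D-th sample kept, D = round(M/L).

    The actual number of kept samples may differ slightly from L when M/L is
    not integer; the kept count is recorded and should be used in rate
    accounting.  Reconstruction requires lowpass interpolation.
    """
    if not 1 <= L <= M:
        raise ValueError("need 1 <= L <= M")
    rows = _decimation_rows(M, L)
    return CompressionBasis(
        W=np.eye(M),
        kind="downsample",
        interpolation_required=True,
        downsample_factor=int(round(M / L)),
        kept_rows=rows,
    )


def build_haar_basis(M: int) -> CompressionBasis:
    """Orthonormal discrete Haar matrix, coarse (scaling) functions first."""
    if M < 1 or M & (M - 1):
        raise ValueError("M must be a power of two")
    H = np.array([[1.0]])
    while H.shape[0] < M:
        n = H.shape[0]
        top = np.kron(H, [1.0, 1.0])
        bot = np.kron(np.eye(n), [1.0, -1.0]) * np.sqrt(n)
        H = np.vstack([top, bot])
    H /= np.sqrt(M)
    # rows of H are the Haar functions; basis waveforms go in columns of W
    return CompressionBasis(W=H.T, kind="haar")


def compress(X: SpikeMatrix | np.ndarray, basis: CompressionBasis, L: int) -> CoefficientSet:
    """Transform and keep L coefficients: ``C = E W^T X``."""
    A = X.waveforms if isinstance(X, SpikeMatrix) else np.asarray(X, float)
    if A.shape[0] != basis.M:
        raise ValueError("spike length does not match basis dimension")
    if basis.kind == "downsample":
        basis = build_downsampling_basis(basis.M, L)
    E = basis.selection_matrix(L)
    C = E @ (basis.W.T @ A)
    return CoefficientSet(
        C=C, basis_ref=basis.kind, L=L,
        kept_rows=basis.kept_rows.copy() if basis.kept_rows is not None else None,
    )


def quantize(coeffs: CoefficientSet, bits: int = 10) -> CoefficientSet:
    """Uniform mid-rise quantization over the coefficient range.

    Used only to make the data-rate accounting realistic; off by default in
    the evaluation pipeline.
    """
    if bits < 2:
        raise ValueError("need at least 2 bits")
    C = coeffs.C
    lo, hi = C.min(), C.max()
    if hi == lo:
        warnings.warn("degenerate coefficient range; quantization is a no-op")
        return CoefficientSet(C.copy(), coeffs.basis_ref, coeffs.L, bits, True, coeffs.kept_rows)
    step = (hi - lo) / (2**bits)
    q = lo + (np.floor((C - lo) / step) + 0.5) * step
    q = np.clip(q, lo, hi)
    return CoefficientSet(q, coeffs.basis_ref, coeffs.L, bits, True, coeffs.kept_rows)


def _lowpass_interpolate(Xhat: np.ndarray, D: int) -> np.ndarray:
    """Ideal frequency-domain lowpass interpolation of zero-stuffed columns.

    Keeps DFT bins below fs/(2D) and rescales by D to restore amplitude.
    """
    M = Xhat.shape[0]
    F = np.fft.rfft(Xhat, axis=0)
    cutoff_bin = M / (2 * D)
    bins = np.arange(F.shape[0])
    F[bins > cutoff_bin] = 0.0
    F[bins == cutoff_bin] *= 0.5  # half-weight an exactly-Nyquist bin
    return np.fft.irfft(F, M, axis=0) * D


def reconstruct(coeffs: CoefficientSet, basis: CompressionBasis) -> np.ndarray:
    """Receiver-side reconstruction ``Xhat = W E^T C`` (plus lowpass
    interpolation for the downsampling basis)."""
    if basis.kind != coeffs.basis_ref:
        raise ValueError("coefficients were produced with a different basis kind")
    if basis.kind == "downsample" and coeffs.kept_rows is not None:
        rows = coeffs.kept_rows
        E = np.zeros((rows.size, basis.M))
        E[np.arange(rows.size), rows] = 1.0
    else:
        E = basis.selection_matrix(coeffs.C.shape[0])
    if E.shape[0] != coeffs.C.shape[0]:
        raise ValueError("coefficient count does not match the selection matrix")
    Xhat = basis.W @ (E.T @ coeffs.C)
    if basis.interpolation_required:
        D = basis.downsample_factor or int(round(basis.M / coeffs.L))
        Xhat = _lowpass_interpolate(Xhat, D)
    return Xhat
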