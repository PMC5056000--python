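"""Shift-invariant tight frames: fixed Haar bank, learned banks, operators.

A bank of m real p x p filters whose vectorized kernels are the rows of an
orthogonal p^2 x p^2 matrix scaled by 1/p generates, under periodic
(circular) correlation at unit stride, an undecimated tight frame: the
analysis operator W satisfies W^H W = I (the unitary extension principle),
so synthesis(analysis(x)) = x exactly and the frame preserves energy.  The
fixed layer is the 2 x 2 shift-invariant Haar system; the adaptive layer is
learned from the data by an orthogonality-constrained least-squares
(Procrustes) update solved with an SVD.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.fft import dct

__all__ = [
    "FilterBank",
    "CoefficientStack",
    "haar_fixed_bank",
    "delta_bank",
    "init_adaptive_bank",
    "analysis",
    "synthesis",
    "extract_patches",
    "update_filters_svd",
]


def _fourier_symbols(filters: np.ndarray, n: int) -> np.ndarray:
    """DFT of each p x p kernel zero-embedded on an n x n grid."""
    m, p, _ = filters.shape
    kernels = np.zeros((m, n, n))
    kernels[:, :p, :p] = filters
    return np.fft.fft2(kernels, axes=(-2, -1))


def _uep_residual(filters: np.ndarray, n: int = 32) -> float:
    """Exact operator-norm distance of W^H W from identity.

    For a shift-invariant bank W^H W is diagonal in the Fourier basis with
    symbol sum_m |h_hat_m|^2, so the residual is computed exactly from the
    filter DFTs rather than sampled on random images.
    """
    h = _fourier_symbols(filters, n)
    symbol = np.sum(np.abs(h) ** 2, axis=0)
    return float(np.max(np.abs(symbol - 1.0)))


@dataclasses.dataclass
class FilterBank:
    """A set of m real p x p filters generating a shift-invariant frame.

    ``uep_residual`` is the measured distance of W^H W from the identity;
    it is < 1e-10 for every bank this module constructs.
    """

    filters: np.ndarray
    layer: str = "adaptive"  # "fixed" or "adaptive"
    uep_residual: float = dataclasses.field(init=False)
    _fft_cache: dict = dataclasses.field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        filters = np.asarray(self.filters, dtype=float)
        if filters.ndim != 3 or filters.shape[1] != filters.shape[2]:
            raise ValueError("filters must have shape (m, p, p)")
        self.filters = filters
        self.uep_residual = _uep_residual(filters, n=max(32, 2 * self.p))

    @property
    def m(self) -> int:
        return self.filters.shape[0]

    @property
    def p(self) -> int:
        return self.filters.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """The m x p^2 scaled filter matrix W (rows are vectorized kernels)."""
        return self.filters.reshape(self.m, -1)

    def _symbols(self, n: int) -> np.ndarray:
        if n not in self._fft_cache:
            self._fft_cache[n] = _fourier_symbols(self.filters, n)
        return self._fft_cache[n]

    def analyze(self, image: np.ndarray) -> np.ndarray:
        """Periodic correlation of the image with every filter (unit stride).

        ``image`` may carry leading axes (e.g. a stack of coefficient
        channels); the filters act on the trailing two.  Output shape is
        ``(m, *image.shape)``.
        """
        image = np.asarray(image, dtype=complex)
        n = image.shape[-1]
        if image.shape[-2] != n:
            raise ValueError("image must be square in its trailing axes")
        if self.p > n:
            raise ValueError(f"filter size {self.p} exceeds image size {n}")
        h = self._symbols(n)
        x_hat = np.fft.fft2(image, axes=(-2, -1))
        out = np.empty((self.m, *image.shape), dtype=complex)
        for i in range(self.m):
            out[i] = np.fft.ifft2(np.conj(h[i]) * x_hat, axes=(-2, -1))
        return out

    def synthesize(self, stack: np.ndarray) -> np.ndarray:
        """Adjoint W^H of :meth:`analyze`; the inverse when the bank is tight."""
        stack = np.asarray(stack, dtype=complex)
        if stack.shape[0] != self.m:
            raise ValueError(
                f"stack has {stack.shape[0]} channels, bank has {self.m} filters"
            )
        n = stack.shape[-1]
        if stack.shape[-2] != n:
            raise ValueError("stack must be square in its trailing axes")
        h = self._symbols(n)
        acc = np.zeros(stack.shape[1:], dtype=complex)
        for i in range(self.m):
            acc += np.fft.ifft2(h[i] * np.fft.fft2(stack[i], axes=(-2, -1)), axes=(-2, -1))
        return acc


@dataclasses.dataclass
class CoefficientStack:
    """Per-filter coefficient images produced by an analysis operator."""

    data: np.ndarray
    bank: FilterBank

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def norm(self) -> float:
        return float(np.linalg.norm(self.data))

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)


def analysis(bank: FilterBank, image: np.ndarray) -> CoefficientStack:
    """Apply the frame analysis operator W; see :meth:`FilterBank.analyze`."""
    return CoefficientStack(data=bank.analyze(image), bank=bank)


def synthesis(bank: FilterBank, stack: CoefficientStack | np.ndarray) -> np.ndarray:
    """Apply the synthesis operator W^H; see :meth:`FilterBank.synthesize`."""
    data = stack.data if isinstance(stack, CoefficientStack) else stack
    return bank.synthesize(data)


def _order_filters(matrix: np.ndarray) -> np.ndarray:
    """Deterministic ordering for constructed banks.

    The low-pass-most kernel (largest |DC| response, sign flipped
    nonnegative) comes first; the rest follow by decreasing |DC| response
    with lexicographic tie-break on the kernel entries.  Only applied to
    deterministic constructors: reordering a Procrustes solution would
    change its objective value.
    """
    matrix = matrix.copy()
    for i in range(matrix.shape[0]):
        dc = matrix[i].sum()
        if dc < -1e-12:
            matrix[i] = -matrix[i]
        elif abs(dc) <= 1e-12:
            nz = np.flatnonzero(np.abs(matrix[i]) > 1e-12)
            if nz.size and matrix[i, nz[0]] < 0:
                matrix[i] = -matrix[i]
    keys = [
        (-round(abs(matrix[i].sum()), 10), tuple(np.round(matrix[i], 10)))
        for i in range(matrix.shape[0])
    ]
    order = sorted(range(matrix.shape[0]), key=lambda i: keys[i])
    return matrix[order]


def _haar_matrix(p: int) -> np.ndarray:
    """Orthonormal 1-D Haar basis (rows), p a power of two."""
    h = np.array([[1.0]])
    while h.shape[0] < p:
        h = np.vstack(
            [np.kron(h, [1.0, 1.0]), np.kron(np.eye(h.shape[0]), [1.0, -1.0])]
        )
    h /= np.linalg.norm(h, axis=1, keepdims=True)
    return h


def haar_fixed_bank() -> FilterBank:
    """The fixed layer: four 2 x 2 shift-invariant Haar filters (LL, LH, HL, HH).

    The kernels are the 2-D Haar patch basis scaled by 1/2, so the
    undecimated system is a tight frame (W^H W = I): the low-pass filter
    reproduces constants and the three high-pass filters annihilate them.
    """
    bank = init_adaptive_bank(2)
    return FilterBank(filters=bank.filters, layer="fixed")


def delta_bank() -> FilterBank:
    """Single-filter identity bank (W = I); the fixed layer of the one-layer
    data-driven tight frame baseline."""
    return FilterBank(filters=np.ones((1, 1, 1)), layer="fixed")


def init_adaptive_bank(p: int, init: str = "haar") -> FilterBank:
    """Deterministic tight initialization of a p^2-filter bank of p x p kernels.

    ``init='haar'`` builds the separable 2-D Haar-type orthogonal patch
    basis (p a power of two); ``init='dct'`` uses the orthonormal DCT-II
    basis (any p).  Either way the kernels are rows of an orthogonal
    p^2 x p^2 matrix scaled by 1/p, hence tight.
    """
    if p < 2:
        raise ValueError("filter size must be >= 2")
    if init == "haar" and p & (p - 1) == 0:
        basis = _haar_matrix(p)
    elif init in ("haar", "dct"):
        basis = dct(np.eye(p), axis=1, norm="ortho")
    else:
        raise ValueError(f"unknown init '{init}'")
    kernels = np.stack(
        [np.outer(basis[i], basis[j]) for i in range(p) for j in range(p)]
    )
    matrix = _order_filters(kernels.reshape(p * p, -1) / p)
    return FilterBank(filters=matrix.reshape(p * p, p, p), layer="adaptive")


def extract_patches(image: np.ndarray, p: int, stride: str = "unit") -> np.ndarray:
    """Vectorized p x p patches of a 2-D array as columns of a p^2 x L matrix.

    ``stride='unit'`` takes one patch per pixel with periodic wrap (L = N^2,
    raster order), matching the shift-invariant analysis operator: column
    (i*N + j) holds x[(i+s) % N, (j+t) % N] at row (s*p + t).
    ``stride='nonoverlap'`` partitions the grid into disjoint blocks
    (requires p | N).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("extract_patches expects a 2-D array")
    n = image.shape[0]
    if p > n:
        raise ValueError(f"patch size {p} exceeds grid size {n}")
    if stride == "unit":
        rows = [
            np.roll(image, (-s, -t), axis=(0, 1)).ravel()
            for s in range(p)
            for t in range(p)
        ]
        return np.stack(rows)
    if stride == "nonoverlap":
        if n % p:
            raise ValueError("nonoverlap stride requires p to divide the grid size")
        blocks = image.reshape(n // p, p, n // p, p).transpose(0, 2, 1, 3)
        return blocks.reshape(-1, p * p).T
    raise ValueError(f"unknown stride '{stride}'")


def update_filters_svd(
    patch_matrix: np.ndarray,
    coeff_matrix: np.ndarray,
    previous: FilterBank | None = None,
) -> FilterBank:
    """Tight-frame filter update: orthogonal Procrustes via SVD.

    Minimizes ||W P - C||_F over banks W = (1/p) O with O orthogonal, where
    P stacks image patches and C the target coefficient vectors.  Since
    ||W P||_F is then fixed, the minimizer maximizes Re tr(O P C^H) and is
    W = (1/p) U V^T from the SVD of Re(C P^H) = U S V^T (the real part
    keeps learned filters real on complex data).  Singular-vector signs are
    pinned (largest-magnitude entry of each left vector positive, the right
    vector flipped with it), which leaves W itself unchanged.
    """
    patch_matrix = np.asarray(patch_matrix)
    coeff_matrix = np.asarray(coeff_matrix)
    if patch_matrix.shape != coeff_matrix.shape:
        raise ValueError("patch and coefficient matrices must share a shape")
    msq, ell = patch_matrix.shape
    p = int(round(np.sqrt(msq)))
    if p * p != msq:
        raise ValueError("row count must be a perfect square p^2")
    if ell < msq:
        raise ValueError(f"need at least p^2={msq} patches, got {ell}")
    cross = np.real(coeff_matrix @ patch_matrix.conj().T)
    scale = np.linalg.norm(patch_matrix) * np.linalg.norm(coeff_matrix)
    if scale == 0 or np.linalg.norm(cross) < 1e-14 * max(scale, 1.0):
        warnings.warn(
            "degenerate (all-zero) input to the filter update; keeping the "
            "previous bank",
            RuntimeWarning,
            stacklevel=2,
        )
        return previous if previous is not None else init_adaptive_bank(p)
    u, _, vt = np.linalg.svd(cross)
    for i in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i, :] = -vt[i, :]
    w = (u @ vt) / p
    return FilterBank(filters=w.reshape(msq, p, p), layer="adaptive")
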