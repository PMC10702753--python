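"""Block-level compressive-sensing primitives.

The acquisition model is classical block-based CS: an image plane is tiled
into B x B blocks, each block is sparsified with the orthonormal 2-D DCT,
vectorized to length L = B**2, and compressed by a single shared Gaussian
measurement matrix A (M x L, M <= L) as Y = A v.  Reconstruction inverts
the chain with orthogonal matching pursuit (OMP): greedily pick the
dictionary atom most correlated with the residual, refit by least squares
on the accumulated support, and stop at a residual tolerance or at
``max_atoms`` selected atoms.

All functions are pure and deterministic given their inputs (the matrix
generator is seeded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn

__all__ = [
    "OMPResult",
    "split_into_blocks",
    "merge_blocks",
    "forward_dct2",
    "inverse_dct2",
    "vectorize",
    "devectorize",
    "make_measurement_matrix",
    "acquire",
    "omp_reconstruct",
]


def split_into_blocks(plane: np.ndarray, block_size: int) -> list[np.ndarray]:
    """Tile a square image plane into B x B blocks in row-major block order.

    Parameters
    ----------
    plane : (N, N) array
        One image channel.
    block_size : int
        Block side length B >= 2; both plane dimensions must be divisible
        by it.

    Returns
    -------
    list of (B, B) arrays, ordered left-to-right then top-to-bottom, whose
    concatenation tiles the plane exactly.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got shape {plane.shape}")
    if block_size < 2:
        raise ValueError(f"block size must be >= 2, got {block_size}")
    h, w = plane.shape
    for name, dim in (("height", h), ("width", w)):
        if dim % block_size != 0:
            raise ValueError(
                f"plane {name} {dim} is not divisible by block size {block_size}"
            )
    b = block_size
    blocks = (
        plane.reshape(h // b, b, w // b, b)
        .swapaxes(1, 2)
        .reshape(-1, b, b)
    )
    return [blocks[i] for i in range(blocks.shape[0])]


def merge_blocks(blocks: list[np.ndarray], dims: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`split_into_blocks` under the same ordering."""
    h, w = dims
    if not blocks:
        raise ValueError("no blocks to merge")
    arr = np.asarray(blocks, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("blocks must be a list of equal square matrices")
    b = arr.shape[1]
    if arr.shape[0] * b * b != h * w:
        raise ValueError(
            f"{arr.shape[0]} blocks of size {b}x{b} cannot tile a {h}x{w} plane"
        )
    return (
        arr.reshape(h // b, w // b, b, b)
        .swapaxes(1, 2)
        .reshape(h, w)
    )


def forward_dct2(block: np.ndarray) -> np.ndarray:
    """Orthonormal type-II 2-D DCT of a square block (energy preserving)."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[0] != block.shape[1]:
        raise ValueError(f"expected a square block, got shape {block.shape}")
    return dctn(block, type=2, norm="ortho")


def inverse_dct2(coeff: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_dct2`."""
    coeff = np.asarray(coeff, dtype=float)
    if coeff.ndim != 2 or coeff.shape[0] != coeff.shape[1]:
        raise ValueError(f"expected a square block, got shape {coeff.shape}")
    return idctn(coeff, type=2, norm="ortho")


def vectorize(coeff: np.ndarray) -> np.ndarray:
    """Flatten a B x B coefficient block to length B**2, column-major.

    Element (r, c) maps to index c*B + r.  Any fixed bijection works for
    the acquisition algebra; column-major is this codec's convention.
    """
    coeff = np.asarray(coeff, dtype=float)
    if coeff.ndim != 2 or coeff.shape[0] != coeff.shape[1]:
        raise ValueError(f"expected a square block, got shape {coeff.shape}")
    return coeff.reshape(-1, order="F")


def devectorize(v: np.ndarray, block_size: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: length B**2 vector back to B x B."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size != block_size * block_size:
        raise ValueError(
            f"vector of length {v.size} does not reshape to "
            f"{block_size}x{block_size}"
        )
    return v.reshape(block_size, block_size, order="F")


def make_measurement_matrix(m: int, ambient_dim: int, seed: int) -> np.ndarray:
    """Gaussian measurement matrix A with i.i.d. N(0, 1/M) entries.

    The 1/M variance makes ``||A v|| ~ ||v||`` in expectation.  Identical
    seeds give bitwise-identical matrices, which lets encoder and decoder
    share A through the compressed header.
    """
    if m < 1:
        raise ValueError(f"measurement count must be >= 1, got {m}")
    if m > ambient_dim:
        raise ValueError(
            f"measurement count {m} exceeds ambient dimension {ambient_dim}; "
            "compressive acquisition requires M <= L"
        )
    rng = np.random.default_rng(seed)
    return rng.standard_normal((m, ambient_dim)) / np.sqrt(m)


def acquire(a: np.ndarray, v: np.ndarray) -> np.ndarray:
    """CS acquisition Y = A v (length M)."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float).ravel()
    if a.ndim != 2 or a.shape[1] != v.size:
        raise ValueError(
            f"matrix of shape {a.shape} cannot acquire a length-{v.size} vector"
        )
    return a @ v


@dataclass
class OMPResult:
    """Outcome of an OMP reconstruction.

    Attributes
    ----------
    estimate : (L,) array
        Support-restricted least-squares solution embedded in length L.
    support : list of int
        Atom indices in selection order (no repeats).
    residual_norm : float
        ``||Y - A @ estimate||_2`` at termination.
    iterations : int
        Number of greedy selections performed.
    residual_history : list of float
        Residual norm after each iteration (starting point included).
    """

    estimate: np.ndarray
    support: list[int]
    residual_norm: float
    iterations: int
    residual_history: list[float] = field(default_factory=list)


def omp_reconstruct(
    a: np.ndarray,
    y: np.ndarray,
    max_atoms: int | None = None,
    tol: float | None = None,
) -> OMPResult:
    """Orthogonal matching pursuit for ``Y = A v`` with sparse ``v``.

    Per iteration the atom (column of the column-normalized copy of A)
    with maximal absolute correlation to the residual is added to the
    support, the least-squares fit of Y on the supported columns of the
    *original* A is recomputed, and the residual is updated.  Stops when
    the residual norm drops to ``tol`` (default ``1e-6 * ||Y||``) or
    ``max_atoms`` atoms (default M) have been selected.  All-zero columns
    are never selected.
    """
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, ell = a.shape
    if y.size != m:
        raise ValueError(
            f"measurement vector length {y.size} does not match A's {m} rows"
        )
    if max_atoms is None:
        max_atoms = m
    if not 1 <= max_atoms <= m:
        raise ValueError(f"max_atoms must be in [1, {m}], got {max_atoms}")

    y_norm = float(np.linalg.norm(y))
    if tol is None:
        tol = 1e-6 * y_norm

    col_norms = np.linalg.norm(a, axis=0)
    usable = col_norms > 0
    # correlations use unit-norm atoms; the LS refit uses raw columns
    a_unit = np.where(usable, col_norms, 1.0)

    estimate = np.zeros(ell)
    support: list[int] = []
    residual = y.copy()
    res_norm = y_norm
    history = [res_norm]

    if y_norm == 0.0:
        return OMPResult(estimate, support, 0.0, 0, history)

    available = usable.copy()
    while res_norm > tol and len(support) < max_atoms:
        corr = np.abs(a.T @ residual) / a_unit
        corr[~available] = -np.inf
        best = int(np.argmax(corr))
        if not np.isfinite(corr[best]):
            break  # no usable atom left
        support.append(best)
        available[best] = False
        a_s = a[:, support]
        # least squares on the support via normal equations (Gaussian
        # submatrices are well conditioned for |support| <= M); SVD fallback
        try:
            coef = np.linalg.solve(a_s.T @ a_s, a_s.T @ y)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(a_s, y, rcond=None)
        residual = y - a_s @ coef
        res_norm = float(np.linalg.norm(residual))
        history.append(res_norm)

    if support:
        estimate[support] = coef
    return OMPResult(estimate, support, res_norm, len(support), history)
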