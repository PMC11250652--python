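"""Dense multilinear algebra primitives.

Conventions
-----------
Modes are numbered 1..N at the API surface (matching the standard tensor
literature); internal axis arithmetic is 0-based and hidden.

The mode-n unfolding follows the Kolda–Bader index map: entry
``(i_1, ..., i_N)`` of the tensor lands at row ``i_n`` and column

    j = 1 + sum_{k != n} (i_k - 1) * J_k,   J_k = prod_{m < k, m != n} I_m

(all 1-based).  Equivalently: move mode n to the front and reshape in
Fortran (column-major) order.  This column order is normative — singular
value thresholding of unfoldings depends on it only up to column
permutation, but round-trips and matricized identities pin it exactly.

All computation is in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShapeError",
    "ModeRangeError",
    "as_tensor",
    "unfold",
    "fold",
    "mode_n_product",
    "multi_mode_product",
    "TuckerModel",
    "tucker_reconstruct",
    "inner_product",
    "frobenius_norm",
    "kronecker",
]


class ShapeError(ValueError):
    """Dimensions of an operand do not conform."""


class ModeRangeError(IndexError):
    """A mode index lies outside 1..N."""


def as_tensor(data, *, min_order: int = 2) -> np.ndarray:
    """Validate and coerce ``data`` to a finite float64 N-way array.

    Parameters
    ----------
    data : array_like
        The tensor entries.
    min_order : int
        Minimum number of modes required (default 2).

    Returns
    -------
    numpy.ndarray
        A C-contiguous float64 array of order >= ``min_order``.
    """
    a = np.ascontiguousarray(data, dtype=np.float64)
    if a.ndim < min_order:
        raise ShapeError(f"tensor must have order >= {min_order}, got {a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError("tensor entries must all be finite")
    return a


def _check_mode(n: int, order: int) -> int:
    """Map a 1-based mode index to a 0-based axis, validating the range."""
    if not 1 <= n <= order:
        raise ModeRangeError(f"mode {n} out of range for order-{order} tensor")
    return n - 1


def unfold(x: np.ndarray, n: int) -> np.ndarray:
    """Mode-n unfolding (matricization) of ``x``.

    Returns the ``I_n x prod_{j != n} I_j`` matrix whose columns enumerate
    the remaining modes in the Kolda–Bader order (mode 1 fastest, skipping
    mode n).
    """
    x = np.asarray(x)
    ax = _check_mode(n, x.ndim)
    return np.moveaxis(x, ax, 0).reshape(x.shape[ax], -1, order="F")


def fold(m: np.ndarray, n: int, shape) -> np.ndarray:
    """Inverse of :func:`unfold`: refold matrix ``m`` along mode ``n``.

    ``shape`` is the full tensor shape ``(I_1, ..., I_N)``; ``m`` must be
    ``I_n x prod_{j != n} I_j``.
    """
    m = np.asarray(m)
    shape = tuple(int(s) for s in shape)
    ax = _check_mode(n, len(shape))
    rest = [s for j, s in enumerate(shape) if j != ax]
    if m.shape != (shape[ax], int(np.prod(rest, dtype=np.int64))):
        raise ShapeError(
            f"matrix of shape {m.shape} cannot fold to {shape} along mode {n}"
        )
    t = m.reshape([shape[ax]] + rest, order="F")
    return np.moveaxis(t, 0, ax)


def mode_n_product(x: np.ndarray, u: np.ndarray, n: int) -> np.ndarray:
    """Mode-n product ``x ×_n u``: left-multiply the mode-n unfolding by ``u``.

    ``u`` is ``J x I_n``; the result has mode n of extent ``J`` and
    satisfies ``unfold(result, n) == u @ unfold(x, n)``.
    """
    x = np.asarray(x)
    u = np.asarray(u)
    ax = _check_mode(n, x.ndim)
    if u.ndim != 2 or u.shape[1] != x.shape[ax]:
        raise ShapeError(
            f"factor of shape {u.shape} does not conform with mode {n} "
            f"of extent {x.shape[ax]}"
        )
    return np.moveaxis(np.tensordot(u, x, axes=(1, ax)), 0, ax)


def multi_mode_product(
    x: np.ndarray,
    factors,
    *,
    transpose: bool = False,
    skip: int | None = None,
) -> np.ndarray:
    """Apply ``mode_n_product`` with ``factors[i-1]`` along each mode i.

    Parameters
    ----------
    x : ndarray
    factors : sequence of N matrices, one per mode (entry for a skipped
        mode may be anything, it is not touched).
    transpose : bool
        Apply each factor transposed (projection onto factor columns).
    skip : int or None
        1-based mode to leave untouched.

    Distinct-mode products commute, so the application order is
    immaterial; modes are applied in increasing order.
    """
    x = np.asarray(x)
    if len(factors) != x.ndim:
        raise ShapeError(
            f"expected {x.ndim} factors for an order-{x.ndim} tensor, "
            f"got {len(factors)}"
        )
    out = x
    for i, u in enumerate(factors, start=1):
        if skip is not None and i == skip:
            continue
        u = np.asarray(u)
        out = mode_n_product(out, u.T if transpose else u, i)
    return out


@dataclass(frozen=True)
class TuckerModel:
    """A Tucker decomposition: core tensor plus per-mode factor matrices.

    ``core`` has shape ``(R_1, ..., R_N)``; ``factors[i-1]`` is
    ``I_i x R_i`` with orthonormal columns.  The reconstruction is
    ``core ×_1 U_1 ×_2 ... ×_N U_N``.
    """

    core: np.ndarray
    factors: tuple = field(default_factory=tuple)

    ORTHO_TOL = 1e-10

    def __post_init__(self):
        object.__setattr__(self, "core", as_tensor(self.core, min_order=1))
        object.__setattr__(
            self, "factors", tuple(np.asarray(u, dtype=np.float64) for u in self.factors)
        )

    @property
    def order(self) -> int:
        return self.core.ndim

    @property
    def shape(self) -> tuple:
        """Shape (I_1, ..., I_N) of the reconstructed tensor."""
        return tuple(u.shape[0] for u in self.factors)

    @property
    def rank(self) -> tuple:
        return self.core.shape

    def validate(self) -> None:
        """Check shape conformance and column orthonormality of the factors."""
        if len(self.factors) != self.order:
            raise ShapeError(
                f"core of order {self.order} needs {self.order} factors, "
                f"got {len(self.factors)}"
            )
        for i, u in enumerate(self.factors, start=1):
            if u.ndim != 2 or u.shape[1] != self.core.shape[i - 1]:
                raise ShapeError(
                    f"factor {i} of shape {u.shape} does not conform with "
                    f"core rank {self.core.shape[i - 1]}"
                )
            if u.shape[0] < u.shape[1]:
                raise ShapeError(f"factor {i} is wider than tall: {u.shape}")
            r = u.shape[1]
            dev = np.max(np.abs(u.T @ u - np.eye(r)))
            if dev > self.ORTHO_TOL:
                raise ValueError(
                    f"factor {i} columns not orthonormal (deviation {dev:.2e})"
                )

    def reconstruct(self) -> np.ndarray:
        return tucker_reconstruct(self)


def tucker_reconstruct(model: TuckerModel) -> np.ndarray:
    """Reconstruct ``core ×_1 U_1 ... ×_N U_N`` from a Tucker model.

    Its mode-n unfolding equals
    ``U_n C_(n) (U_N ⊗ ... ⊗ U_{n+1} ⊗ U_{n-1} ⊗ ... ⊗ U_1)ᵀ``.
    """
    return multi_mode_product(model.core, model.factors)


def inner_product(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean inner product: sum of elementwise products."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.vdot(x, y))


def frobenius_norm(x: np.ndarray) -> float:
    """Frobenius norm: square root of the sum of squared entries."""
    return float(np.linalg.norm(np.asarray(x).ravel()))


def kronecker(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Kronecker product with block structure ``[a_ij * b]``."""
    return np.kron(np.asarray(a), np.asarray(b))
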