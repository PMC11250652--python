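"""Proximal and orthogonalization primitives: SVT and thin-QR.

Singular value thresholding (SVT) is the proximal operator of the nuclear
norm; here it acts on unfoldings of the (small) core tensor, so a plain
economy-size SVD is used throughout — the inputs are R x R^{N-1} matrices
and a randomized or truncated SVD would buy nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ShrinkageResult", "svt", "orthonormalize_qr", "RankDeficiencyWarning"]


class RankDeficiencyWarning(RuntimeWarning):
    """A matrix handed to :func:`orthonormalize_qr` was rank deficient."""


@dataclass(frozen=True)
class ShrinkageResult:
    """Output of :func:`svt`.

    Attributes
    ----------
    matrix : ndarray
        The soft-thresholded matrix, same shape as the input.
    rank_after : int
        Number of singular values surviving the shrinkage.
    """

    matrix: np.ndarray
    rank_after: int


def svt(z: np.ndarray, tau: float) -> ShrinkageResult:
    """Singular value thresholding ``U diag(max{sigma - tau, 0}) Vᵀ``.

    Minimizes ``tau*||W||_* + 0.5*||W - z||_F^2`` over W (the nuclear-norm
    prox at z with step tau).

    Parameters
    ----------
    z : ndarray, 2-D and finite
    tau : float, >= 0
        Shrinkage threshold applied to every singular value.
    """
    if tau < 0:
        raise ValueError(f"threshold tau must be nonnegative, got {tau}")
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 2:
        raise ValueError(f"svt expects a matrix, got ndim={z.ndim}")
    if not np.all(np.isfinite(z)):
        raise ValueError("svt input must be finite")
    if tau == 0.0:
        return ShrinkageResult(matrix=z.copy(), rank_after=int(np.linalg.matrix_rank(z)))
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    s_shrunk = np.maximum(s - tau, 0.0)
    kept = int(np.count_nonzero(s_shrunk))
    out = (u[:, :kept] * s_shrunk[:kept]) @ vt[:kept]
    if kept == 0:
        out = np.zeros_like(z)
    return ShrinkageResult(matrix=out, rank_after=kept)


def _complete_deficient(q: np.ndarray, good: np.ndarray) -> np.ndarray:
    # Replace columns flagged bad with a deterministic orthonormal basis of
    # the complement, built from canonical axes in index order.
    rows, cols = q.shape
    basis = [q[:, j] for j in range(cols) if good[j]]
    fill = []
    for j in range(rows):
        if len(basis) + len(fill) == cols:
            break
        v = np.zeros(rows)
        v[j] = 1.0
        for b in basis + fill:
            v -= (b @ v) * b
        nrm = np.linalg.norm(v)
        if nrm > 1e-8:
            fill.append(v / nrm)
    out = q.copy()
    it = iter(fill)
    for j in range(cols):
        if not good[j]:
            out[:, j] = next(it)
    return out


def orthonormalize_qr(m: np.ndarray, *, rank_tol: float = 1e-12) -> np.ndarray:
    """Orthonormalize the columns of ``m`` via thin QR.

    Returns the Q factor of ``m = Q R`` under the sign convention that R has
    a nonnegative diagonal, which makes Q unique (hence deterministic across
    runs and platforms) for full-column-rank input.  ``Q`` spans the same
    column space as ``m`` and satisfies ``QᵀQ = I``.

    Rank-deficient input does not raise: the directions lost to deficiency
    are completed from a deterministic orthonormal basis of the complement
    (canonical axes, in order) and a :class:`RankDeficiencyWarning` is
    emitted.  Early alternating-minimization iterates can be degenerate and
    must not abort the solve.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < m.shape[1]:
        raise ValueError(f"expected a tall matrix (rows >= cols), got shape {m.shape}")
    q, r = np.linalg.qr(m, mode="reduced")
    d = np.diagonal(r).copy()
    sign = np.where(d < 0, -1.0, 1.0)
    q = q * sign
    scale = max(np.max(np.abs(d)), 1.0)
    good = np.abs(d) > rank_tol * scale
    if not np.all(good):
        warnings.warn(
            f"rank-deficient input ({int(np.sum(~good))} of {m.shape[1]} columns); "
            "completing from canonical complement",
            RankDeficiencyWarning,
            stacklevel=2,
        )
        q = _complete_deficient(q, good)
    return q
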