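"""Weighted Whittaker smoother with per-point smoothing vector.

Every baseline corrector in this package reduces to repeated solves of
the penalized least-squares normal equations

    (W + D' Lambda D) z = W y

where ``W = diag(w)`` holds per-point fidelity weights, ``D`` is the
order-``d`` forward-difference operator and ``Lambda`` carries one
penalty weight per difference row.  The smoothing parameter may be a
single scalar (classic Whittaker / AsLS-family smoothing) or a length-n
vector that is reduced to the ``n - d`` penalty rows by averaging over
each row's stencil; the average reduces exactly to the scalar case when
all entries are equal.

The system matrix is symmetric positive definite and banded with
bandwidth ``d``, so it is solved with a banded Cholesky factorization;
no dense matrix is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

#: Default clamp bounds for smoothing parameters.  Values far outside
#: the practically useful 1e1..1e8 range produce ill-conditioned
#: systems; the clamp keeps the banded Cholesky factorization stable.
LAM_MIN = 1.0
LAM_MAX = 1e12


def difference_matrix(n: int, order: int = 2) -> sp.csr_matrix:
    """Sparse forward-difference operator of shape ``(n - order, n)``.

    Parameters
    ----------
    n
        Number of data points.
    order
        Difference order ``d`` (1 or 2).  Each row carries the
        binomial-coefficient stencil, e.g. ``[-1, 1]`` for ``d = 1``
        and ``[1, -2, 1]`` for ``d = 2``.

    Returns
    -------
    scipy.sparse.csr_matrix
        Operator ``D`` with ``(D z)_k = (Delta^d z)_k``.
    """
    if order < 1:
        raise ValueError(f"difference order must be >= 1, got {order}")
    if n <= order:
        raise ValueError(f"need n > order, got n={n}, order={order}")
    eye = sp.eye(n, format="csc")
    d = eye
    for _ in range(order):
        d = d[1:] - d[:-1]
    return d.tocsr()


@dataclass
class SmootherProblem:
    """One weighted Whittaker solve: data, weights, smoothing, order.

    ``lam`` may be a positive scalar or a positive vector of length
    ``len(y)``; a vector is mapped onto the penalty rows by averaging
    over each difference stencil.
    """

    y: np.ndarray
    w: np.ndarray
    lam: float | np.ndarray
    order: int = 2

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        n = self.y.size
        if self.y.ndim != 1 or n < self.order + 1:
            raise ValueError(
                f"y must be 1-D with at least order+1={self.order + 1} points, got shape {self.y.shape}"
            )
        if self.w.shape != self.y.shape:
            raise ValueError("w and y must have identical shape")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("weights must lie in [0, 1]")
        lam = np.asarray(self.lam, dtype=float)
        if lam.ndim == 0:
            lam = np.full(n, float(lam))
        elif lam.shape != (n,):
            raise ValueError("vector lam must have the same length as y")
        if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
            raise ValueError("all smoothing parameters must be positive and finite")
        self.lam_vector: np.ndarray = lam

    def penalty_row_weights(self) -> np.ndarray:
        """Per-row penalty weights: stencil mean of the lambda vector."""
        d = self.order
        kernel = np.full(d + 1, 1.0 / (d + 1))
        return np.convolve(self.lam_vector, kernel, mode="valid")


def whittaker_solve(problem: SmootherProblem) -> np.ndarray:
    """Solve ``(W + D' Lambda D) z = W y`` for the fitted vector z.

    Uses a symmetric banded Cholesky solve (``scipy.linalg.solveh_banded``).
    Raises :class:`numpy.linalg.LinAlgError` when the system is singular,
    e.g. all-zero weights combined with a vanishing penalty.
    """
    n = problem.y.size
    d = problem.order
    dmat = difference_matrix(n, d)
    lam_rows = problem.penalty_row_weights()
    a = sp.diags(problem.w) + dmat.T @ sp.diags(lam_rows) @ dmat
    a = a.tocsr()
    # upper banded storage: ab[u + i - j, j] = a[i, j]
    ab = np.zeros((d + 1, n))
    for k in range(d + 1):
        ab[d - k, k:] = a.diagonal(k)
    rhs = problem.w * problem.y
    try:
        return scipy.linalg.solveh_banded(ab, rhs, lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "singular Whittaker system: weights and penalty cannot both vanish"
        ) from exc
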