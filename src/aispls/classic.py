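"""Classic penalized-least-squares baseline correctors.

Reference implementations of the four iteratively reweighted Whittaker
baseline estimators used as comparators in the benchmark:

* **AsLS** — fixed asymmetry: weight ``p`` above the fit, ``1 - p``
  below it.
* **airPLS** — weight 0 above the fit and ``exp(t (y - z) / |d_t|)``
  below it, with ``|d_t|`` the L1 norm of the negative residuals;
  terminates when that norm drops below ``0.001 |y|``.
* **arPLS** — a generalized logistic weight on the positive residuals
  driven by the mean and standard deviation of the negative residuals.
* **asPLS** — arPLS-style weights plus a per-point smoothing scale
  ``|d_i| / max|d|``.  The published description of this method leaves
  several details open; this implementation follows the common
  convention and is intended as a comparator, not a reference.

All methods share the same contract: weights stay in [0, 1] at every
iteration, the iteration count never exceeds ``max_iter``, and the raw
(non-post-processed) corrected vector is ``y - baseline``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .result import CorrectionResult, IterationTrace
from .smoother import LAM_MAX, LAM_MIN, SmootherProblem, whittaker_solve

__all__ = [
    "asls_baseline",
    "airpls_baseline",
    "arpls_baseline",
    "aspls_baseline",
]

#: Relative weight-change threshold used where the method's own
#: termination rule is not otherwise specified.
WEIGHT_TOL = 1e-3


def _validate(y: np.ndarray, lam: float, order: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < order + 1:
        raise ValueError("y must be a 1-D vector with at least order+1 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if lam <= 0:
        raise ValueError(f"smoothing parameter must be positive, got {lam}")
    return y


def _result(y: np.ndarray, z: np.ndarray, trace: IterationTrace, lam) -> CorrectionResult:
    return CorrectionResult(baseline=z, corrected=y - z, trace=trace, lam_final=lam)


def asls_baseline(
    y: np.ndarray,
    lam: float = 1e6,
    p: float = 0.01,
    max_iter: int = 50,
    order: int = 2,
) -> CorrectionResult:
    """Asymmetric least squares: weight ``p`` where y > z, else ``1 - p``.

    A small ``p`` pushes the fit underneath the peaks, making z an
    estimate of the baseline rather than of the signal.
    """
    y = _validate(y, lam, order)
    if not 0.0 < p < 1.0:
        raise ValueError(f"asymmetry p must lie in (0, 1), got {p}")
    w = np.ones_like(y)
    trace = IterationTrace()
    z = y
    for t in range(1, max_iter + 1):
        z = whittaker_solve(SmootherProblem(y, w, lam, order))
        w_new = np.where(y > z, p, 1.0 - p)
        trace.log(t, float(np.linalg.norm(y - z)), w_new, lam)
        delta = np.linalg.norm(w_new - w) / max(np.linalg.norm(w_new), 1e-300)
        w = w_new
        if delta < WEIGHT_TOL:
            trace.converged = True
            break
    return _result(y, z, trace, lam)


def airpls_baseline(
    y: np.ndarray,
    lam: float = 1e5,
    max_iter: int = 200,
    order: int = 2,
) -> CorrectionResult:
    """Adaptive iteratively reweighted PLS.

    Points above the current fit get weight 0; points at or below it
    get ``exp(t (y - z) / |d_t|)`` where ``d_t`` collects the negative
    residuals and ``|d_t|`` is their L1 norm.  Terminates when
    ``|d_t| <= 0.001 |y|`` (L1 norms) or the iteration cap is reached.
    An empty negative-residual set is treated as converged.
    """
    y = _validate(y, lam, order)
    w = np.ones_like(y)
    trace = IterationTrace()
    abs_y = float(np.sum(np.abs(y)))
    z = y
    for t in range(1, max_iter + 1):
        z = whittaker_solve(SmootherProblem(y, w, lam, order))
        d = y - z
        neg = d < 0
        dssn = float(np.sum(np.abs(d[neg])))
        trace.log(t, dssn, w, lam)
        if dssn <= 0.001 * abs_y:
            trace.converged = True
            break
        if t >= max_iter:
            break
        w = np.zeros_like(y)
        below = d <= 0
        w[below] = np.exp(t * d[below] / dssn)
    return _result(y, z, trace, lam)


def _arpls_weights(d: np.ndarray) -> np.ndarray:
    """arPLS weight rule: logistic on positive residuals, 1 below the fit.

    The logistic is ``1 / (1 + exp(2 (d - (-m + 2 s)) / s))`` with m, s
    the mean and standard deviation of the negative residuals.  A zero
    (or undefined) s degenerates to a hard threshold at ``-m + 2 s``.
    """
    w = np.ones_like(d)
    above = d > 0
    d_minus = d[d <= 0]
    if d_minus.size == 0:
        w[above] = 0.0
        return w
    m = float(np.mean(d_minus))
    s = float(np.std(d_minus))
    thr = -m + 2.0 * s
    if s == 0.0:
        w[above] = (d[above] < thr).astype(float)
    else:
        w[above] = expit(-2.0 * (d[above] - thr) / s)
    return w


def arpls_baseline(
    y: np.ndarray,
    lam: float = 1e6,
    max_iter: int = 100,
    order: int = 2,
    tol: float = WEIGHT_TOL,
) -> CorrectionResult:
    """Asymmetrically reweighted PLS with logistic weights."""
    y = _validate(y, lam, order)
    w = np.ones_like(y)
    trace = IterationTrace()
    z = y
    for t in range(1, max_iter + 1):
        z = whittaker_solve(SmootherProblem(y, w, lam, order))
        d = y - z
        w_new = _arpls_weights(d)
        trace.log(t, float(np.linalg.norm(d[d < 0])), w_new, lam)
        delta = np.linalg.norm(w_new - w) / max(np.linalg.norm(w_new), 1e-300)
        w = w_new
        if delta < tol:
            trace.converged = True
            break
    return _result(y, z, trace, lam)


def aspls_baseline(
    y: np.ndarray,
    lam: float = 1e8,
    max_iter: int = 100,
    order: int = 2,
    tol: float = WEIGHT_TOL,
) -> CorrectionResult:
    """Adaptive smoothing-parameter PLS (comparator-quality).

    arPLS-style logistic weights combined with a per-point smoothing
    scale ``alpha_i = |d_i| / max|d|`` applied multiplicatively to the
    scalar ``lam``; the effective per-point smoothing is clamped to the
    numerically safe range.  A flat residual vector leaves the
    smoothing uniform.
    """
    y = _validate(y, lam, order)
    w = np.ones_like(y)
    alpha = np.ones_like(y)
    trace = IterationTrace()
    z = y
    for t in range(1, max_iter + 1):
        lam_vec = np.clip(lam * alpha, LAM_MIN, LAM_MAX)
        z = whittaker_solve(SmootherProblem(y, w, lam_vec, order))
        d = y - z
        w_new = _arpls_weights(d)
        trace.log(t, float(np.linalg.norm(d[d < 0])), w_new, lam_vec)
        abs_d = np.abs(d)
        max_d = float(np.max(abs_d))
        # residuals at solver precision mean a flat fit: leave alpha alone
        if max_d > 1e-10 * max(1.0, float(np.max(np.abs(y)))):
            alpha = abs_d / max_d
        delta = np.linalg.norm(w_new - w) / max(np.linalg.norm(w_new), 1e-300)
        w = w_new
        if delta < tol:
            trace.converged = True
            break
    return _result(y, z, trace, np.clip(lam * alpha, LAM_MIN, LAM_MAX))
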