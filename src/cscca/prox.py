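"""Proximal operators for sparse canonical directions.

Two operators drive every solver update in this package:

* plain (weighted) soft-thresholding, the proximal map of the l1 penalty;
* the proximal map of a weighted l1 penalty restricted to the zero-sum
  hyperplane ``B_p = {b : sum_j b_j = 0}``, i.e.

      g(h, lam, w) = argmin_{b in B_p} 0.5 ||h - b||_2^2 + lam * sum_j w_j |b_j|.

The zero-sum constraint is what makes canonical scores of log-abundance
data invariant to per-sample scaling (compositionality).  The constrained
prox is solved by an augmented Lagrangian method (ALM): the equality
constraint enters through a quadratic penalty plus a scalar dual variable
updated by gradient ascent, and each ALM subproblem is minimized by cyclic
coordinate descent with a closed-form soft-threshold update per coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def deco(func):
            return func

        if args and callable(args[0]):
            return args[0]
        return deco


__all__ = [
    "ProxOptions",
    "ProxConvergenceError",
    "soft_threshold",
    "soft_threshold_vector",
    "prox_zero_sum_weighted_l1",
]


@dataclass
class ProxOptions:
    """Controls for the ALM / coordinate-descent inner solver.

    ``mu1`` is the quadratic-penalty step and ``mu2`` the dual-ascent step;
    both default to 1, the values used throughout the numerical studies.
    ``inner_tol`` bounds both the constraint violation ``|1'b|`` and the
    max-norm change of the iterate at convergence.
    """

    mu1: float = 1.0
    mu2: float = 1.0
    inner_tol: float = 1e-8
    max_inner_iter: int = 1000
    max_alm_iter: int = 1000

    def __post_init__(self) -> None:
        if self.mu1 <= 0 or self.mu2 <= 0:
            raise ValueError("mu1 and mu2 must be positive")
        if self.inner_tol <= 0:
            raise ValueError("inner_tol must be positive")
        if self.max_inner_iter < 1 or self.max_alm_iter < 1:
            raise ValueError("iteration caps must be >= 1")


class ProxConvergenceError(RuntimeError):
    """Raised when the ALM loop exhausts its iteration budget.

    Carries the last iterate and the residual so callers can inspect the
    failure.
    """

    def __init__(self, message: str, iterate: np.ndarray, residual: float):
        super().__init__(message)
        self.iterate = iterate
        self.residual = residual


def soft_threshold(x: float, lam: float) -> float:
    """Scalar soft-thresholding ``sign(x) * max(|x| - lam, 0)``."""
    if lam < 0:
        raise ValueError("threshold lam must be nonnegative")
    if x > lam:
        return x - lam
    if x < -lam:
        return x + lam
    return 0.0


def soft_threshold_vector(v: np.ndarray, lam) -> np.ndarray:
    """Componentwise soft-thresholding.

    ``lam`` may be a scalar or a per-coordinate array of nonnegative
    thresholds (used for adaptive, weighted penalties).
    """
    v = np.asarray(v, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("threshold lam must be nonnegative")
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


@njit(cache=True)
def _alm_kernel(h, lam, w, b, mu1, mu2, tol, max_inner, max_alm):
    """ALM outer loop with cyclic coordinate-descent inner loop.

    Each coordinate update is O(1) by maintaining the running sum of b.
    Returns (b, n_alm_iter, converged_flag, residual).
    """
    p = h.shape[0]
    d = 0.0
    b_prev = b.copy()
    residual = 0.0
    for it in range(max_alm):
        for _ in range(max_inner):
            max_delta = 0.0
            s = b.sum()
            for j in range(p):
                r = s - b[j] + d
                z = h[j] - mu1 * r
                t = lam * w[j]
                if z > t:
                    nb = (z - t) / (1.0 + mu1)
                elif z < -t:
                    nb = (z + t) / (1.0 + mu1)
                else:
                    nb = 0.0
                delta = nb - b[j]
                if delta > max_delta:
                    max_delta = delta
                elif -delta > max_delta:
                    max_delta = -delta
                s += delta
                b[j] = nb
            if max_delta < tol:
                break
        viol = b.sum()
        change = 0.0
        for j in range(p):
            c = b[j] - b_prev[j]
            if c > change:
                change = c
            elif -c > change:
                change = -c
        residual = abs(viol) if abs(viol) > change else change
        if residual < tol:
            return b, it + 1, True, residual
        d += mu2 * viol
        b_prev[:] = b
    return b, max_alm, False, residual


def prox_zero_sum_weighted_l1(
    h: np.ndarray,
    lam: float,
    w: np.ndarray,
    opts: ProxOptions | None = None,
    b_init: np.ndarray | None = None,
) -> np.ndarray:
    """Zero-sum constrained weighted-l1 proximal operator ``g(h, lam, w)``.

    Parameters
    ----------
    h
        Point being proximated, length p >= 2.
    lam
        Nonnegative global penalty level.
    w
        Nonnegative per-coordinate penalty weights, length p.
    opts
        ALM controls; defaults to :class:`ProxOptions`.
    b_init
        Optional warm start (e.g. the previous outer iterate of an
        alternating solver).  The problem is strictly convex, so warm
        starts affect speed only.

    Returns
    -------
    numpy.ndarray
        The minimizer, with ``|sum(b)| <= inner_tol * p``.
    """
    opts = opts or ProxOptions()
    h = np.asarray(h, dtype=float)
    w = np.asarray(w, dtype=float)
    if h.ndim != 1 or h.shape[0] < 2:
        raise ValueError("h must be a vector of length >= 2")
    if w.shape != h.shape:
        raise ValueError("w must match h in length")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")

    if lam == 0.0 or np.all(w == 0.0):
        # Penalty vanishes: exact Euclidean projection onto the hyperplane.
        return h - h.mean()

    if b_init is not None:
        b0 = np.asarray(b_init, dtype=float).copy()
        if b0.shape != h.shape:
            raise ValueError("b_init must match h in length")
    else:
        b0 = h - h.mean()

    b, n_iter, converged, residual = _alm_kernel(
        h,
        float(lam),
        w,
        b0,
        float(opts.mu1),
        float(opts.mu2),
        float(opts.inner_tol),
        int(opts.max_inner_iter),
        int(opts.max_alm_iter),
    )
    if not converged:
        raise ProxConvergenceError(
            f"ALM did not converge within {opts.max_alm_iter} iterations "
            f"(residual {residual:.3e})",
            iterate=b,
            residual=residual,
        )
    return b
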