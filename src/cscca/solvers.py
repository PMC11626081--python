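"""Alternating solvers for sparse canonical correlation analysis.

Four estimators share one alternating scheme driven by the sample
cross-covariance ``S`` (q x p) between the two views:

* ``fit_scca_baseline`` -- plain sparse CCA with diagonal covariance
  substitution: both directions updated by soft-thresholding + l2
  normalization, no compositional constraint;
* ``fit_cscca`` -- compositional sparse CCA: the direction on the
  log-compositional side is constrained to the zero-sum hyperplane via
  the ALM prox, making scores invariant to per-sample scaling;
* ``fit_cscca_two_sided`` -- both views compositional, both directions
  zero-sum;
* ``fit_sacca`` -- (structure-)adaptive variants: penalty weights are
  re-estimated each outer iteration from the current coefficients,
  ``w_j = |b_j|^{-gamma}`` elementwise or shared within taxonomic groups,
  capped at ``C_U`` (features currently at zero get the cap).

Each non-degenerate direction has unit l2 norm; sign indeterminacy of the
pair is resolved by making the largest-magnitude entry of ``a`` positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import CrossCovariance, OmicsMatrix, cross_covariance
from .prox import ProxOptions, prox_zero_sum_weighted_l1, soft_threshold_vector

__all__ = [
    "CanonicalPair",
    "WeightConstraint",
    "SolverOptions",
    "initialize_a",
    "update_b",
    "update_a",
    "update_weights",
    "penalty_h",
    "fit_scca_baseline",
    "fit_cscca",
    "fit_cscca_two_sided",
    "fit_sacca",
    "fit_sacca_two_sided",
    "fit_from_cross_cov",
    "resolve_method",
    "METHOD_NAMES",
]

METHOD_NAMES = ("scca", "cscca", "accca", "sacca")


@dataclass
class CanonicalPair:
    """A fitted canonical pair (a, b) with diagnostics."""

    a: np.ndarray
    b: np.ndarray
    support_a: np.ndarray
    support_b: np.ndarray
    sample_correlation: float
    n_iterations: int
    converged: bool
    degenerate: bool


@dataclass
class WeightConstraint:
    """Feasible set for adaptive penalty weights.

    kind:
        ``"none"`` (fixed weights), ``"elementwise_box"`` (each weight free
        in [0, C_U]) or ``"group"`` (weights shared within each group of
        ``groups``, e.g. taxa grouped by phylum).
    groups:
        Length-p sequence of group labels, required iff kind == "group".
    C_U:
        Upper cap on weights; features with zero coefficient receive it.
    gamma:
        Adaptive exponent in (0, 1]; weights are |coef|^-gamma.
    """

    kind: str = "none"
    groups: Sequence | None = None
    C_U: float = 1e5
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "elementwise_box", "group"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "group" and self.groups is None:
            raise ValueError("group constraint requires a groups sequence")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")
        if self.C_U <= 0:
            raise ValueError("C_U must be positive")


@dataclass
class SolverOptions:
    lam_a: float = 0.0
    lam_b: float = 0.0
    outer_tol: float = 1e-6
    max_outer_iter: int = 200
    prox: ProxOptions = field(default_factory=ProxOptions)

    def __post_init__(self) -> None:
        if self.lam_a < 0 or self.lam_b < 0:
            raise ValueError("penalty levels must be nonnegative")
        if self.outer_tol <= 0:
            raise ValueError("outer_tol must be positive")
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")


def _as_matrix(S: CrossCovariance | np.ndarray) -> np.ndarray:
    if isinstance(S, CrossCovariance):
        return S.matrix
    return np.asarray(S, dtype=float)


def initialize_a(S: CrossCovariance | np.ndarray) -> np.ndarray:
    """First left singular vector of S, unit norm, sign-fixed.

    The sign is chosen so the largest-magnitude entry (lowest index on
    ties) is positive, for reproducibility.
    """
    mat = _as_matrix(S)
    if not np.any(mat):
        raise ValueError("cross-covariance matrix is identically zero")
    u, _, _ = np.linalg.svd(mat, full_matrices=False)
    a = u[:, 0]
    j = int(np.argmax(np.abs(a)))
    if a[j] < 0:
        a = -a
    return a


def update_b(
    S: CrossCovariance | np.ndarray,
    a: np.ndarray,
    lam_b: float,
    w: np.ndarray,
    opts: ProxOptions | None = None,
    b_init: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Zero-sum-constrained b update: prox of S'a, then l2 normalization.

    Returns (b, degenerate): when the prox output is the zero vector the
    direction is degenerate and the zero vector is returned unnormalized.
    """
    mat = _as_matrix(S)
    h = mat.T @ a
    raw = prox_zero_sum_weighted_l1(h, lam_b, w, opts, b_init=b_init)
    nrm = np.linalg.norm(raw)
    if nrm == 0.0:
        return np.zeros_like(raw), True
    return raw / nrm, False


def update_a(
    S: CrossCovariance | np.ndarray,
    b: np.ndarray,
    lam_a: float,
    w: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Unconstrained-side a update: soft-threshold S b, then normalize.

    With lam_a at or above the max-norm of ``v = S b`` (weight-adjusted),
    the whole vector thresholds to zero and the update is degenerate.
    """
    mat = _as_matrix(S)
    v = mat @ b
    thresh = lam_a if w is None else lam_a * np.asarray(w, dtype=float)
    raw = soft_threshold_vector(v, thresh)
    nrm = np.linalg.norm(raw)
    if nrm == 0.0:
        return np.zeros_like(raw), True
    return raw / nrm, False


def penalty_h(w: float, gamma: float) -> float:
    """Weight-penalty function h(w; gamma).

    h(w; gamma) = exp(w^(1 - 1/gamma) / (1 - 1/gamma)) for 0 < gamma < 1
    and h(w; 1) = w.  Minimizing ``w |b| - log h(w, gamma)`` over w yields
    the adaptive weight |b|^-gamma, so h encodes the adaptive-lasso rule.
    """
    if not (0 < gamma <= 1):
        raise ValueError("gamma must lie in (0, 1]")
    if w <= 0:
        raise ValueError("w must be positive")
    if gamma == 1:
        return float(w)
    expo = 1.0 - 1.0 / gamma
    return float(np.exp(w**expo / expo))


def update_weights(b: np.ndarray, constraint: WeightConstraint) -> np.ndarray:
    """Closed-form weight update given current coefficients.

    Elementwise: w_j = min(C_U, |b_j|^-gamma), w_j = C_U at b_j = 0.
    Group: one shared weight per group, min(C_U, (mean |b_j|)^-gamma),
    C_U when the whole group is zero.
    """
    b = np.asarray(b, dtype=float)
    if constraint.kind == "none":
        raise ValueError("update_weights requires an adaptive constraint")
    absb = np.abs(b)
    gamma, cap = constraint.gamma, constraint.C_U
    if constraint.kind == "elementwise_box":
        w = np.full_like(absb, cap)
        nz = absb > 0
        w[nz] = np.minimum(cap, absb[nz] ** -gamma)
        return w
    groups = np.asarray(constraint.groups)
    if groups.shape[0] != b.shape[0]:
        raise ValueError("groups length does not match coefficient vector")
    w = np.empty_like(absb)
    for g in np.unique(groups):
        idx = groups == g
        m = absb[idx].mean()
        w[idx] = cap if m == 0 else min(cap, m**-gamma)
    return w


def _norm_or_degenerate(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    nrm = np.linalg.norm(raw)
    if nrm == 0.0:
        return np.zeros_like(raw), True
    return raw / nrm, False


def _fix_sign(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = a if np.any(a) else b
    if not np.any(ref):
        return a, b
    j = int(np.argmax(np.abs(ref)))
    if ref[j] < 0:
        return -a, -b
    return a, b


def fit_from_cross_cov(
    S: CrossCovariance | np.ndarray,
    lam_a: float = 0.0,
    lam_b: float = 0.0,
    *,
    zero_sum_a: bool = False,
    zero_sum_b: bool = True,
    w_a: np.ndarray | None = None,
    w_b: np.ndarray | None = None,
    adapt_a: WeightConstraint | None = None,
    adapt_b: WeightConstraint | None = None,
    opts: SolverOptions | None = None,
) -> tuple[np.ndarray, np.ndarray, int, bool, bool, np.ndarray, np.ndarray]:
    """Core alternating loop on a precomputed cross-covariance.

    Alternates the b and a updates (with optional per-iteration adaptive
    weight refresh, initialized at all-ones) until the max-norm change of
    both directions drops below ``outer_tol`` or a side degenerates.

    Returns ``(a, b, n_iter, converged, degenerate, w_a, w_b)``.
    """
    opts = opts or SolverOptions(lam_a=lam_a, lam_b=lam_b)
    mat = _as_matrix(S)
    q, p = mat.shape
    wa = np.ones(q) if w_a is None else np.asarray(w_a, dtype=float)
    wb = np.ones(p) if w_b is None else np.asarray(w_b, dtype=float)

    a = initialize_a(mat)
    b = np.zeros(p)
    b_raw_prev: np.ndarray | None = None
    converged = False
    degenerate = False
    n_iter = 0
    for n_iter in range(1, opts.max_outer_iter + 1):
        a_prev, b_prev = a, b
        # --- b step
        h = mat.T @ a
        if zero_sum_b:
            raw = prox_zero_sum_weighted_l1(h, lam_b, wb, opts.prox, b_init=b_raw_prev)
            b_raw_prev = raw
        else:
            raw = soft_threshold_vector(h, lam_b * wb)
        b, deg = _norm_or_degenerate(raw)
        if deg:
            degenerate = True
            break
        if adapt_b is not None:
            wb = update_weights(b, adapt_b)
        # --- a step
        v = mat @ b
        if zero_sum_a:
            raw_a = prox_zero_sum_weighted_l1(v, lam_a, wa, opts.prox)
        else:
            raw_a = soft_threshold_vector(v, lam_a * wa)
        a, deg = _norm_or_degenerate(raw_a)
        if deg:
            degenerate = True
            break
        if adapt_a is not None:
            wa = update_weights(a, adapt_a)
        change = max(
            np.max(np.abs(a - a_prev)),
            np.max(np.abs(b - b_prev)),
        )
        if change < opts.outer_tol:
            converged = True
            break
    if degenerate:
        converged = True
    a, b = _fix_sign(a, b)
    return a, b, n_iter, converged, degenerate, wa, wb


def _values(M) -> np.ndarray:
    return M.values if isinstance(M, OmicsMatrix) else np.asarray(M, dtype=float)


def _score_correlation(Y, Z, a: np.ndarray, b: np.ndarray) -> float:
    if not np.any(a) or not np.any(b):
        return 0.0
    u = _values(Y) @ a
    v = _values(Z) @ b
    if u.std() == 0 or v.std() == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def _make_pair(Y, Z, a, b, n_iter, converged, degenerate) -> CanonicalPair:
    return CanonicalPair(
        a=a,
        b=b,
        support_a=np.flatnonzero(a),
        support_b=np.flatnonzero(b),
        sample_correlation=_score_correlation(Y, Z, a, b),
        n_iterations=n_iter,
        converged=converged,
        degenerate=degenerate,
    )


def fit_scca_baseline(Y, Z, opts: SolverOptions | None = None) -> CanonicalPair:
    """Plain sparse CCA: soft-threshold updates on both sides, no zero-sum.

    This is the diagonal-covariance penalized-matrix-decomposition scheme;
    it ignores compositionality entirely and serves as the comparison
    baseline.
    """
    opts = opts or SolverOptions()
    S = cross_covariance(Y, Z)
    a, b, it, conv, deg, _, _ = fit_from_cross_cov(
        S, opts.lam_a, opts.lam_b, zero_sum_a=False, zero_sum_b=False, opts=opts
    )
    return _make_pair(Y, Z, a, b, it, conv, deg)


def fit_cscca(
    Y, Z, opts: SolverOptions | None = None, w: np.ndarray | None = None
) -> CanonicalPair:
    """Compositional sparse CCA: Y non-compositional vs Z log-compositional.

    ``w`` is an optional fixed weight vector on the compositional side
    (defaults to uniform weights).
    """
    opts = opts or SolverOptions()
    S = cross_covariance(Y, Z)
    a, b, it, conv, deg, _, _ = fit_from_cross_cov(
        S, opts.lam_a, opts.lam_b, zero_sum_a=False, zero_sum_b=True, w_b=w, opts=opts
    )
    return _make_pair(Y, Z, a, b, it, conv, deg)


def fit_cscca_two_sided(
    U,
    Z,
    opts: SolverOptions | None = None,
    w1: np.ndarray | None = None,
    w2: np.ndarray | None = None,
) -> CanonicalPair:
    """Two-sided compositional sparse CCA: both U and Z log-compositional.

    Both directions are constrained to their zero-sum hyperplanes; ``w1``
    weights the a side (U features), ``w2`` the b side (Z features).
    """
    opts = opts or SolverOptions()
    S = cross_covariance(U, Z)
    a, b, it, conv, deg, _, _ = fit_from_cross_cov(
        S,
        opts.lam_a,
        opts.lam_b,
        zero_sum_a=True,
        zero_sum_b=True,
        w_a=w1,
        w_b=w2,
        opts=opts,
    )
    return _make_pair(U, Z, a, b, it, conv, deg)


def fit_sacca(
    Y,
    Z,
    opts: SolverOptions | None = None,
    constraint: WeightConstraint | None = None,
    adapt_a: bool = True,
) -> tuple[CanonicalPair, dict]:
    """(Structure-)adaptive compositional sparse CCA, one-sided.

    The compositional side's weights follow ``constraint`` (elementwise or
    group); the non-compositional side, when ``adapt_a`` is true, uses
    elementwise adaptive weights with the same gamma and cap.  Weights
    start uniform, so the first iteration coincides with plain C-sCCA.

    Returns the fitted pair and the final weights ``{"a": ..., "b": ...}``.
    """
    opts = opts or SolverOptions()
    if constraint is None or constraint.kind == "none":
        raise ValueError("fit_sacca requires an adaptive WeightConstraint")
    S = cross_covariance(Y, Z)
    ca = (
        WeightConstraint(kind="elementwise_box", C_U=constraint.C_U, gamma=constraint.gamma)
        if adapt_a
        else None
    )
    a, b, it, conv, deg, wa, wb = fit_from_cross_cov(
        S,
        opts.lam_a,
        opts.lam_b,
        zero_sum_a=False,
        zero_sum_b=True,
        adapt_a=ca,
        adapt_b=constraint,
        opts=opts,
    )
    return _make_pair(Y, Z, a, b, it, conv, deg), {"a": wa, "b": wb}


def fit_sacca_two_sided(
    U,
    Z,
    opts: SolverOptions | None = None,
    constraint_a: WeightConstraint | None = None,
    constraint_b: WeightConstraint | None = None,
) -> tuple[CanonicalPair, dict]:
    """Adaptive two-sided compositional sparse CCA (both sides zero-sum)."""
    opts = opts or SolverOptions()
    if constraint_b is None or constraint_b.kind == "none":
        raise ValueError("an adaptive constraint is required on the b side")
    S = cross_covariance(U, Z)
    a, b, it, conv, deg, wa, wb = fit_from_cross_cov(
        S,
        opts.lam_a,
        opts.lam_b,
        zero_sum_a=True,
        zero_sum_b=True,
        adapt_a=constraint_a,
        adapt_b=constraint_b,
        opts=opts,
    )
    return _make_pair(U, Z, a, b, it, conv, deg), {"a": wa, "b": wb}


def resolve_method(
    method: str,
    *,
    two_sided: bool = False,
    gamma: float = 1.0,
    groups_a: Sequence | None = None,
    groups_b: Sequence | None = None,
    C_U: float = 1e5,
) -> dict:
    """Translate a method name into alternating-loop settings.

    Recognized names: ``scca`` (no constraints), ``cscca`` (zero-sum on
    compositional sides, uniform weights), ``accca`` (elementwise adaptive
    weights), ``sacca`` (group weights on compositional sides, elementwise
    on a non-compositional a side).  ``"two_sided"`` is accepted as an
    alias for two-sided cscca, and a ``_two_sided`` suffix on any name
    sets the flag.
    """
    name = method.lower().replace("-", "_")
    if name == "two_sided":
        name, two_sided = "cscca", True
    if name.endswith("_two_sided"):
        name, two_sided = name[: -len("_two_sided")], True
    if name not in METHOD_NAMES:
        raise ValueError(f"unknown method {method!r}; expected one of {METHOD_NAMES}")
    elementwise = WeightConstraint(kind="elementwise_box", C_U=C_U, gamma=gamma)
    adapt_a = adapt_b = None
    if name == "accca":
        adapt_a, adapt_b = elementwise, elementwise
    elif name == "sacca":
        if groups_b is None:
            raise ValueError("sacca requires group labels for the compositional side")
        adapt_b = WeightConstraint(kind="group", groups=groups_b, C_U=C_U, gamma=gamma)
        if two_sided:
            if groups_a is None:
                raise ValueError("two-sided sacca requires group labels for both sides")
            adapt_a = WeightConstraint(kind="group", groups=groups_a, C_U=C_U, gamma=gamma)
        else:
            adapt_a = elementwise
    return {
        "zero_sum_a": two_sided and name != "scca",
        "zero_sum_b": name != "scca",
        "adapt_a": adapt_a,
        "adapt_b": adapt_b,
    }
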