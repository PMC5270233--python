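"""Univariate penalized-quadratic solvers.

Every coordinate update of the meta-analytic SVM reduces to minimizing

    q(z) = b/2 (z - c)^2 + lambda1 sqrt(z^2 + d) + lambda2 |z|

where b > 0 is the local curvature, c the unpenalized minimizer and d >= 0
the sum of squared coefficients of the same feature in the other studies.
For d = 0 the group term collapses into the L1 term and the minimizer is the
soft-thresholding operator in closed form. For d > 0 the |z| term is smoothed
by the rescaled logistic CDF F_s and the stationary point is found by damped
Newton iteration on the smoothed derivative

    b (z - c) + lambda1 z / sqrt(z^2 + d) + lambda2 F_s(z).

The hot paths are numba-compiled; the public functions validate and delegate.
"""

from __future__ import annotations

import math

import numba
import numpy as np

from .datamodel import ConvergenceError, UnivariateProblem

__all__ = [
    "soft_threshold",
    "univariate_lasso_min",
    "logistic_cdf_form",
    "logistic_weight",
    "logistic_curvature",
    "smoothed_abs",
    "univariate_sgl_min",
]


@numba.njit(cache=True)
def _soft_threshold(y: float, lam: float) -> float:
    if y > lam:
        return y - lam
    if y < -lam:
        return y + lam
    return 0.0


@numba.njit(cache=True)
def _fs(z: float, s: float) -> float:
    # 2*sigmoid(z/s) - 1 == tanh(z/(2s)); tanh is overflow-free.
    return math.tanh(z / (2.0 * s))


@numba.njit(cache=True)
def _smoothed_abs(z: float, s: float) -> float:
    # integral of F_s from 0 to z: 2s * log(cosh(z/(2s))), computed stably.
    x = abs(z) / (2.0 * s)
    return 2.0 * s * (x + math.log1p(math.exp(-2.0 * x)) - math.log(2.0))


@numba.njit(cache=True)
def _sgl_newton(
    b: float,
    c: float,
    d: float,
    l1: float,
    l2: float,
    s: float,
    tol: float,
    max_inner: int,
):
    """Bracketed Newton on the smoothed univariate derivative; returns (z, ok).

    The derivative b(z-c) + l1 z/sqrt(z^2+d) + l2 F_s(z) is strictly
    increasing, negative at 0 and positive at c (for c > 0; mirrored for
    c < 0), so the unique root lies between 0 and c. Newton steps that leave
    the bracket, or make no progress in the stiff |z| ~ s region, fall back
    to bisection of the bracket.
    """
    if l1 + l2 <= 0.0:
        return c, True
    if d <= 0.0:
        return _soft_threshold(c, (l1 + l2) / b), True
    if c == 0.0:
        return 0.0, True
    lo, hi = (0.0, c) if c > 0.0 else (c, 0.0)
    # start at the all-L1 closed form; always inside the bracket
    z = _soft_threshold(c, (l1 + l2) / b)
    tol_abs = tol * max(1.0, b * (1.0 + abs(c)) + l1 + l2)
    for _ in range(max_inner):
        root = math.sqrt(z * z + d)
        t = _fs(z, s)
        g = b * (z - c) + l1 * z / root + l2 * t
        if abs(g) <= tol_abs:
            return z, True
        if g > 0.0:
            hi = z
        else:
            lo = z
        h = b + l1 * d / (root * root * root) + l2 * (1.0 - t * t) / (2.0 * s)
        z_new = z - g / h
        if not (lo < z_new < hi):
            z_new = 0.5 * (lo + hi)
        if z_new == z:  # bracket exhausted at machine precision
            return z, True
        z = z_new
    root = math.sqrt(z * z + d)
    g = b * (z - c) + l1 * z / root + l2 * _fs(z, s)
    return z, abs(g) <= tol_abs


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------

def soft_threshold(y: float, lam: float) -> float:
    """Soft-thresholding ST(y, lam): shrink y toward zero by lam, clip at 0."""
    if lam <= 0:
        raise ValueError("soft_threshold requires lam > 0")
    return _soft_threshold(float(y), float(lam))


def univariate_lasso_min(b: float, c: float, lam: float) -> float:
    """Exact minimizer ST(c, lam/b) of b/2 (z-c)^2 + lam |z|."""
    if b <= 0:
        raise ValueError("curvature b must be > 0")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return _soft_threshold(float(c), float(lam) / float(b))


def logistic_cdf_form(z: float, s: float) -> float:
    """Rescaled logistic CDF F_s(z) = 2 exp(z/s)/(1+exp(z/s)) - 1, in (-1, 1).

    Odd in z and tending to sign(z) as s -> 0; evaluated as tanh(z/(2s)) so
    large |z|/s cannot overflow.
    """
    if s <= 0:
        raise ValueError("scale s must be > 0")
    return _fs(float(z), float(s))


def logistic_weight(z: float, s: float) -> float:
    """Logistic weight w_s(z) = F_s(z) (1 + F_s(z)) / (2s).

    Zero at the origin and asymmetric in z: it equals the true derivative of
    F_s only at z = 0 (and is negative for z < 0), so the Newton curvature
    uses :func:`logistic_curvature` instead.
    """
    if s <= 0:
        raise ValueError("scale s must be > 0")
    f = _fs(float(z), float(s))
    return f * (1.0 + f) / (2.0 * s)


def logistic_curvature(z: float, s: float) -> float:
    """Derivative of F_s: (1 - F_s(z)^2) / (2s); the smoothed-|z| curvature."""
    if s <= 0:
        raise ValueError("scale s must be > 0")
    f = _fs(float(z), float(s))
    return (1.0 - f * f) / (2.0 * s)


def smoothed_abs(z: float, s: float) -> float:
    """Smoothed absolute value: the antiderivative of F_s vanishing at 0.

    Converges to |z| - 2s log 2 pointwise as z grows; differences of this
    function approximate differences of |z| within O(s).
    """
    if s <= 0:
        raise ValueError("scale s must be > 0")
    return _smoothed_abs(float(z), float(s))


def univariate_sgl_min(
    prob: UnivariateProblem,
    tol: float = 1e-8,
    max_inner: int = 100,
) -> float:
    """Minimize one coordinate's sparse-group-lasso problem.

    Closed form for d = 0 (pure L1) and for lambda1 = lambda2 = 0 (returns c);
    otherwise damped Newton on the logistic-smoothed objective.

    Raises
    ------
    ConvergenceError
        If the Newton iteration has not met the derivative tolerance after
        ``max_inner`` steps (typically an ill-conditioned b, s pairing).
    """
    z, ok = _sgl_newton(
        float(prob.b),
        float(prob.c),
        float(prob.d),
        float(prob.lambda1),
        float(prob.lambda2),
        float(prob.s),
        float(tol),
        int(max_inner),
    )
    if not ok:
        raise ConvergenceError(
            f"univariate solver did not converge in {max_inner} iterations "
            f"(b={prob.b:.3g}, s={prob.s:.3g})"
        )
    return z
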