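"""Meta-analytic SVM fitting.

The estimator minimizes, over M per-study coefficient vectors beta^(m),

    Q(beta) = sum_m (1/n^m) sum_i [1 - y_i^m f(x_i^m; beta^m)]_+
              + lambda1 sum_j sqrt(sum_m beta_jm^2)
              + lambda2 sum_m sum_j |beta_jm|

with f(x; beta^m) = beta_0^m + x . beta_{1..p}^m. The group term couples each
feature's coefficients across studies (consensus selection); the L1 term
allows study-specific dropouts. Intercepts are never penalized.

Algorithm (successive quadratic approximation + coordinate-descent Newton):
the hinge satisfies [1 - y f]_+ = (1 - y f)/2 + |y - f|/2 for y in {-1, +1},
and |y - f| is majorized at the current iterate beta* by the weighted
quadratic (1/2)[(y - f)^2 / a* + a*] with a* = max(|y - f(beta*)|, delta).
Each outer round rebuilds the weights at the current iterate, then minimizes
the resulting majorizer by coordinate sweeps until the coefficients
stabilize; each coordinate's subproblem is a penalized univariate quadratic
solved exactly by the closed-form/Newton routines in
:mod:`metasvm.penalties`. This is a majorize-minimize scheme, so the exact
objective above is non-increasing along the trace (a sweep that fails to
decrease it — possible only at the O(s) smoothing-bias floor — is rolled
back and treated as convergence).

The per-study loss is normalized by n^(m); lambda1/lambda2 are interpreted on
that scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np

from .datamodel import (
    CoefficientSet,
    ConvergenceError,
    FitResult,
    MetaDataset,
    PenaltyConfig,
    StudyData,
    validate_meta_dataset,
)
from .penalties import _fs, _sgl_newton, _smoothed_abs, logistic_curvature

__all__ = [
    "SQAState",
    "decision_values",
    "hinge_objective",
    "hinge_identity_check",
    "build_sqa_weights",
    "smoothed_objective",
    "smoothed_gradient_hessian",
    "fit",
]


# ---------------------------------------------------------------------------
# Objective pieces
# ---------------------------------------------------------------------------

def decision_values(study: StudyData, beta_m: np.ndarray) -> np.ndarray:
    """Linear decision values f(x_i; beta^m) = beta_0 + x_i . beta_{1..p}."""
    beta_m = np.asarray(beta_m, dtype=float).ravel()
    if beta_m.shape[0] != study.p + 1:
        raise ValueError(
            f"coefficient vector length {beta_m.shape[0]} != p+1 = {study.p + 1}"
        )
    return beta_m[0] + study.X @ beta_m[1:]


def hinge_objective(
    data: MetaDataset,
    beta: CoefficientSet,
    cfg: PenaltyConfig,
    normalized: bool = False,
) -> float:
    """Exact (unsmoothed) penalized hinge objective.

    With ``normalized=False`` the hinge sum is raw; with ``normalized=True``
    each study's hinge sum is divided by n^(m) — the scaling on which the
    solver operates and interprets the lambdas.
    """
    total = 0.0
    for m, st in enumerate(data.studies):
        margins = 1.0 - st.y * decision_values(st, beta.beta[m])
        loss = float(np.sum(np.maximum(margins, 0.0)))
        total += loss / st.n if normalized else loss
    total += cfg.lambda1 * float(np.sum(beta.group_norms()))
    total += cfg.lambda2 * float(np.sum(np.abs(beta.beta[:, 1:])))
    return total


def hinge_identity_check(y: float, f: float) -> tuple[float, float]:
    """Both sides of [1 - y f]_+ = (1 - y f)/2 + |y - f|/2 (valid for y^2=1)."""
    if y not in (-1.0, 1.0, -1, 1):
        raise ValueError("y must be -1 or +1")
    lhs = max(0.0, 1.0 - y * f)
    rhs = (1.0 - y * f) / 2.0 + abs(y - f) / 2.0
    return lhs, rhs


# ---------------------------------------------------------------------------
# Successive quadratic approximation
# ---------------------------------------------------------------------------

@dataclass
class SQAState:
    """Quadratic expansion of the hinge at beta_star.

    ``floored_resid[m]`` holds a*_i = max(|y_i - f(x_i; beta_star^m)|, delta)
    and ``weights[m]`` their reciprocals w_i = 1/a*_i; both strictly positive
    and finite.
    """

    beta_star: CoefficientSet
    weights: list[np.ndarray]
    floored_resid: list[np.ndarray]


def build_sqa_weights(
    data: MetaDataset, beta_star: CoefficientSet, delta: float
) -> SQAState:
    """Quadratic-majorization weights w_i = 1/max(|y_i - f_i(beta_star)|, delta)."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    weights, floored = [], []
    for m, st in enumerate(data.studies):
        resid = st.y - decision_values(st, beta_star.beta[m])
        a = np.maximum(np.abs(resid), delta)
        floored.append(a)
        weights.append(1.0 / a)
    return SQAState(beta_star.copy(), weights, floored)


def smoothed_objective(
    data: MetaDataset,
    beta: CoefficientSet,
    state: SQAState,
    cfg: PenaltyConfig,
) -> float:
    """The smoothed quadratic majorizer of the normalized objective.

    Loss part: per study, 1/2 - (1/2n) sum y_i f_i + (1/4n) sum a*_i
    + (1/4n) sum (y_i - f_i)^2 / a*_i, which touches the normalized hinge at
    the expansion point and lies above it elsewhere. Penalty part: group norm
    smoothed with eps under the root, |z| smoothed by the logistic
    antiderivative. Used as the finite-difference oracle target and for
    majorization checks.
    """
    total = 0.0
    for m, st in enumerate(data.studies):
        f = decision_values(st, beta.beta[m])
        a = state.floored_resid[m]
        n = st.n
        total += (
            0.5
            - float(np.sum(st.y * f)) / (2.0 * n)
            + float(np.sum(a)) / (4.0 * n)
            + float(np.sum((st.y - f) ** 2 / a)) / (4.0 * n)
        )
    group_sq = np.sum(beta.beta[:, 1:] ** 2, axis=0)
    total += cfg.lambda1 * float(np.sum(np.sqrt(group_sq + cfg.eps)))
    for m in range(data.M):
        for bj in beta.beta[m, 1:]:
            total += cfg.lambda2 * _smoothed_abs(float(bj), cfg.s)
    return total


def smoothed_gradient_hessian(
    data: MetaDataset,
    beta: CoefficientSet,
    state: SQAState,
    cfg: PenaltyConfig,
    m: int,
    j: int,
) -> tuple[float, float]:
    """Gradient entry and Hessian diagonal of the smoothed objective.

    Coordinate (m, j) with j = 0 the intercept. The penalty contributes
    lambda1 * beta_j / sqrt(beta_j^2 + d_j + eps) + lambda2 * F_s(beta_j) to
    the gradient and lambda1 * (d_j + eps)/(beta_j^2 + d_j + eps)^{3/2}
    + lambda2 * F_s'(beta_j) to the curvature, with
    d_j = sum_{m' != m} beta_jm'^2 and nothing for j = 0. The returned
    curvature is strictly positive.
    """
    st = data.studies[m]
    n = st.n
    w = state.weights[m]
    f = decision_values(st, beta.beta[m])
    xj = np.ones(n) if j == 0 else st.X[:, j - 1]
    g = -(float(np.sum(w * xj * (st.y - f))) + float(np.sum(st.y * xj))) / (2.0 * n)
    h = float(np.sum(w * xj * xj)) / (2.0 * n)
    if j > 0:
        bj = beta.beta[m, j]
        d = float(np.sum(beta.beta[:, j] ** 2)) - bj * bj
        root = math.sqrt(bj * bj + d + cfg.eps)
        g += cfg.lambda1 * bj / root + cfg.lambda2 * _fs(float(bj), cfg.s)
        h += cfg.lambda1 * (d + cfg.eps) / root**3
        h += cfg.lambda2 * logistic_curvature(float(bj), cfg.s)
    if not (math.isfinite(g) and math.isfinite(h)):
        raise FloatingPointError(
            "non-finite gradient/Hessian entry; residual floor delta too small"
        )
    return g, h


# ---------------------------------------------------------------------------
# Coordinate-descent sweep (hot path)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _majorizer_sweeps(
    Xa, y, w, offsets, beta, group_sq, zy, l1, l2, s,
    inner_tol, max_inner, max_sweeps, stab_tol,
):
    """Coordinate sweeps on the fixed-weight majorizer until stable, in place.

    Xa is the row-concatenated [1 | X] design of all studies, w the SQA
    weights built at the expansion point, zy[m, j] = sum_i y_i x_ij (fixed
    per dataset). Sweeps run studies outer, coordinates inner, and stop when
    no coefficient moves by more than a relative 1e-9. Returns the number of
    univariate solves that failed to converge (0 in normal operation).
    """
    M = beta.shape[0]
    P1 = beta.shape[1]
    nfail = 0
    # per-outer constants: curvature of each coordinate under these weights
    bq = np.empty((M, P1))
    for m in range(M):
        o0 = offsets[m]
        o1 = offsets[m + 1]
        inv2n = 1.0 / (2.0 * (o1 - o0))
        for j in range(P1):
            acc = 0.0
            for i in range(o0, o1):
                xij = Xa[i, j]
                acc += w[i] * xij * xij
            bq[m, j] = acc * inv2n
    for _ in range(max_sweeps):
        max_move = 0.0
        max_mag = 1.0
        for m in range(M):
            o0 = offsets[m]
            o1 = offsets[m + 1]
            n = o1 - o0
            inv2n = 1.0 / (2.0 * n)
            r = np.empty(n)
            for i in range(n):
                acc = y[o0 + i]
                for j in range(P1):
                    acc -= Xa[o0 + i, j] * beta[m, j]
                r[i] = acc
            for j in range(P1):
                b = bq[m, j]
                if b <= 1e-300:
                    continue  # all-zero feature column: coefficient stays 0
                gq = 0.0
                for i in range(n):
                    gq += w[o0 + i] * Xa[o0 + i, j] * r[i]
                old = beta[m, j]
                g = -inv2n * (gq + zy[m, j])
                c = old - g / b
                if j == 0:
                    z = c
                else:
                    d = group_sq[j] - old * old
                    if d < 0.0:
                        d = 0.0
                    z, ok = _sgl_newton(b, c, d, l1, l2, s, inner_tol, max_inner)
                    if not ok:
                        nfail += 1
                if z != old:
                    diff = z - old
                    for i in range(n):
                        r[i] -= Xa[o0 + i, j] * diff
                    if j > 0:
                        group_sq[j] += z * z - old * old
                    beta[m, j] = z
                    if abs(diff) > max_move:
                        max_move = abs(diff)
                if abs(z) > max_mag:
                    max_mag = abs(z)
        if max_move <= stab_tol * max_mag or nfail > 0:
            break
    return nfail


def _augmented_design(data: MetaDataset):
    blocks = [np.column_stack([np.ones(st.n), st.X]) for st in data.studies]
    offsets = np.zeros(data.M + 1, dtype=np.int64)
    for m, st in enumerate(data.studies):
        offsets[m + 1] = offsets[m] + st.n
    return np.ascontiguousarray(np.vstack(blocks)), np.concatenate(
        [st.y for st in data.studies]
    ), offsets


# ---------------------------------------------------------------------------
# Fitting loop
# ---------------------------------------------------------------------------

def fit(
    data: MetaDataset,
    cfg: PenaltyConfig,
    init: CoefficientSet | None = None,
) -> FitResult:
    """Fit the meta-analytic SVM by SQA + coordinate-descent Newton.

    Each outer round rebuilds the majorization weights at the current
    iterate, then minimizes the fixed-weight majorizer by exact coordinate
    sweeps (intercept first, then features in index order, studies in index
    order) until the coefficients stabilize. Terminates when the normalized
    objective changes by less than tol*(1+|objective|), when a sweep no
    longer decreases it (smoothing floor; the sweep is rolled back), or at
    ``max_outer`` rounds. ``objective_trace`` records the exact objective on
    the normalized scale and is non-increasing.
    """
    validate_meta_dataset(data)
    M, p = data.M, data.p
    if init is None:
        beta = np.zeros((M, p + 1))
    else:
        if init.beta.shape != (M, p + 1):
            raise ValueError(
                f"init shape {init.beta.shape} != expected {(M, p + 1)}"
            )
        beta = init.beta.astype(float).copy()
    Xa, y_all, offsets = _augmented_design(data)
    group_sq = np.concatenate([[0.0], np.sum(beta[:, 1:] ** 2, axis=0)])
    zy = np.stack([np.concatenate([[st.y.sum()], st.y @ st.X])
                   for st in data.studies])

    def objective(b: np.ndarray) -> float:
        return hinge_objective(data, CoefficientSet(b), cfg, normalized=True)

    trace = [objective(beta)]
    converged = False
    for _ in range(cfg.max_outer):
        resid = np.abs(y_all - _rowwise_decision(Xa, offsets, beta))
        w = 1.0 / np.maximum(resid, cfg.delta)
        beta_prev = beta.copy()
        gs_prev = group_sq.copy()
        # minimize the fixed-weight majorizer by coordinate sweeps
        nfail = _majorizer_sweeps(
            Xa, y_all, w, offsets, beta, group_sq, zy,
            cfg.lambda1, cfg.lambda2, cfg.s, cfg.inner_tol, cfg.max_inner,
            cfg.inner_sweeps, cfg.stab_tol,
        )
        if nfail:
            raise ConvergenceError(
                f"{nfail} univariate subproblems failed to converge"
            )
        new_obj = objective(beta)
        if new_obj > trace[-1] + 1e-12 * (1.0 + abs(trace[-1])):
            # smoothing-bias floor reached: roll back, keep trace monotone
            beta = beta_prev
            group_sq = gs_prev
            converged = True
            break
        trace.append(new_obj)
        if abs(trace[-2] - new_obj) <= cfg.tol * (1.0 + abs(new_obj)):
            converged = True
            break

    coef = CoefficientSet(beta)
    thr = cfg.selection_threshold
    selected = np.abs(beta[:, 1:]) > thr
    return FitResult(
        coefficients=coef,
        objective_trace=trace,
        converged=converged,
        n_outer=len(trace) - 1,
        selected=selected,
        selected_union=selected.any(axis=0),
    )


def _rowwise_decision(Xa, offsets, beta):
    out = np.empty(Xa.shape[0])
    for m in range(beta.shape[0]):
        sl = slice(offsets[m], offsets[m + 1])
        out[sl] = Xa[sl] @ beta[m]
    return out
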