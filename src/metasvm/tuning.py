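"""Cross-validated choice of the penalty weights (lambda1, lambda2).

K-fold CV stratified within each study: folds are drawn class-balanced per
study with a seeded RNG, the model is fit jointly on the training folds of
every study, and each grid point is scored by the mean hinge loss on the
pooled held-out samples. The chosen pair is then picked by one of three
rules (score minimum, one-standard-error, or the default group-preferring
one-standard-error rule; see :func:`cv_grid_search`). The default grid
spans [0.01, 1] x lambda_max on a log scale in each penalty, where
lambda_max is the smallest weight that keeps every feature at zero when the
other penalty is off.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MetaDataset, PenaltyConfig, validate_meta_dataset
from .solver import fit

__all__ = ["lambda_max", "default_grid", "make_folds", "cv_grid_search"]


def lambda_max(data: MetaDataset) -> tuple[float, float]:
    """Smallest (lambda1, lambda2) zeroing all features with the other at 0.

    At beta = 0 every residual is |y| = 1, all quadratic-approximation
    weights are 1, and the normalized-loss gradient for feature j in study m
    is g_jm = -(1/n^m) sum_i y_i x_ij. Feature j stays at zero under the L1
    penalty iff |g_jm| <= lambda2 for all (m, j), and under the group penalty
    iff the across-study norm of (g_j1..g_jM) is <= lambda1 for all j.
    """
    validate_meta_dataset(data)
    G = np.stack(
        [st.y @ st.X / st.n for st in data.studies]
    )  # (M, p)
    l2max = float(np.max(np.abs(G)))
    l1max = float(np.max(np.sqrt(np.sum(G**2, axis=0))))
    return l1max, l2max


def default_grid(
    data: MetaDataset,
    n_points: int = 8,
    lo_frac: float = 0.01,
) -> list[tuple[float, float]]:
    """Cross product of log-spaced fractions [lo_frac, 1] of each lambda_max."""
    l1max, l2max = lambda_max(data)
    fracs = np.logspace(np.log10(lo_frac), 0.0, n_points)
    return [
        (float(l1max * f1), float(l2max * f2)) for f1 in fracs for f2 in fracs
    ]


def make_folds(
    data: MetaDataset, k: int, seed: int
) -> list[list[np.ndarray]]:
    """Per-study fold assignments, stratified by class.

    Returns ``folds[f][m]`` = indices of study m held out in fold f.

    Raises
    ------
    ValueError
        If any class of any study has fewer than k samples (a fold would
        lose that class).
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    per_study = []
    for st in data.studies:
        assign = np.empty(st.n, dtype=np.int64)
        for cls in (-1.0, 1.0):
            idx = np.flatnonzero(st.y == cls)
            if idx.size < k:
                raise ValueError(
                    f"study '{st.name}': class {int(cls):+d} has {idx.size} "
                    f"samples, fewer than k={k} folds (a fold would hold a "
                    f"single class); reduce k"
                )
            rng.shuffle(idx)
            assign[idx] = np.arange(idx.size) % k
        per_study.append(assign)
    return [
        [np.flatnonzero(assign == f) for assign in per_study] for f in range(k)
    ]


def _heldout_hinge(data: MetaDataset, beta: np.ndarray, held: list[np.ndarray]) -> tuple[float, int]:
    total, count = 0.0, 0
    for m, st in enumerate(data.studies):
        idx = held[m]
        if idx.size == 0:
            continue
        f = beta[m, 0] + st.X[idx] @ beta[m, 1:]
        total += float(np.sum(np.maximum(1.0 - st.y[idx] * f, 0.0)))
        count += idx.size
    return total, count


def cv_grid_search(
    data: MetaDataset,
    grid: list[tuple[float, float]] | None,
    k: int,
    seed: int,
    cfg: PenaltyConfig,
    rule: str = "1se_group",
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Score every (lambda1, lambda2) pair by k-fold CV hinge loss.

    ``rule`` picks the pair from the score table:

    - ``"min"``: smallest mean held-out hinge, exact ties broken toward the
      larger lambda1 + lambda2.
    - ``"1se"``: most penalized pair (largest lambda1 + lambda2) whose mean
      score is within one standard error of the minimum.
    - ``"1se_group"`` (default): among pairs within one standard error of
      the minimum, the largest group weight lambda1, then the smallest
      lambda2. Prediction loss is nearly flat over a wide penalty range
      here, and among statistically indistinguishable models a consensus
      feature selector should prefer the one whose sparsity comes from the
      shared across-study structure rather than study-specific dropout;
      the elementwise tie-break avoids trading that structure away.

    Returns the chosen pair and the full score table (mean and SE per pair)
    in grid order. Fits within a fold are warm-started along a
    strong-to-weak penalty path.
    """
    validate_meta_dataset(data)
    if grid is None:
        grid = default_grid(data)
    if len(grid) == 0:
        raise ValueError("empty grid")
    if rule not in ("min", "1se", "1se_group"):
        raise ValueError(f"unknown CV rule '{rule}'")
    folds = make_folds(data, k, seed)
    # fit strong-to-weak so warm starts carry sparse solutions forward
    order = sorted(
        range(len(grid)), key=lambda i: -(grid[i][0] + grid[i][1])
    )
    fold_losses = np.zeros((k, len(grid)))
    for f, held in enumerate(folds):
        keep = [
            np.setdiff1d(np.arange(st.n), idx)
            for st, idx in zip(data.studies, held)
        ]
        train = data.subset_samples(keep)
        warm = None
        fold_count = sum(idx.size for idx in held)
        for i in order:
            l1, l2 = grid[i]
            res = fit(train, cfg.with_lambdas(l1, l2), init=warm)
            warm = res.coefficients
            loss, _ = _heldout_hinge(data, res.coefficients.beta, held)
            fold_losses[f, i] = loss / fold_count
    cv_loss = fold_losses.mean(axis=0)
    cv_se = fold_losses.std(axis=0, ddof=1) / np.sqrt(k)
    table = pd.DataFrame(
        {
            "lambda1": [g[0] for g in grid],
            "lambda2": [g[1] for g in grid],
            "cv_hinge": cv_loss,
            "cv_se": cv_se,
        }
    )
    imin = min(
        range(len(grid)),
        key=lambda i: (cv_loss[i], -(grid[i][0] + grid[i][1])),
    )
    if rule == "min":
        best = imin
    else:
        cutoff = cv_loss[imin] + cv_se[imin]
        cand = [i for i in range(len(grid)) if cv_loss[i] <= cutoff]
        if rule == "1se":
            best = max(cand, key=lambda i: grid[i][0] + grid[i][1])
        else:
            best = max(cand, key=lambda i: (grid[i][0], -grid[i][1]))
    return (grid[best][0], grid[best][1]), table
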