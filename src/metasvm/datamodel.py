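"""Domain types shared across the meta-analytic SVM package.

A *meta-dataset* is a collection of M case/control studies measuring the same
ordered panel of p features (genes, probes, ...). Each study m contributes a
numeric matrix X^(m) of shape n^(m) x p and a label vector y^(m) with entries
in {-1, +1} (-1 = control, +1 = case). The joint classifier is linear per
study, f(x; beta^(m)) = beta_0^(m) + sum_j x_j beta_j^(m), and the M
coefficient vectors are tied together by a group penalty on each feature's
across-study coefficient vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyData",
    "MetaDataset",
    "CoefficientSet",
    "PenaltyConfig",
    "FitResult",
    "UnivariateProblem",
    "validate_meta_dataset",
    "save_meta_dataset",
    "load_meta_dataset",
    "load_study",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative solver exhausts its iteration budget."""


@dataclass
class StudyData:
    """One study: samples x features matrix plus binary phenotype labels.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Numeric feature values, one row per sample.
    y : ndarray, shape (n,)
        Phenotype labels in {-1, +1}; -1 = control, +1 = case.
    name : str
        Study identifier used in reports and on disk.
    sample_ids : sequence of str, optional
        Defaults to ``s1..sn``.
    """

    X: np.ndarray
    y: np.ndarray
    name: str = "study"
    sample_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(self.X.shape[0])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class MetaDataset:
    """M aligned studies sharing one ordered feature panel."""

    studies: list[StudyData]
    feature_names: list[str]

    @property
    def M(self) -> int:
        return len(self.studies)

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def subset_samples(self, keep: Sequence[np.ndarray]) -> "MetaDataset":
        """Return a copy restricted to the given per-study sample indices."""
        studies = []
        for st, idx in zip(self.studies, keep):
            idx = np.asarray(idx)
            studies.append(
                StudyData(
                    st.X[idx],
                    st.y[idx],
                    name=st.name,
                    sample_ids=[st.sample_ids[i] for i in idx],
                )
            )
        return MetaDataset(studies, list(self.feature_names))


@dataclass
class CoefficientSet:
    """Per-study coefficient vectors, stacked as an M x (p+1) matrix.

    Column 0 holds the unpenalized intercepts beta_0^(m); columns 1..p hold
    the feature coefficients beta_j^(m).
    """

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))

    @property
    def M(self) -> int:
        return self.beta.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[1] - 1

    def group_norm(self, j: int) -> float:
        """Across-study Euclidean norm of feature j's coefficients (1-based j)."""
        if not 1 <= j <= self.p:
            raise IndexError(f"feature index {j} outside 1..{self.p}")
        return float(np.sqrt(np.sum(self.beta[:, j] ** 2)))

    def group_norms(self) -> np.ndarray:
        """Vector of all p across-study group norms."""
        return np.sqrt(np.sum(self.beta[:, 1:] ** 2, axis=0))

    @staticmethod
    def zeros(M: int, p: int) -> "CoefficientSet":
        return CoefficientSet(np.zeros((M, p + 1)))

    def copy(self) -> "CoefficientSet":
        return CoefficientSet(self.beta.copy())


@dataclass
class PenaltyConfig:
    """Penalty weights and solver controls.

    Parameters
    ----------
    lambda1 : float
        Group-lasso weight on each feature's across-study coefficient norm.
        Interpreted on the per-study-normalized hinge scale.
    lambda2 : float
        Elementwise L1 weight, same scale.
    s : float
        Scale of the logistic smoothing of \\|z\\|; smaller is closer to the
        exact L1 penalty but stiffer (the smoothed curvature grows like 1/s).
    eps : float
        Constant added under the group-norm square root so the group penalty
        is twice differentiable at zero.
    delta : float
        Floor on the absolute residual used in the quadratic-approximation
        weights w_i = 1/max(|y_i - f_i|, delta); keeps the Hessian finite.
        Too small a floor (<= 1e-6) makes samples riding the hinge kink
        freeze the iteration far from the optimum.
    max_outer : int
        Maximum number of outer (weight rebuild + majorizer minimization)
        rounds.
    inner_sweeps : int
        Maximum coordinate sweeps per outer round when minimizing the
        fixed-weight majorizer (the loop exits early once coefficients
        stabilize).
    stab_tol : float
        Relative coefficient-stability tolerance ending those sweeps; the
        majorizer only needs to be minimized well enough to keep the outer
        loop descending, not to machine precision.
    max_inner : int
        Maximum damped-Newton iterations for one univariate subproblem.
    tol : float
        Relative objective-change convergence tolerance of the outer loop.
    inner_tol : float
        First-derivative tolerance of the univariate Newton solver.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    s: float = 1e-3
    eps: float = 1e-8
    delta: float = 1e-4
    max_outer: int = 200
    max_inner: int = 100
    tol: float = 1e-6
    inner_tol: float = 1e-8
    inner_sweeps: int = 50
    stab_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights lambda1, lambda2 must be >= 0")
        for name in ("s", "eps", "delta", "tol", "inner_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_outer < 1 or self.max_inner < 1:
            raise ValueError("iteration limits must be >= 1")

    @property
    def selection_threshold(self) -> float:
        """Coefficients with |beta| below 10*s are reported as not selected.

        The logistic smoothing cannot produce exact zeros, but its bias is on
        the order of the smoothing scale, so anything within 10*s of zero is
        indistinguishable from an exact zero of the unsmoothed problem.
        """
        return 10.0 * self.s

    def with_lambdas(self, lambda1: float, lambda2: float) -> "PenaltyConfig":
        return replace(self, lambda1=lambda1, lambda2=lambda2)


@dataclass
class FitResult:
    """Converged coefficients plus the optimization and selection record."""

    coefficients: CoefficientSet
    objective_trace: list[float]
    converged: bool
    n_outer: int
    selected: np.ndarray = field(default=None)  # (M, p) bool
    selected_union: np.ndarray = field(default=None)  # (p,) bool


@dataclass
class UnivariateProblem:
    """One coordinate's local problem: b/2 (z-c)^2 + l1 sqrt(z^2+d) + l2 |z|.

    ``b`` is the quadratic curvature, ``c`` the unpenalized minimizer and
    ``d`` the sum of squared sibling coefficients (the same feature's
    coefficients in the other studies).
    """

    b: float
    c: float
    d: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    s: float = 1e-3
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("curvature b must be > 0")
        if self.d < 0:
            raise ValueError("sibling sum of squares d must be >= 0")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.s <= 0 or self.eps <= 0:
            raise ValueError("smoothing constants must be > 0")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_meta_dataset(data: MetaDataset) -> MetaDataset:
    """Check all meta-dataset invariants; return the dataset unchanged.

    Raises
    ------
    ValueError
        On a feature mismatch between studies, labels outside {-1, +1},
        a study containing a single class, non-numeric entries, or fewer
        than two samples in a study.
    """
    if data.M < 1:
        raise ValueError("a meta-dataset needs at least one study")
    p = data.p
    for st in data.studies:
        if st.X.ndim != 2 or st.X.shape[1] != p:
            raise ValueError(
                f"feature mismatch: study '{st.name}' has {st.X.shape[1]} "
                f"features, expected {p}"
            )
        if st.n < 2:
            raise ValueError(f"study '{st.name}' has fewer than 2 samples")
        if st.y.shape[0] != st.n:
            raise ValueError(
                f"study '{st.name}': {st.y.shape[0]} labels for {st.n} samples"
            )
        if not np.all(np.isfinite(st.X)):
            raise ValueError(f"study '{st.name}' contains non-finite values")
        labels = set(np.unique(st.y))
        if not labels <= {-1.0, 1.0}:
            raise ValueError(
                f"study '{st.name}' labels must be coded -1/+1 "
                f"(got {sorted(labels)}); recode e.g. 0/1 to -1/+1"
            )
        if len(labels) < 2:
            raise ValueError(f"study '{st.name}' contains a single class")
    return data


# ---------------------------------------------------------------------------
# On-disk format
#
# Per study two TSV files: <name>.expr.tsv holds the feature-by-sample matrix
# (first column = feature IDs, header row = sample IDs) and <name>.labels.tsv
# holds two columns (sample ID, label). A meta.json manifest records study
# order and the shared feature order.
# ---------------------------------------------------------------------------

def save_meta_dataset(data: MetaDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for st in data.studies:
        expr = pd.DataFrame(
            st.X.T, index=data.feature_names, columns=list(st.sample_ids)
        )
        expr.index.name = "feature"
        expr.to_csv(outdir / f"{st.name}.expr.tsv", sep="\t")
        labels = pd.DataFrame(
            {"sample": list(st.sample_ids), "label": st.y.astype(int)}
        )
        labels.to_csv(outdir / f"{st.name}.labels.tsv", sep="\t", index=False)
    manifest = {
        "studies": [st.name for st in data.studies],
        "n_features": data.p,
    }
    (outdir / "meta.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def load_study(
    expr_path: str | Path,
    labels_path: str | Path,
    name: str | None = None,
    recode01: bool = False,
) -> tuple[StudyData, list[str]]:
    """Read one study from its expression and label TSVs.

    With ``recode01=True`` labels coded {0, 1} are mapped to {-1, +1}
    (0 -> -1); otherwise labels are taken as stored.
    """
    expr = pd.read_csv(
        expr_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    lab = pd.read_csv(labels_path, sep="\t")
    if lab.shape[1] < 2:
        raise ValueError(f"label file {labels_path} needs (sample, label) columns")
    lab = lab.set_index(lab.columns[0])[lab.columns[1]]
    try:
        y = lab.loc[expr.columns].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"label file {labels_path} misses sample {exc}") from exc
    if recode01:
        uniq = set(np.unique(y))
        if uniq <= {0.0, 1.0}:
            y = np.where(y > 0, 1.0, -1.0)
    if name is None:
        name = Path(expr_path).name.replace(".expr.tsv", "")
    return StudyData(
        expr.to_numpy(dtype=float).T,
        y,
        name=name,
        sample_ids=list(expr.columns),
    ), list(expr.index)


def load_meta_dataset(indir: str | Path, recode01: bool = False) -> MetaDataset:
    """Read a meta-dataset written by :func:`save_meta_dataset`."""
    indir = Path(indir)
    manifest = json.loads((indir / "meta.json").read_text())
    studies: list[StudyData] = []
    feature_names: list[str] | None = None
    for name in manifest["studies"]:
        st, feats = load_study(
            indir / f"{name}.expr.tsv",
            indir / f"{name}.labels.tsv",
            name=name,
            recode01=recode01,
        )
        if feature_names is None:
            feature_names = feats
        elif feats != feature_names:
            raise ValueError(f"feature mismatch: study '{name}' feature order differs")
        studies.append(st)
    return validate_meta_dataset(MetaDataset(studies, feature_names))
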