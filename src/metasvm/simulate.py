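"""Synthetic multi-study expression data with correlated gene clusters.

The generator emulates a small meta-analysis of case/control expression
studies. Gene correlation enters through C clusters of ``cluster_size`` genes:
for each cluster and study a covariance is drawn from an inverse-Wishart
distribution with scale psi = 0.5 I + 0.5 J and 60 degrees of freedom, then
rescaled to unit diagonal (a correlation matrix); clustered genes are sampled
jointly MVN(0, R * Sigma) while unclustered genes are independent N(0, R),
with R a total-variance scale. The first ``n_de`` genes are differentially
expressed: case samples are shifted by study-specific effect sizes drawn from
Unif(0.1, 0.5). Optionally the last ``n_noise_studies`` studies are replaced
wholesale by N(0, R) noise carrying no signal, mimicking meta-analyses where
only a subset of studies is informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import MetaDataset, StudyData

__all__ = [
    "SimulationSpec",
    "SimulatedMeta",
    "sample_cluster_labels",
    "sample_cluster_covariance",
    "generate",
]


def _default_psi() -> np.ndarray:
    return 0.5 * np.eye(5) + 0.5 * np.ones((5, 5))


@dataclass
class SimulationSpec:
    """Generative protocol parameters (defaults are the benchmark conditions).

    P genes x N samples per study (first N/2 controls, last N/2 cases) in
    each of M studies; C clusters of ``cluster_size`` correlated genes;
    ``n_de`` genes (1..n_de) carry Unif(0.1, 0.5) case shifts; R scales the
    total variance (benchmark scenarios use 0.1 / 0.3 / 0.5).
    """

    P: int = 30
    N: int = 20
    M: int = 3
    n_clusters: int = 2
    cluster_size: int = 5
    wishart_df: int = 60
    wishart_psi: np.ndarray = field(default_factory=_default_psi)
    R: float = 1.0
    n_de: int = 10
    effect_low: float = 0.1
    effect_high: float = 0.5
    n_noise_studies: int = 0
    random_noise_studies: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.wishart_psi = np.asarray(self.wishart_psi, dtype=float)
        if self.n_clusters * self.cluster_size > self.P:
            raise ValueError("clusters do not fit: C * cluster_size > P")
        if self.n_de > self.P:
            raise ValueError("n_de > P")
        if self.n_noise_studies >= self.M:
            raise ValueError("n_noise_studies must be < M")
        if self.N % 2:
            raise ValueError("N must be even (N/2 controls, N/2 cases)")
        if self.R <= 0:
            raise ValueError("variance scale R must be > 0")


@dataclass
class SimulatedMeta:
    """Generated meta-dataset plus the ground truth used to score selection."""

    data: MetaDataset
    truth: np.ndarray  # (P,) bool, True = DE gene
    noise_studies: set[int]


def sample_cluster_labels(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Assign genes to clusters: label c in 1..C for cluster members, 0 otherwise.

    Exactly ``cluster_size`` genes per cluster, chosen uniformly at random.
    """
    labels = np.zeros(spec.P, dtype=np.int64)
    perm = rng.permutation(spec.P)
    for c in range(spec.n_clusters):
        members = perm[c * spec.cluster_size : (c + 1) * spec.cluster_size]
        labels[members] = c + 1
    return labels


def sample_cluster_covariance(
    spec: SimulationSpec, rng: np.random.Generator, max_tries: int = 100
) -> np.ndarray:
    """One unit-diagonal (correlation-scaled) inverse-Wishart covariance draw.

    Draws Sigma* ~ InvWishart(psi, df) and returns D^-1 Sigma* D^-1 with
    D = diag(sqrt(diag Sigma*)): symmetric, positive definite, unit diagonal.
    Degenerate draws (numerically non-PD after rescaling) are redrawn.
    """
    psi = spec.wishart_psi
    for _ in range(max_tries):
        sigma_star = stats.invwishart.rvs(
            df=spec.wishart_df, scale=psi, random_state=rng
        )
        d = np.sqrt(np.diag(sigma_star))
        corr = sigma_star / np.outer(d, d)
        corr = (corr + corr.T) / 2.0
        if np.linalg.eigvalsh(corr).min() > 1e-10:
            np.fill_diagonal(corr, 1.0)
            return corr
    raise RuntimeError(f"no positive-definite draw in {max_tries} tries")


def generate(spec: SimulationSpec) -> SimulatedMeta:
    """Generate the full M-study dataset; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    labels = sample_cluster_labels(spec, rng)
    half = spec.N // 2
    if spec.random_noise_studies:
        noise = set(
            rng.choice(spec.M, size=spec.n_noise_studies, replace=False).tolist()
        )
    else:
        noise = set(range(spec.M - spec.n_noise_studies, spec.M))
    y = np.concatenate([-np.ones(half), np.ones(half)])
    studies = []
    sd = float(np.sqrt(spec.R))
    for m in range(spec.M):
        if m in noise:
            Y = rng.normal(0.0, sd, size=(spec.P, spec.N))
        else:
            Y = np.empty((spec.P, spec.N))
            for c in range(1, spec.n_clusters + 1):
                idx = np.flatnonzero(labels == c)
                corr = sample_cluster_covariance(spec, rng)
                block = rng.multivariate_normal(
                    np.zeros(spec.cluster_size), spec.R * corr, size=spec.N,
                    method="cholesky",
                )
                Y[idx, :] = block.T
            free = np.flatnonzero(labels == 0)
            Y[free, :] = rng.normal(0.0, sd, size=(free.size, spec.N))
            mu = rng.uniform(spec.effect_low, spec.effect_high, size=spec.n_de)
            Y[: spec.n_de, half:] += mu[:, None]
        studies.append(
            StudyData(
                Y.T,
                y.copy(),
                name=f"study{m + 1}",
                sample_ids=[f"study{m + 1}_s{i + 1}" for i in range(spec.N)],
            )
        )
    feature_names = [f"gene{p + 1:02d}" for p in range(spec.P)]
    truth = np.zeros(spec.P, dtype=bool)
    truth[: spec.n_de] = True
    return SimulatedMeta(MetaDataset(studies, feature_names), truth, noise)
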