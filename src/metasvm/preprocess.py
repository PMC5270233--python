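"""Preprocessing operators for user-supplied multi-study matrices.

Three standard steps before a joint fit: intersect feature panels across
studies (different platforms rarely share every probe), standardize each
feature within each study (studies come from different platforms, so
centering/scaling is per study, never pooled), and keep only the most
expressed/most variable features by a rank-sum filter. The filter is
label-blind: it looks only at per-study means and variances, so it cannot
bias downstream selection toward the phenotype.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datamodel import MetaDataset, StudyData

__all__ = ["match_features", "center_scale", "ranksum_filter"]


def match_features(
    studies: list[tuple[StudyData, list[str]]]
) -> MetaDataset:
    """Align studies on the intersection of their feature panels.

    Input is a list of (study, feature_names) pairs whose panels may differ;
    output keeps the shared features only, in the first study's order.
    """
    if not studies:
        raise ValueError("no studies given")
    shared = set(studies[0][1])
    for _, feats in studies[1:]:
        shared &= set(feats)
    if not shared:
        raise ValueError("empty feature intersection across studies")
    order = [f for f in studies[0][1] if f in shared]
    aligned = []
    for st, feats in studies:
        pos = {f: i for i, f in enumerate(feats)}
        idx = np.array([pos[f] for f in order])
        aligned.append(
            StudyData(st.X[:, idx], st.y, name=st.name, sample_ids=st.sample_ids)
        )
    return MetaDataset(aligned, order)


def center_scale(data: MetaDataset) -> MetaDataset:
    """Per study, per feature: subtract the mean, divide by the sample SD.

    Idempotent (standardized input comes back unchanged). A zero-variance
    feature in any study is an error naming the feature.
    """
    studies = []
    for st in data.studies:
        mu = st.X.mean(axis=0)
        sd = st.X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd <= 0)
        if bad.size:
            names = ", ".join(data.feature_names[j] for j in bad[:5])
            raise ValueError(
                f"zero-variance feature(s) in study '{st.name}': {names}"
            )
        studies.append(
            StudyData((st.X - mu) / sd, st.y, name=st.name, sample_ids=st.sample_ids)
        )
    return MetaDataset(studies, list(data.feature_names))


def ranksum_filter(data: MetaDataset, n_keep: int) -> MetaDataset:
    """Keep the n_keep features with the best mean/variance rank sum.

    Within each study every feature gets a descending rank (rank 1 = largest)
    for its mean intensity and, separately, for its variance; the rank sum
    adds both criteria over all studies and small sums win (highly expressed,
    highly variable features are retained). Ties are broken by feature name.
    Invariant to study order.
    """
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    if n_keep > data.p:
        raise ValueError(f"n_keep={n_keep} exceeds p={data.p}")
    ranksum = np.zeros(data.p)
    for st in data.studies:
        for crit in (st.X.mean(axis=0), st.X.var(axis=0, ddof=1)):
            ranksum += stats.rankdata(-crit, method="average")
    order = sorted(range(data.p), key=lambda j: (ranksum[j], data.feature_names[j]))
    keep = np.array(sorted(order[:n_keep]))
    studies = [
        StudyData(st.X[:, keep], st.y, name=st.name, sample_ids=st.sample_ids)
        for st in data.studies
    ]
    return MetaDataset(studies, [data.feature_names[j] for j in keep])
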