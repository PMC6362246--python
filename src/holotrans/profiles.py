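"""Expression-profile clustering and retention rules.

Stage-expression profiles (log2(TPM+1), median-centered per gene) are
clustered hierarchically with correlation distance (1 - Pearson r) under
average linkage; the tree is cut at a fraction of the maximum merge height
set by the profile-matching threshold (default 80%).  Clusters with near-
identical mean profiles are then merged automatically (replacing the
manual combining step of the original workflow), and only clusters
containing at least one transcription factor and more than 20
GO-annotated members are retained.  TF "predominance" at a stage means a
TPM more than three times the stage mean over all TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def normalize_profiles(tpm: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM+1), median-centered within each gene."""
    lg = np.log2(tpm + 1.0)
    return lg.sub(lg.median(axis=1), axis=0)


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 - Pearson r between profile rows; zero-variance rows get distance 1.

    Distances are clipped to [0, 2]; the diagonal is 0.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0  # zero-variance convention
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


@dataclass
class ProfileClusterSet:
    """A partition of genes into profile clusters with per-cluster means."""

    clusters: Dict[int, List[str]]
    mean_profiles: pd.DataFrame  # cluster id x stages
    retained: Dict[int, bool] = field(default_factory=dict)

    def members(self) -> List[str]:
        return sorted(g for ms in self.clusters.values() for g in ms)


def _mean_profiles(
    profiles: pd.DataFrame, clusters: Dict[int, List[str]]
) -> pd.DataFrame:
    rows = {cid: profiles.loc[ms].mean(axis=0) for cid, ms in clusters.items()}
    return pd.DataFrame(rows).T


def cluster_profiles(
    profiles: pd.DataFrame,
    match_threshold: float = 0.80,
    interpretation: str = "tree_height",
) -> ProfileClusterSet:
    """Average-linkage clustering of profiles with correlation distance.

    ``interpretation`` selects how the matching threshold is applied:
    'tree_height' cuts the dendrogram at (1 - threshold) x maximum merge
    height; 'correlation_floor' cuts at distance 1 - threshold directly
    (a minimum-correlation reading of the same parameter).
    """
    if profiles.empty:
        raise ValueError("need at least one profile")
    if profiles.shape[1] < 2:
        raise ValueError("need at least two stages")
    profiles = profiles.sort_index()
    genes = list(profiles.index)
    if len(genes) == 1:
        cl = {1: genes}
        return ProfileClusterSet(cl, _mean_profiles(profiles, cl), {1: True})
    dist = _correlation_distance(profiles.to_numpy(dtype=float))
    z = linkage(squareform(dist, checks=False), method="average")
    max_h = float(z[:, 2].max())
    if interpretation == "tree_height":
        cut = (1.0 - match_threshold) * max_h
    elif interpretation == "correlation_floor":
        cut = 1.0 - match_threshold
    else:
        raise ValueError(f"unknown interpretation {interpretation!r}")
    labels = fcluster(z, t=cut, criterion="distance")
    clusters: Dict[int, List[str]] = {}
    for g, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(g)
    # renumber deterministically by smallest member gene id
    order = sorted(clusters, key=lambda c: min(clusters[c]))
    clusters = {i + 1: sorted(clusters[c]) for i, c in enumerate(order)}
    return ProfileClusterSet(
        clusters, _mean_profiles(profiles, clusters), {c: True for c in clusters}
    )


def merge_similar_clusters(
    cs: ProfileClusterSet, r_min: float = 0.90
) -> ProfileClusterSet:
    """Greedily merge the most-correlated pair of cluster means while r >= r_min."""
    clusters = {c: list(ms) for c, ms in cs.clusters.items()}
    means = cs.mean_profiles.copy()
    while len(clusters) > 1:
        ids = sorted(clusters)
        corr = np.corrcoef(means.loc[ids].to_numpy(dtype=float))
        corr = np.atleast_2d(corr)
        corr[~np.isfinite(corr)] = 0.0
        best = None  # (r, i, j)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                r = corr[a, b]
                if r >= r_min and (best is None or r > best[0]):
                    best = (r, ids[a], ids[b])
        if best is None:
            break
        _, i, j = best
        ni, nj = len(clusters[i]), len(clusters[j])
        merged_mean = (means.loc[i] * ni + means.loc[j] * nj) / (ni + nj)
        clusters[i] = sorted(clusters[i] + clusters.pop(j))
        means = means.drop(index=j)
        means.loc[i] = merged_mean
    order = sorted(clusters, key=lambda c: min(clusters[c]))
    renumbered = {k + 1: clusters[c] for k, c in enumerate(order)}
    new_means = pd.DataFrame(
        {k + 1: means.loc[c] for k, c in enumerate(order)}
    ).T
    return ProfileClusterSet(renumbered, new_means, {c: True for c in renumbered})


def retain_clusters(
    cs: ProfileClusterSet, tf_ids: Set[str], go_annotated: Set[str]
) -> ProfileClusterSet:
    """Flag clusters with >= 1 TF member and > 20 GO-annotated members.

    Retention only flags clusters; the partition is unchanged.
    """
    retained = {
        cid: len(set(ms) & tf_ids) >= 1 and len(set(ms) & go_annotated) > 20
        for cid, ms in cs.clusters.items()
    }
    return ProfileClusterSet(cs.clusters, cs.mean_profiles, retained)


def select_predominant_tfs(
    tf_tpm: pd.DataFrame, multiple: float = 3.0
) -> Dict[str, List[str]]:
    """Per stage: TFs with TPM strictly above multiple x the stage mean over TFs."""
    if tf_tpm.empty:
        return {}
    out: Dict[str, List[str]] = {}
    for stage in tf_tpm.columns:
        mean = float(tf_tpm[stage].mean())
        sel = tf_tpm.index[tf_tpm[stage] > multiple * mean]
        out[stage] = sorted(sel)
    return out
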