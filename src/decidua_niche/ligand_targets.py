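"""Selection of genes that spatially track a cell subset's distribution.

Feeds upstream-ligand prediction: for every candidate gene the maximal
information coefficient (MIC) between its spot expression and the subset's
distribution probability is computed; genes with MIC >= 0.9 go into
spatial-expression clustering (average linkage on 1 - Pearson correlation
of spot profiles, 2-6 clusters chosen by silhouette), and only the
cluster(s) whose mean profile correlates positively with the subset
probability are retained.  Also provides the direct subset-gene Pearson
correlation used for single-gene spatial association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .core_io import CellTypeProbabilities, GeneMatrix
from .lr import _pearson_with_p
from .mic import mic

__all__ = ["MICSelection", "select_tracking_genes", "subset_gene_correlation"]


@dataclass
class MICSelection:
    """Outcome of the MIC screen and positive-cluster filter."""

    table: pd.DataFrame  # index gene; columns mic, selected, cluster, cluster_sign, retained

    @property
    def retained_genes(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def select_tracking_genes(expr: GeneMatrix, subset_prob: np.ndarray,
                          candidates: list[str], mic_min: float = 0.9,
                          max_clusters: int = 6, alpha: float = 0.6,
                          c: int = 15) -> MICSelection:
    """MIC screen plus spatial clustering with a positive-correlation filter.

    ``subset_prob`` is the per-spot distribution probability of the tracked
    subset, aligned to ``expr`` rows.  Genes never observed in the matrix
    raise; an empty selection is a valid outcome.
    """
    subset_prob = np.asarray(subset_prob, dtype=float)
    if subset_prob.size != expr.n_spots:
        raise ValueError("subset probability must align with expression spots")
    missing = [g for g in candidates if g not in set(expr.genes)]
    if missing:
        raise KeyError(f"candidate genes absent from expression matrix: {missing[:5]}")
    mic_scores = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes legitimately score 0
        for g in candidates:
            mic_scores[g] = mic(expr.gene_values(g), subset_prob, alpha=alpha, c=c)
    table = pd.DataFrame({"mic": pd.Series(mic_scores)})
    table.index.name = "gene"
    table["selected"] = table["mic"] >= mic_min
    table["cluster"] = -1
    table["cluster_sign"] = 0.0
    table["retained"] = False
    kept = list(table.index[table["selected"]])
    if not kept:
        return MICSelection(table=table)
    profiles = np.stack([expr.gene_values(g) for g in kept])
    clusters = _cluster_profiles(profiles, max_clusters=max_clusters)
    table.loc[kept, "cluster"] = clusters
    for cl in np.unique(clusters):
        members = [g for g, c_ in zip(kept, clusters) if c_ == cl]
        mean_profile = profiles[clusters == cl].mean(axis=0)
        r, _ = _pearson_with_p(mean_profile, subset_prob)
        table.loc[members, "cluster_sign"] = r
        if r > 0:
            table.loc[members, "retained"] = True
    return MICSelection(table=table)


def _cluster_profiles(profiles: np.ndarray, max_clusters: int = 6) -> np.ndarray:
    """Average-linkage clustering on 1 - Pearson correlation of profiles.

    The cluster count in 2..max_clusters is chosen by silhouette on the
    same distance; degenerate cases (fewer than 3 profiles, or zero
    spread) collapse to a single cluster.
    """
    k = profiles.shape[0]
    if k == 1:
        return np.zeros(1, dtype=int)
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if k == 2:
        return hierarchy.fcluster(linkage, t=2, criterion="maxclust") - 1
    best_labels = None
    best_score = -np.inf
    for n_cl in range(2, min(max_clusters, k - 1) + 1):
        labels = hierarchy.fcluster(linkage, t=n_cl, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        if score > best_score:
            best_score, best_labels = score, labels
    if best_labels is None:
        return np.zeros(k, dtype=int)
    return best_labels


def subset_gene_correlation(probs: CellTypeProbabilities, expr: GeneMatrix,
                            subset: str, gene: str) -> tuple[float, float]:
    """Pearson r (with two-sided P) between a subset's spatial distribution
    probability and a gene's spot expression."""
    if list(probs.spot_ids) != list(expr.spot_ids):
        raise ValueError("probabilities and expression must list the same spots")
    p = probs.column(subset)
    g = expr.gene_values(gene)
    if p.std() == 0 or g.std() == 0:
        warnings.warn("zero variance; correlation reported as 0 with P = 1", stacklevel=2)
        return 0.0, 1.0
    return _pearson_with_p(p, g)
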