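"""Phi-coefficient correlation of binary outlier profiles, graph pruning and
PCA-based cluster reporting.

The phi coefficient of two binary vectors is the Pearson correlation computed
from their 2x2 contingency table; genes whose outlier profiles are tightly
phi-correlated mark candidate co-amplified regions or co-regulated pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass(frozen=True)
class PruneConfig:
    """Threshold tau on phi and the minimum degree a gene must keep.

    tau is a calibration default (planted blocks in the synthetic cohort
    separate at 0.30), not a literature value.
    """

    tau: float = 0.30
    min_degree: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must be in (0, 1)")
        if self.min_degree < 0:
            raise ValueError("min_degree must be >= 0")


@dataclass
class GeneClusterSet:
    """Connected-component clusters with prognosis labels and PCA coordinates."""

    clusters: dict[int, list[str]]
    prognosis: dict[int, str]  # cluster id -> {good, poor}
    coordinates: pd.DataFrame  # gene -> PC1, PC2, cluster


def phi_matrix(b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise phi coefficients between the rows of a binary matrix.

    phi = (n11*n00 - n10*n01) / sqrt(r1*r0*c1*c0) from the 2x2 contingency
    table of each row pair; identical to the Pearson correlation of the rows.
    Rows must be non-constant (each needs at least one 0 and one 1).
    """
    x = b.to_numpy(dtype=float)
    n = x.shape[1]
    ones = x.sum(axis=1)
    constant = (ones == 0) | (ones == n)
    if constant.any():
        raise ValueError(f"constant rows: {b.index[constant].tolist()}")
    n11 = x @ x.T
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = n - n11 - n10 - n01
    r1 = ones[:, None]
    r0 = n - r1
    c1 = ones[None, :]
    c0 = n - c1
    phi = (n11 * n00 - n10 * n01) / np.sqrt(r1 * r0 * c1 * c0)
    np.fill_diagonal(phi, 1.0)
    return pd.DataFrame(phi, index=b.index, columns=b.index)


def prune_correlation_graph(r: pd.DataFrame, config: PruneConfig | None = None) -> list[str]:
    """Iteratively remove weakly connected genes from the phi graph.

    The matrix is thresholded at tau into an adjacency graph (edge iff
    phi >= tau, i != j); while any gene has degree below min_degree, the gene
    of smallest degree is removed (ties broken by gene id) and degrees
    recomputed, until the retained set is stable. May return an empty list.
    """
    config = config or PruneConfig()
    if r.shape[0] == 0:
        return []
    genes = list(r.index)
    adj = (r.to_numpy() >= config.tau)
    np.fill_diagonal(adj, False)
    alive = np.ones(len(genes), dtype=bool)
    degree = adj.sum(axis=1)
    while True:
        low = alive & (degree < config.min_degree)
        if not low.any():
            break
        # smallest degree, tie-break on gene id
        cand = np.flatnonzero(low)
        cand = cand[degree[cand] == degree[cand].min()]
        victim = min(cand, key=lambda i: genes[i])
        alive[victim] = False
        degree = degree - adj[:, victim]
        degree[victim] = 0
        adj[victim, :] = False
        adj[:, victim] = False
    return [g for g, a in zip(genes, alive) if a]


def pca_clusters(
    b: pd.DataFrame,
    hr_direction: pd.Series | None = None,
    config: PruneConfig | None = None,
) -> GeneClusterSet:
    """Cluster retained genes and compute their 2-D PCA projection.

    Genes are observations and samples variables; each sample column is
    mean-centred and genes are projected onto the first two principal axes.
    Cluster membership is the connected components of the tau-thresholded phi
    graph (the programmatic equivalent of circling PCA groups by eye). A
    cluster is labelled "poor" when the majority of its members carry hazard
    ratio > 1 in ``hr_direction`` (a gene -> HR series), else "good".
    """
    config = config or PruneConfig()
    if b.shape[0] < 2:
        raise ValueError("need at least 2 genes for PCA clustering")
    x = b.to_numpy(dtype=float)
    centred = x - x.mean(axis=0, keepdims=True)
    # SVD of the gene x sample matrix; scores = projections on right singular axes
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    coords = u[:, :2] * s[:2]
    phi = phi_matrix(b)
    adj = csr_matrix((phi.to_numpy() >= config.tau))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[str]] = {}
    for gene, lab in zip(b.index, labels):
        clusters.setdefault(int(lab), []).append(gene)
    prognosis: dict[int, str] = {}
    for cid, members in clusters.items():
        if hr_direction is None:
            prognosis[cid] = "unknown"
        else:
            hrs = hr_direction.reindex(members).dropna()
            n_poor = int((hrs > 1).sum())
            prognosis[cid] = "poor" if n_poor * 2 > len(hrs) else "good"
    coordinates = pd.DataFrame(
        {"PC1": coords[:, 0], "PC2": coords[:, 1], "cluster": labels}, index=b.index
    )
    return GeneClusterSet(clusters=clusters, prognosis=prognosis, coordinates=coordinates)
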