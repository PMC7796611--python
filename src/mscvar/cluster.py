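"""Sample grouping: PCA on HVG expression, shared-nearest-neighbor graph,
Louvain community detection.

The SNN construction reproduces the contract of the Seurat workflow it
emulates: each sample's neighbor set is its k nearest (Euclidean in the
first ``n_pcs`` principal components, the sample itself included), edge
weights are Jaccard overlaps of neighbor sets, and edges below the prune
threshold (1/15 by default) are dropped.  Community detection maximizes
Reichardt-Bornholdt modularity with a resolution parameter (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError

DEFAULT_K = 10
DEFAULT_N_PCS = 10
DEFAULT_RESOLUTION = 2.0
DEFAULT_PRUNE = 1.0 / 15.0


@dataclass(frozen=True)
class Embedding:
    """PCA embedding: samples x components scores, variances, loadings."""

    coords: pd.DataFrame          # samples x PC1..PCn
    explained_variance: pd.Series  # per component
    loadings: pd.DataFrame         # genes x components

    @property
    def sample_ids(self) -> list[str]:
        return self.coords.index.tolist()


@dataclass(frozen=True)
class ClusterResult:
    labels: pd.Series      # sample_id -> cluster int (0-based, size-ordered)
    modularity: float
    parameters: dict = field(default_factory=dict)


def pca(em: ExpressionMatrix, genes: list[str] | None = None,
        n_pcs: int | None = None) -> Embedding:
    """Column-centered, unscaled PCA of samples over the given genes.

    Computed by SVD; component signs are canonicalized so each loading
    vector's largest-magnitude entry is positive.
    """
    values = em.values
    if genes is not None:
        missing = set(genes) - set(values.index)
        if missing:
            raise ValidationError(f"genes absent from matrix: {sorted(missing)[:5]}")
        values = values.loc[genes]
    X = values.to_numpy(dtype=float).T  # samples x genes
    n_samples, n_genes = X.shape
    max_pcs = min(n_samples, n_genes)
    if n_pcs is None:
        n_pcs = max_pcs
    if n_pcs > max_pcs:
        raise ValidationError(f"n_pcs={n_pcs} exceeds admissible maximum {max_pcs}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :n_pcs] * S[:n_pcs]
    var = S**2 / max(n_samples - 1, 1)
    pcs = [f"PC{i + 1}" for i in range(n_pcs)]
    return Embedding(
        coords=pd.DataFrame(scores, index=values.columns, columns=pcs),
        explained_variance=pd.Series(var[:n_pcs], index=pcs),
        loadings=pd.DataFrame(Vt[:n_pcs].T, index=values.index, columns=pcs),
    )


def snn_graph(
    emb: Embedding,
    k: int = DEFAULT_K,
    n_pcs: int = DEFAULT_N_PCS,
    prune: float = DEFAULT_PRUNE,
) -> nx.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Neighbor sets have size k and include the sample itself; ties in
    distance are broken by sample order for determinism.
    """
    coords = emb.coords.to_numpy(dtype=float)[:, : min(n_pcs, emb.coords.shape[1])]
    n = coords.shape[0]
    if n <= k:
        raise ValidationError(f"need more than k={k} samples, got {n}; reduce k")
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    # argsort on (distance, index) for deterministic ties; self has distance 0
    neighbor_sets = []
    for i in range(n):
        order = np.lexsort((np.arange(n), d2[i]))
        neighbor_sets.append(frozenset(order[:k].tolist()))
    g = nx.Graph()
    ids = emb.sample_ids
    g.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            if inter == 0:
                continue
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w >= prune:
                g.add_edge(ids[i], ids[j], weight=w)
    return g


def louvain_cluster(
    graph: nx.Graph,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 1,
) -> ClusterResult:
    """Louvain community detection on the SNN graph.

    Deterministic for a given seed; labels are consecutive integers from
    0 ordered by decreasing community size (ties by smallest member).
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    nodes = sorted(graph.nodes())
    canonical = nx.Graph()
    canonical.add_nodes_from(nodes)
    canonical.add_edges_from(
        (u, v, d) for u, v, d in graph.edges(data=True)
    )
    comms = nx.community.louvain_communities(
        canonical, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = {}
    for lab, comm in enumerate(comms):
        for node in comm:
            labels[node] = lab
    q = nx.community.modularity(
        canonical, comms, weight="weight", resolution=resolution
    )
    return ClusterResult(
        labels=pd.Series(labels, name="cluster").loc[nodes].rename_axis("sample_id"),
        modularity=float(q),
        parameters={"resolution": resolution, "seed": seed},
    )


def cluster_samples(
    em: ExpressionMatrix,
    hvgs: list[str],
    k: int = DEFAULT_K,
    n_pcs: int = DEFAULT_N_PCS,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 1,
    prune: float = DEFAULT_PRUNE,
) -> tuple[Embedding, ClusterResult]:
    """HVG expression -> PCA -> SNN -> Louvain, the full grouping chain."""
    n_pcs_eff = min(n_pcs, len(em.sample_ids), len(hvgs))
    emb = pca(em, genes=hvgs, n_pcs=n_pcs_eff)
    graph = snn_graph(emb, k=k, n_pcs=n_pcs_eff, prune=prune)
    result = louvain_cluster(graph, resolution=resolution, seed=seed)
    params = dict(result.parameters)
    params.update({"k": k, "n_pcs": n_pcs_eff})
    return emb, ClusterResult(result.labels, result.modularity, params)
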