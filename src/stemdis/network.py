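"""Confidence-filtered protein-interaction networks: hubs and clusters.

The network stage mirrors a STRING-style workflow: restrict a scored edge
list to a gene set of interest, keep only edges whose combined confidence
strictly exceeds a floor (default 0.9, the "highest confidence" setting),
extract the largest connected component, flag hub proteins (degree strictly
greater than five by default), and partition the component by spectral
embedding + k-means.

Clustering embeds nodes with the k smallest nontrivial eigenvectors of the
confidence-weighted symmetric normalized Laplacian and runs k-means with a
fixed seed and 10 restarts, so assignments are deterministic for fixed
inputs.  Disconnected graphs are clustered per component, with k apportioned
to components by size (largest-remainder, at least one cluster each).
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.linalg import eigh
from sklearn.cluster import KMeans

__all__ = [
    "read_edges",
    "write_edges",
    "build_network",
    "largest_component",
    "hubs",
    "cluster",
]

MIN_CONFIDENCE_DEFAULT = 0.9
HUB_MIN_LINKS_DEFAULT = 5


def read_edges(path) -> list[tuple[str, str, float]]:
    """Read a (nodeA, nodeB, confidence) TSV; '#' lines are comments."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                conf = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad confidence {parts[2]!r}") from exc
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"{path}:{lineno}: confidence outside [0, 1]")
            edges.append((parts[0], parts[1], conf))
    return edges


def write_edges(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b, c in edges:
            fh.write(f"{a}\t{b}\t{c:.3f}\n")


def build_network(
    edges: list[tuple[str, str, float]],
    gene_set: list[str] | set[str],
    min_confidence: float = MIN_CONFIDENCE_DEFAULT,
) -> nx.Graph:
    """Induced network over ``gene_set`` keeping edges with confidence
    strictly above ``min_confidence``.

    Duplicate/reversed edges are merged keeping the maximum confidence;
    self-loops are dropped.  Nodes from ``gene_set`` with no surviving edge
    are kept as isolates so component extraction sees the full gene set.
    """
    genes = set(gene_set)
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for a, b, conf in edges:
        if a == b or a not in genes or b not in genes:
            continue
        if conf <= min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    return g


def largest_component(graph: nx.Graph) -> nx.Graph:
    """Subgraph induced by the largest connected component.

    Size ties break toward the component containing the lexicographically
    smallest node.  An empty graph yields an empty graph.
    """
    if graph.number_of_nodes() == 0:
        return graph.copy()
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    return graph.subgraph(comps[0]).copy()


def hubs(graph: nx.Graph, min_links: int = HUB_MIN_LINKS_DEFAULT) -> list[str]:
    """Nodes with degree strictly greater than ``min_links`` (default 5)."""
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    return sorted(n for n, d in graph.degree() if d > min_links)


def _spectral_kmeans(graph: nx.Graph, k: int, seed: int) -> dict[str, int]:
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if k == 1 or n == 1:
        return {v: 0 for v in nodes}
    lap = nx.normalized_laplacian_matrix(graph, nodelist=nodes, weight="confidence")
    vals, vecs = eigh(np.asarray(lap.todense()))
    # skip the trivial (near-zero) eigenvector of each connected component
    emb = vecs[:, 1 : k + 1]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    return {v: int(l) for v, l in zip(nodes, labels)}


def cluster(graph: nx.Graph, k: int, seed: int = 0) -> dict[str, int]:
    """Partition nodes into ``k`` clusters by spectral embedding + k-means.

    Disconnected graphs are clustered per connected component with k shared
    out proportionally to component size (every component gets at least one
    cluster); cluster ids are globally unique across components.
    """
    n = graph.number_of_nodes()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds node count {n}")
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    if len(comps) > k:
        raise ValueError(
            f"graph has {len(comps)} components but k={k}; "
            "cluster the largest component or raise k"
        )
    # largest-remainder apportionment of k over components, floor 1 each
    sizes = np.array([len(c) for c in comps], dtype=float)
    quota = sizes / sizes.sum() * k
    alloc = np.maximum(np.floor(quota).astype(int), 1)
    alloc = np.minimum(alloc, sizes.astype(int))
    while alloc.sum() < k:
        rem = np.where(alloc < sizes, quota - alloc, -np.inf)
        alloc[int(np.argmax(rem))] += 1
    while alloc.sum() > k:
        rem = np.where(alloc > 1, quota - alloc, np.inf)
        alloc[int(np.argmin(rem))] -= 1
    assignment: dict[str, int] = {}
    offset = 0
    for comp, kc in zip(comps, alloc):
        sub = graph.subgraph(comp)
        local = _spectral_kmeans(sub, int(kc), seed)
        for v, l in local.items():
            assignment[v] = l + offset
        offset += int(kc)
    return assignment
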