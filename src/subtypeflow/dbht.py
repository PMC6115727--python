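"""Correlation-network clustering: PMFG construction and DBHT extraction.

Samples are vertices of a planar maximally filtered graph (PMFG): edges are
considered in decreasing Pearson similarity and kept whenever the graph
stays planar, stopping at the 3(N-2) edges of a planar triangulation.  The
directed bubble hierarchical tree (DBHT) then reads a parameter-free flat
clustering plus intra-/inter-cluster hierarchies off the PMFG's clique-3
(bubble) decomposition:

1. decompose the triangulation into *bubbles* -- maximal pieces containing
   no separating 3-clique -- which, glued along their separating 3-cliques,
   form the bubble tree;
2. direct each bubble-tree edge toward the bubble into which the shared
   3-clique is more strongly attached (more edges from the clique to the
   bubble's remaining vertices);
3. bubbles with no outgoing direction ("converging" bubbles) seed the
   clusters; every other vertex is attached to the cluster it is most
   strongly connected to, growing outward from the seeds;
4. complete linkage on the dissimilarity matrix within clusters (intra
   hierarchy) and between clusters (inter hierarchy) is merged into a
   single N-1-merge dendrogram whose cut at the inter-cluster level
   reproduces the flat labels.

Tie-breaking rules are deterministic throughout (documented inline); with
generic real-valued similarities they never fire.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


class ZeroVarianceError(ValueError):
    """A sample column has zero variance, so Pearson correlation is undefined."""


def pearson_similarity(X: np.ndarray, sample_ids=None) -> np.ndarray:
    """Pearson correlation matrix between the columns of ``X`` (P x N)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    sd = X.std(axis=0)
    bad = np.nonzero(sd == 0.0)[0]
    if bad.size:
        name = sample_ids[bad[0]] if sample_ids is not None else f"column {bad[0]}"
        raise ZeroVarianceError(f"sample {name} has zero variance across genes")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def dissimilarity(r: np.ndarray, mode: str = "printed") -> np.ndarray:
    """Distance from correlation: ``2 (1 - r)`` (``mode="printed"``, the
    default) or the metric variant ``sqrt(2 (1 - r))`` (``mode="sqrt"``).
    Both are strictly decreasing in ``r``, so the PMFG edge order and the
    linkage topology are identical; only merge heights differ."""
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.abs(r).max() > 1.0 + 1e-9:
        raise ValueError("similarity entries must lie in [-1, 1]")
    d = 2.0 * (1.0 - np.clip(r, -1.0, 1.0))
    if mode == "sqrt":
        d = np.sqrt(d)
    elif mode != "printed":
        raise ValueError(f"unknown dissimilarity mode: {mode!r}")
    np.fill_diagonal(d, 0.0)
    return d


def sorted_candidate_edges(r: np.ndarray):
    """All vertex pairs in decreasing similarity; equal similarities are
    ordered lexicographically by (min index, max index) for determinism."""
    N = r.shape[0]
    iu, ju = np.triu_indices(N, k=1)
    order = np.lexsort((ju, iu, -r[iu, ju]))
    return list(zip(iu[order], ju[order], r[iu, ju][order]))


def build_pmfg(r: np.ndarray) -> nx.Graph:
    """Greedy planarity-filtered graph: returns a connected planar graph
    with exactly ``3 (N - 2)`` edges; edge attribute ``weight`` stores the
    similarity."""
    r = np.asarray(r, dtype=float)
    N = r.shape[0]
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("similarity matrix must be square")
    if N < 3:
        raise ValueError(f"PMFG needs at least 3 vertices, got {N}")
    target = 3 * (N - 2)
    g = nx.Graph()
    g.add_nodes_from(range(N))
    for i, j, w in sorted_candidate_edges(r):
        g.add_edge(int(i), int(j), weight=float(w))
        ok, _ = nx.check_planarity(g, counterexample=False)
        if not ok:
            g.remove_edge(int(i), int(j))
        elif g.number_of_edges() == target:
            break
    return g


# ---------------------------------------------------------------------------
# bubble (clique-3) decomposition


def _triangles(g: nx.Graph):
    out = []
    nodes = sorted(g.nodes())
    adj = {u: set(g[u]) for u in nodes}
    for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges())):
        for w in sorted(adj[u] & adj[v]):
            if w > v:
                out.append((u, v, w))
    return out


def _separating_triangle(g: nx.Graph):
    """First (lexicographically) 3-clique whose removal disconnects g."""
    if g.number_of_nodes() <= 4:
        return None
    for tri in _triangles(g):
        h = g.copy()
        h.remove_nodes_from(tri)
        if h.number_of_nodes() and not nx.is_connected(h):
            return tri
    return None


def bubble_decomposition(g: nx.Graph) -> list[frozenset]:
    """Maximal subgraph pieces containing no separating 3-clique, obtained
    by recursively splitting on separating 3-cliques (each separator is
    kept in every piece it borders).  The pieces are the DBHT bubbles."""
    out: list[frozenset] = []
    stack = [g]
    while stack:
        h = stack.pop()
        tri = _separating_triangle(h)
        if tri is None:
            out.append(frozenset(h.nodes()))
            continue
        rest = h.copy()
        rest.remove_nodes_from(tri)
        for comp in nx.connected_components(rest):
            stack.append(h.subgraph(comp | set(tri)).copy())
    # sort for determinism: by size descending, then by sorted member tuple
    return sorted(set(out), key=lambda b: (-len(b), tuple(sorted(b))))


def _bubble_tree_edges(g: nx.Graph, bubbles: list[frozenset]):
    """Adjacencies between bubbles: pairs sharing a 3-clique of g."""
    edges = []
    for (i, bi), (j, bj) in itertools.combinations(enumerate(bubbles), 2):
        shared = bi & bj
        if len(shared) == 3:
            tri = tuple(sorted(shared))
            if g.has_edge(tri[0], tri[1]) and g.has_edge(tri[0], tri[2]) and g.has_edge(tri[1], tri[2]):
                edges.append((i, j, tri))
    return edges


def converging_bubbles(g: nx.Graph, bubbles: list[frozenset], r: np.ndarray) -> list[int]:
    """Indices of bubbles with no outgoing edge in the directed bubble tree.

    Each bubble-tree edge is directed by where its separating 3-clique is
    more strongly attached: removing the edge splits the bubble tree into
    two sides, and the edge points toward the side whose vertices carry
    the larger total positive similarity to the clique's three vertices.
    Aggregating attachment over whole sides (rather than the two incident
    bubbles alone) makes the arrows funnel consistently toward the
    similarity centroid of each dense region, so one converging bubble
    emerges per tightly-correlated block instead of one per local
    tie-break accident.  Ties go to the side with more vertices, then to
    the side containing the smaller bubble index."""
    edges = _bubble_tree_edges(g, bubbles)
    tree = nx.Graph()
    tree.add_nodes_from(range(len(bubbles)))
    for i, j, _tri in edges:
        tree.add_edge(i, j)
    pos_r = np.maximum(np.asarray(r, dtype=float), 0.0)
    outgoing = [0] * len(bubbles)
    for i, j, tri in edges:
        h = tree.copy()
        h.remove_edge(i, j)
        side_i = nx.node_connected_component(h, i)
        if j in side_i:      # adjacency cycle (several bubbles on one clique):
            side_i = {i}     # fall back to the two incident bubbles
            side_j = {j}
        else:
            side_j = nx.node_connected_component(h, j)
        tri_set = set(tri)

        def mass(side):
            verts = set().union(*(bubbles[b] for b in side)) - tri_set
            if not verts:
                return 0.0, 0
            vs = np.fromiter(verts, dtype=int, count=len(verts))
            return float(pos_r[np.ix_(list(tri), vs)].sum()), len(verts)

        mi, ni = mass(side_i)
        mj, nj = mass(side_j)
        ki = (mi, ni, -min(side_i))
        kj = (mj, nj, -min(side_j))
        if ki > kj:
            outgoing[j] += 1
        else:
            outgoing[i] += 1
    conv = [b for b, o in enumerate(outgoing) if o == 0]
    if not conv:  # cannot happen for a tree; guard for degenerate adjacency
        conv = [0]
    return conv


@dataclass
class DBHTResult:
    """Flat clusters plus the merged intra-/inter-cluster dendrogram.

    ``labels`` are 1-based cluster ids; ``linkage`` is a standard scipy
    (N-1) x 4 merge list whose cut at ``cut_height`` reproduces ``labels``;
    ``bubble_membership`` maps each vertex to the bubble that claimed it.
    """

    labels: np.ndarray
    n_clusters: int
    bubble_membership: np.ndarray
    bubbles: list[frozenset]
    converging: list[int]
    linkage: np.ndarray
    cut_height: float


def dbht_cluster(g: nx.Graph, d: np.ndarray, r: np.ndarray | None = None) -> DBHTResult:
    """Extract the DBHT clustering of PMFG ``g`` with dissimilarity ``d``.

    ``r`` is the similarity matrix used for the attachment mass that
    directs the bubble tree; if omitted it is recovered from the printed
    dissimilarity transform as ``1 - d/2``.
    """
    N = g.number_of_nodes()
    d = np.asarray(d, dtype=float)
    if d.shape != (N, N):
        raise ValueError("dissimilarity matrix does not match the graph")
    if not nx.is_connected(g):
        raise ValueError("graph must be connected (a PMFG is by construction)")
    if r is None:
        r = 1.0 - d / 2.0

    bubbles = bubble_decomposition(g)
    conv = converging_bubbles(g, bubbles, r)

    # seeds: vertices lying in exactly one converging bubble
    labels = np.zeros(N, dtype=int)          # 0 = unassigned
    bubble_member = np.full(N, -1, dtype=int)
    vertex_conv = {v: [] for v in range(N)}
    for rank, bi in enumerate(conv):
        for v in bubbles[bi]:
            vertex_conv[v].append((rank, bi))
    for v in range(N):
        if len(vertex_conv[v]) == 1:
            rank, bi = vertex_conv[v][0]
            labels[v] = rank + 1
            bubble_member[v] = bi

    def scores(v: int, assigned: np.ndarray):
        # attachment = total positive similarity to the cluster (primary),
        # then edge count; feeble cross-links cannot outvote one strong tie
        sc = {}
        for u in g[v]:
            c = assigned[u]
            if c:
                wt, cnt = sc.get(c, (0.0, 0))
                sc[c] = (wt + max(g[v][u].get("weight", 1.0), 0.0), cnt + 1)
        return sc

    # vertices in several converging bubbles: strongest direct attachment
    for v in range(N):
        if len(vertex_conv[v]) > 1:
            sc = scores(v, labels)
            cands = [(sc.get(rank + 1, (0.0, 0)), -(rank + 1)) for rank, _ in vertex_conv[v]]
            best = max(cands)
            labels[v] = -best[1]
            bubble_member[v] = dict((rank + 1, bi) for rank, bi in vertex_conv[v])[-best[1]]

    # remaining vertices: grow clusters outward, strongest attachment first;
    # ties resolved toward the smaller cluster index
    while np.any(labels == 0):
        pending = [v for v in range(N) if labels[v] == 0]
        best_pick = None
        for v in pending:
            sc = scores(v, labels)
            for c, (wt, cnt) in sc.items():
                key = (wt, cnt, -c, -v)
                if best_pick is None or key > best_pick[0]:
                    best_pick = (key, v, c)
        if best_pick is None:  # disconnected leftovers cannot occur (connected g)
            raise RuntimeError("unassignable vertices in a connected graph")
        _, v, c = best_pick
        labels[v] = c

    n_clusters = len(conv)
    # relabel clusters in first-appearance order of sorted vertex index
    remap, nxt = {}, 1
    for v in range(N):
        c = labels[v]
        if c not in remap:
            remap[c] = nxt
            nxt += 1
    labels = np.array([remap[c] for c in labels])

    # merged dendrogram: complete linkage on d, with an offset added to
    # cross-cluster distances so intra merges happen first and cutting at
    # the offset reproduces the flat labels
    offset = float(d.max()) + 1.0
    dprime = d.copy()
    cross = labels[:, None] != labels[None, :]
    dprime[cross] += offset
    np.fill_diagonal(dprime, 0.0)
    Z = linkage(squareform(dprime, checks=False), method="complete")

    return DBHTResult(
        labels=labels,
        n_clusters=n_clusters,
        bubble_membership=bubble_member,
        bubbles=bubbles,
        converging=conv,
        linkage=Z,
        cut_height=offset,
    )


def cluster_samples(X: np.ndarray, sample_ids=None, mode: str = "printed") -> DBHTResult:
    """Convenience front door: Pearson similarity -> PMFG -> DBHT for a
    genes x samples matrix (for instance the sparse component of a BRPCA
    decomposition)."""
    r = pearson_similarity(X, sample_ids=sample_ids)
    g = build_pmfg(r)
    d = dissimilarity(r, mode=mode)
    return dbht_cluster(g, d, r=r)
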