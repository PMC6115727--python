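"""Independent oracles used only by the test suite.

Each is a deliberately naive, brute-force implementation kept separate from
the package code paths it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


# --- planarity by Wagner's theorem (K5 / K3,3 minors), for tiny graphs ----

def _has_k5_minor(g: nx.Graph) -> bool:
    def clique5(h):
        for nodes in itertools.combinations(h.nodes(), 5):
            if all(h.has_edge(a, b) for a, b in itertools.combinations(nodes, 2)):
                return True
        return False

    def search(h, budget):
        if h.number_of_nodes() >= 5 and clique5(h):
            return True
        if budget == 0:
            return False
        for u, v in list(h.edges()):
            h2 = nx.contracted_nodes(h, u, v, self_loops=False)
            if search(h2, budget - 1):
                return True
        return False

    return search(g, max(g.number_of_nodes() - 5, 0))


def _has_k33_minor(g: nx.Graph) -> bool:
    def k33(h):
        nodes = list(h.nodes())
        for left in itertools.combinations(nodes, 3):
            rest = [n for n in nodes if n not in left]
            for right in itertools.combinations(rest, 3):
                if all(h.has_edge(a, b) for a in left for b in right):
                    return True
        return False

    def search(h, budget):
        if h.number_of_nodes() >= 6 and k33(h):
            return True
        if budget == 0:
            return False
        for u, v in list(h.edges()):
            h2 = nx.contracted_nodes(h, u, v, self_loops=False)
            if search(h2, budget - 1):
                return True
        return False

    return search(g, max(g.number_of_nodes() - 6, 0))


def is_planar_minor(g: nx.Graph) -> bool:
    """Planarity for graphs with <= 8 vertices via forbidden minors."""
    n = g.number_of_nodes()
    assert n <= 8, "minor-based planarity oracle is for tiny graphs only"
    if g.number_of_edges() > max(3 * n - 6, 0):
        return False
    return not _has_k5_minor(g) and not _has_k33_minor(g)


def pmfg_bruteforce(r: np.ndarray) -> set[tuple[int, int]]:
    """Greedy planarity-filtered graph using the minor-based planarity test."""
    N = r.shape[0]
    iu, ju = np.triu_indices(N, k=1)
    order = np.lexsort((ju, iu, -r[iu, ju]))
    g = nx.Graph()
    g.add_nodes_from(range(N))
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        g.add_edge(i, j)
        if not is_planar_minor(g):
            g.remove_edge(i, j)
        elif g.number_of_edges() == 3 * (N - 2):
            break
    return {tuple(sorted(e)) for e in g.edges()}


# --- Benjamini-Hochberg step-up, straight from the definition -------------

def bh_bruteforce(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank0, i in enumerate(order):
        q[i] = min(1.0, min(p[order[r]] * m / (r + 1) for r in range(rank0, m)))
    return q


# --- Gaussian naive Bayes log posterior, scalar closed form ---------------

def nb_log_posterior_bruteforce(X, priors, means, variances) -> np.ndarray:
    X = np.atleast_2d(X)
    n, f = X.shape
    c = len(priors)
    out = np.empty((n, c))
    for s in range(n):
        for k in range(c):
            lp = np.log(priors[k])
            for j in range(f):
                var = variances[k][j]
                lp += (-0.5 * np.log(2.0 * np.pi * var)
                       - (X[s, j] - means[k][j]) ** 2 / (2.0 * var))
            out[s, k] = lp
    return out
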