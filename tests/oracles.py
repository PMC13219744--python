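"""Independent brute-force oracles used to validate the package's fast paths.

Everything here deliberately avoids the implementation's own machinery:
likelihoods are computed by naive recursive pruning on an explicitly rebuilt
tree with scipy's matrix exponential; primer matching enumerates degenerate
expansions against sliding windows; clustering and identity oracles work
from full all-pairs matrices.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from sqamp.models import AA_ALPHABET


# ---------------------------------------------------------------------------
# placement oracle: naive pruning on a rebuilt tree

class NaiveTree:
    """Adjacency-list tree; likelihood by recursion, P(t) by scipy expm."""

    def __init__(self, rate_matrix: np.ndarray, pi: np.ndarray):
        self.Q = rate_matrix
        self.pi = pi
        self.adj: dict[int, list[tuple[int, float]]] = {}
        self.tips: dict[int, np.ndarray] = {}
        self._pcache: dict[float, np.ndarray] = {}

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj.setdefault(u, []).append((v, length))
        self.adj.setdefault(v, []).append((u, length))

    def set_tip(self, node: int, row: str) -> None:
        n = len(row)
        M = np.zeros((20, n))
        for j, a in enumerate(row.upper()):
            i = AA_ALPHABET.find(a)
            if i < 0:
                M[:, j] = 1.0
            else:
                M[i, j] = 1.0
        self.tips[node] = M

    def _P(self, t: float) -> np.ndarray:
        key = round(t, 12)
        if key not in self._pcache:
            self._pcache[key] = expm(self.Q * t)
        return self._pcache[key]

    def _partial(self, v: int, parent: int, nsites: int) -> np.ndarray:
        part = (self.tips[v].copy() if v in self.tips
                else np.ones((20, nsites)))
        for u, length in self.adj[v]:
            if u == parent:
                continue
            part = part * (self._P(length) @ self._partial(u, v, nsites))
        return part

    def log_likelihood(self, root: int, nsites: int) -> float:
        site = self.pi @ self._partial(root, -1, nsites)
        return float(np.sum(np.log(site)))


def naive_placement_loglik(resource, model, query_row: str, edge: int,
                           pendant: float) -> float:
    """Rebuild the full tree with the query attached at the midpoint of
    `edge` and compute the likelihood from scratch."""
    rt = resource.tree
    nt = NaiveTree(model.rate_matrix, model.frequencies)
    for v in range(1, rt.n_nodes):
        nt.add_edge(rt.parent[v], v, rt.parent_length[v])
    for v, name in rt.node_name.items():
        nt.set_tip(v, resource.alignment[name])
    # attach query: midpoint node and query tip get fresh ids
    child = rt.edge_child[edge]
    par = rt.parent[child]
    length = rt.parent_length[child]
    mid, qtip = rt.n_nodes, rt.n_nodes + 1
    nt.adj[par] = [(x, l) for x, l in nt.adj[par] if x != child]
    nt.adj[child] = [(x, l) for x, l in nt.adj[child] if x != par]
    nt.add_edge(par, mid, 0.5 * length)
    nt.add_edge(mid, child, 0.5 * length)
    nt.add_edge(mid, qtip, pendant)
    nt.set_tip(qtip, query_row)
    return nt.log_likelihood(mid, len(query_row))


def naive_best_placement(resource, model, query_row: str,
                         grid_size: int = 200,
                         pendant_bounds: tuple[float, float] = (1e-8, 5.0)
                         ) -> tuple[int, float, float]:
    """(best edge, best log-likelihood, best pendant) by exhaustive search:
    for every edge, a log-spaced pendant grid followed by golden refinement
    of the naive likelihood around the best grid point."""
    lo, hi = pendant_bounds
    grid = np.geomspace(lo, hi, grid_size)
    best = (-np.inf, -1, lo)
    for e in range(resource.tree.n_edges):
        lls = [naive_placement_loglik(resource, model, query_row, e, t)
               for t in grid]
        i = int(np.argmax(lls))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid_size - 1)]
        x, fx = _golden(lambda t: naive_placement_loglik(
            resource, model, query_row, e, t), a, b, 1e-6)
        if lls[i] > fx:
            x, fx = grid[i], lls[i]
        if fx > best[0]:
            best = (fx, e, x)
    return best[1], best[0], best[2]


def _golden(f, a, b, tol):
    g = (5 ** 0.5 - 1) / 2
    x1, x2 = b - g * (b - a), a + g * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > tol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + g * (b - a)
            f2 = f(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - g * (b - a)
            f1 = f(x1)
    x = 0.5 * (a + b)
    return x, f(x)


# ---------------------------------------------------------------------------
# primer-matching oracle: expansion x sliding window

def brute_force_sites(primer_seq: str, template: str, max_mismatches: int,
                      expansions: set[str]) -> list[tuple[int, int]]:
    """(start, mismatches) via minimum Hamming distance to any expansion."""
    k = len(primer_seq)
    out = []
    for s in range(len(template) - k + 1):
        window = template[s:s + k]
        mm = min(sum(a != b for a, b in zip(window, e)) for e in expansions)
        if mm <= max_mismatches:
            out.append((s, mm))
    return out


# ---------------------------------------------------------------------------
# clustering oracle: same greedy rule from a precomputed all-pairs matrix

def greedy_from_matrix(ids: list[str], totals: dict[str, int],
                       identity: dict[tuple[str, str], float],
                       threshold: float) -> list[list[str]]:
    order = sorted(ids, key=lambda i: (-totals[i], i))
    clusters: list[list[str]] = []
    for a in order:
        for cl in clusters:
            c = cl[0]
            if identity[tuple(sorted((a, c)))] >= threshold:
                cl.append(a)
                break
        else:
            clusters.append([a])
    return clusters
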