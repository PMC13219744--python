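"""Maximum-likelihood phylogenetic placement of query peptides on a fixed
reference tree (EPA-style), with jplace export.

For every edge of the reference tree the query is attached at the edge
midpoint by a pendant branch whose length is optimized by golden-section
search; the best edge wins and like-weight ratios (LWR) are the softmax of
the per-edge log-likelihoods.  A query is *verified* when its best edge lies
inside the target clade (see :func:`sqamp.resources.target_edges`).

Likelihoods use Felsenstein pruning under a reversible amino-acid model
(LG by default).  Two-pass conditional likelihoods ("down" partials for the
subtree under each edge, "up" partials for the rest of the tree) make each
edge x pendant-length evaluation O(states^2 x sites), so placement of a
query costs seconds even on trees with hundreds of edges.  Gaps and X are
missing data (a vector of ones), never a 21st state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import AlignerConfig
from .models import (ModelConfig, N_STATES, SubstitutionModel, encode_peptide,
                     tip_partials)
from .resources import ReferenceResource, target_edges

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class UnplaceableQueryError(ValueError):
    """Raised when a query cannot be mapped into reference coordinates."""


@dataclass
class AlignedQuery:
    """A query peptide expressed in reference alignment columns."""

    asv_id: str
    row: str  # gapped, length == reference column count


@dataclass
class Placement:
    asv_id: str
    best_edge: int
    log_likelihood: float
    pendant_length: float
    lwr: dict[int, float]
    clade_id: int
    verified: bool


@dataclass
class OptimizerConfig:
    """Pendant-branch optimization bounds (substitutions/site) and tolerance."""

    min_pendant: float = 1e-8
    max_pendant: float = 5.0
    tol: float = 1e-5


def golden_section_max(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Golden-section search for the maximum of a unimodal function."""
    a, b = lo, hi
    x1 = b - GOLDEN * (b - a)
    x2 = a + GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > tol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + GOLDEN * (b - a)
            f2 = f(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - GOLDEN * (b - a)
            f1 = f(x1)
    x = 0.5 * (a + b)
    return x, f(x)


# ---------------------------------------------------------------------------
# query -> reference-column alignment

def align_query(peptide: str, resource: ReferenceResource,
                aligner_config: AlignerConfig = AlignerConfig()) -> "AlignedQuery | str":
    """Global profile alignment of a peptide against the reference alignment.

    The profile score of residue a at column c is the mean substitution
    score of a against the column's non-gap residues; skipping a column
    costs affine gap penalties scaled by the column's non-gap fraction, so
    columns that are mostly gaps in the reference are cheap to skip.  Query
    residues inserted relative to the reference are aligned to an insertion
    state and discarded from the output row.

    Raises UnplaceableQueryError when fewer than half of the query residues
    land in reference columns.
    """
    from Bio.Align import substitution_matrices

    if not peptide:
        raise UnplaceableQueryError("empty peptide")
    ncol = resource.n_columns
    rows = list(resource.alignment.values())
    matrix = substitution_matrices.load(aligner_config.matrix)
    alphabet = matrix.alphabet
    aa_idx = {a: i for i, a in enumerate(alphabet)}
    M = np.asarray(matrix)

    # position-specific profile: mean score per (residue, column)
    counts = np.zeros((len(alphabet), ncol))
    for row in rows:
        for c, a in enumerate(row.upper()):
            if a != "-" and a in aa_idx:
                counts[aa_idx[a], c] += 1
    nongap = counts.sum(axis=0)
    gap_open, gap_ext = aligner_config.open_gap, aligner_config.extend_gap
    with np.errstate(invalid="ignore"):
        profile = (M.T @ counts) / np.where(nongap > 0, nongap, 1.0)
    occ = np.where(nongap > 0, nongap, 0.0) / max(len(rows), 1)

    pep = peptide.upper()
    n = len(pep)
    NEG = -1e18
    # DP over (query residues) x (columns); three affine states
    Mst = np.full((n + 1, ncol + 1), NEG)
    Dst = np.full((n + 1, ncol + 1), NEG)  # column skipped (gap in query)
    Ist = np.full((n + 1, ncol + 1), NEG)  # query residue inserted (discarded)
    ptrM = np.zeros((n + 1, ncol + 1), dtype=np.int8)
    ptrD = np.zeros((n + 1, ncol + 1), dtype=np.int8)
    ptrI = np.zeros((n + 1, ncol + 1), dtype=np.int8)
    Mst[0, 0] = 0.0
    d_open = gap_open * occ  # length ncol, scaled per column
    d_ext = gap_ext * occ
    for j in range(1, ncol + 1):
        o = Mst[0, j - 1] + d_open[j - 1]
        e = Dst[0, j - 1] + d_ext[j - 1]
        Dst[0, j], ptrD[0, j] = (o, 0) if o >= e else (e, 1)
    for i in range(1, n + 1):
        o = Mst[i - 1, 0] + gap_open
        e = Ist[i - 1, 0] + gap_ext
        Ist[i, 0], ptrI[i, 0] = (o, 0) if o >= e else (e, 2)
        a = aa_idx.get(pep[i - 1])
        srow = profile[a] if a is not None else np.zeros(ncol)
        for j in range(1, ncol + 1):
            best, ptr = Mst[i - 1, j - 1], 0
            if Dst[i - 1, j - 1] > best:
                best, ptr = Dst[i - 1, j - 1], 1
            if Ist[i - 1, j - 1] > best:
                best, ptr = Ist[i - 1, j - 1], 2
            Mst[i, j] = best + srow[j - 1]
            ptrM[i, j] = ptr
            o, e = Mst[i, j - 1] + d_open[j - 1], Dst[i, j - 1] + d_ext[j - 1]
            Dst[i, j], ptrD[i, j] = (o, 0) if o >= e else (e, 1)
            o, e = Mst[i - 1, j] + gap_open, Ist[i - 1, j] + gap_ext
            Ist[i, j], ptrI[i, j] = (o, 0) if o >= e else (e, 2)
    # traceback from best final state
    i, j = n, ncol
    state = int(np.argmax([Mst[i, j], Dst[i, j], Ist[i, j]]))
    out = ["-"] * ncol
    matched = 0
    while i > 0 or j > 0:
        if state == 0:
            out[j - 1] = pep[i - 1]
            matched += 1
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            state = int(ptrD[i, j])
            j -= 1
        else:
            state = int(ptrI[i, j])
            i -= 1
    if matched < 0.5 * n:
        raise UnplaceableQueryError(
            f"only {matched}/{n} query residues map to reference columns")
    return AlignedQuery(asv_id="", row="".join(out))


# ---------------------------------------------------------------------------
# likelihood engine

class PlacementEngine:
    """Precomputed two-pass conditional likelihoods for EPA-style placement."""

    def __init__(self, resource: ReferenceResource,
                 model_config: ModelConfig = ModelConfig(),
                 optimizer_config: OptimizerConfig = OptimizerConfig()):
        self.resource = resource
        self.model: SubstitutionModel = model_config.build()
        self.opt = optimizer_config
        tree = resource.tree
        self.tree = tree
        self.nsites = resource.n_columns
        pi = self.model.frequencies

        tips = {}
        for name in tree.leaf_names:
            states = encode_peptide(resource.alignment[name])
            tips[name] = tip_partials(states)

        nn = tree.n_nodes
        # down pass: D[v] = P(subtree data | state at v), per-site scaled
        self.D = [None] * nn
        self.D_scale = [None] * nn
        P_branch = [None] * nn  # P(t_v) for the edge above node v
        for v in range(nn):
            if tree.parent[v] is not None:
                P_branch[v] = self.model.transition_matrix(tree.parent_length[v])
        for v in tree.postorder:
            if not tree.children[v]:
                self.D[v] = tips[tree.node_name[v]]
                self.D_scale[v] = np.zeros(self.nsites)
            else:
                # the anchor is a leaf serving as traversal root: its own tip
                # data folds into its partial alongside its child subtree
                part = (tips[tree.node_name[v]].copy()
                        if v in tree.node_name else
                        np.ones((N_STATES, self.nsites)))
                scale = np.zeros(self.nsites)
                for c in tree.children[v]:
                    part = part * (P_branch[c] @ self.D[c])
                    scale += self.D_scale[c]
                s = part.max(axis=0)
                s[s == 0] = 1.0
                self.D[v] = part / s
                self.D_scale[v] = scale + np.log(s)

        # up pass: for edge e above node v with parent p,
        # R[e] = P(all data outside subtree(v) | state at p)
        self.R = [None] * tree.n_edges
        self.R_scale = [None] * tree.n_edges
        A = [None] * nn          # P(data above v | state at v)
        A_scale = [None] * nn
        A[0] = tips[tree.node_name[0]]  # anchor leaf's own data
        A_scale[0] = np.zeros(self.nsites)
        for p in range(nn):      # node ids are preorder, so parents come first
            if A[p] is None:
                continue
            kids = tree.children[p]
            mats = [P_branch[c] @ self.D[c] for c in kids]
            for idx, v in enumerate(kids):
                part = A[p].copy()
                scale = A_scale[p].copy()
                for jdx, c in enumerate(kids):
                    if jdx == idx:
                        continue
                    part = part * mats[jdx]
                    scale += self.D_scale[c]
                s = part.max(axis=0)
                s[s == 0] = 1.0
                part /= s
                scale = scale + np.log(s)
                e = tree.edge_above[v]
                self.R[e] = part
                self.R_scale[e] = scale
                # A[v](x) = sum_y pi_y P_yx(t_v) R[e](y) / pi_x
                av = (P_branch[v].T @ (pi[:, None] * part)) / pi[:, None]
                s2 = av.max(axis=0)
                s2[s2 == 0] = 1.0
                A[v] = av / s2
                A_scale[v] = scale + np.log(s2)

        # per-edge halves: midpoint m of edge e; transition over t/2 each way
        # combined rest-of-tree partial at each edge midpoint
        self.edge_partials = [None] * tree.n_edges
        self.edge_scale = [None] * tree.n_edges
        for e in range(tree.n_edges):
            v = tree.edge_child[e]
            th = 0.5 * tree.parent_length[v]
            Ph = self.model.transition_matrix(th)
            down = Ph @ self.D[v]
            up = (Ph.T @ (pi[:, None] * self.R[e])) / pi[:, None]
            prod = down * up
            s = prod.max(axis=0)
            s[s == 0] = 1.0
            self.edge_partials[e] = prod / s
            self.edge_scale[e] = (self.D_scale[v] + self.R_scale[e]
                                  + np.log(s))
        self._target_edges = target_edges(resource)
        self._clades = self._clade_runs()

    def _clade_runs(self) -> dict[int, int]:
        """Group edges into contiguous runs of identical target/non-target
        status (connected in the tree); clades numbered by smallest edge id."""
        tree = self.tree
        status = [e in self._target_edges for e in range(tree.n_edges)]
        parent = list(range(tree.n_edges))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in range(tree.n_edges):
            for f in tree.edges_adjacent(e):
                if status[e] == status[f]:
                    parent[find(e)] = find(f)
        roots = sorted({find(e) for e in range(tree.n_edges)},
                       key=lambda r: min(e for e in range(tree.n_edges)
                                         if find(e) == r))
        rank = {r: i for i, r in enumerate(roots)}
        return {e: rank[find(e)] for e in range(tree.n_edges)}

    def reference_log_likelihood(self) -> float:
        """Log-likelihood of the reference tree/alignment alone."""
        pi = self.model.frequencies
        site = pi @ self.D[0]
        return float(np.sum(np.log(site) + self.D_scale[0]))

    def _query_tip(self, query: AlignedQuery) -> np.ndarray:
        states = encode_peptide(query.row)
        if states.shape[0] != self.nsites:
            raise ValueError("query row length != reference columns")
        return tip_partials(states)

    def edge_log_likelihood_partials(self, qtip: np.ndarray, edge: int,
                                     pendant: float) -> float:
        Pq = self.model.transition_matrix(pendant)
        pi = self.model.frequencies
        site = pi @ (self.edge_partials[edge] * (Pq @ qtip))
        return float(np.sum(np.log(site) + self.edge_scale[edge]))

    def place(self, query: AlignedQuery) -> Placement:
        qtip = self._query_tip(query)
        nE = self.tree.n_edges
        lls = np.empty(nE)
        pendants = np.empty(nE)
        for e in range(nE):
            x, fx = golden_section_max(
                lambda t: self.edge_log_likelihood_partials(qtip, e, t),
                self.opt.min_pendant, self.opt.max_pendant, self.opt.tol)
            # the optimum may sit at the lower boundary (query == leaf)
            f_lo = self.edge_log_likelihood_partials(qtip, e, self.opt.min_pendant)
            if f_lo > fx:
                x, fx = self.opt.min_pendant, f_lo
            lls[e] = fx
            pendants[e] = x
        best = int(np.argmax(lls))
        w = np.exp(lls - lls[best])
        lwr = w / w.sum()
        return Placement(
            asv_id=query.asv_id,
            best_edge=best,
            log_likelihood=float(lls[best]),
            pendant_length=float(pendants[best]),
            lwr={e: float(lwr[e]) for e in range(nE)},
            clade_id=self._clades[best],
            verified=best in self._target_edges,
        )


def edge_log_likelihood(resource: ReferenceResource, query: AlignedQuery,
                        edge: int, pendant: float,
                        model_config: ModelConfig = ModelConfig()) -> float:
    """Log-likelihood of the reference tree with `query` attached by a
    pendant branch at the midpoint of `edge`."""
    engine = PlacementEngine(resource, model_config)
    return engine.edge_log_likelihood_partials(engine._query_tip(query),
                                               edge, pendant)


def place_query(resource: ReferenceResource, query: AlignedQuery,
                model_config: ModelConfig = ModelConfig(),
                optimizer_config: OptimizerConfig = OptimizerConfig()) -> Placement:
    """Single-query convenience wrapper; build a PlacementEngine for batches."""
    return PlacementEngine(resource, model_config, optimizer_config).place(query)


def write_jplace(placements: list[Placement], resource: ReferenceResource,
                 path, multiplicities: Optional[dict[str, int]] = None,
                 min_lwr: float = 0.01) -> None:
    """Write placements as jplace v3.

    Edge numbers in the tree string follow the resource's deterministic
    numbering; distal_length is half the attachment edge (midpoint
    convention).  Each record carries the ASV's read multiplicity.
    """
    if not placements:
        raise ValueError("no placements to write")
    tree = resource.tree
    records = []
    for p in placements:
        rows = []
        order = sorted(p.lwr, key=lambda e: -p.lwr[e])
        for e in order:
            if p.lwr[e] < min_lwr and e != p.best_edge:
                continue
            ll = p.log_likelihood + math.log(max(p.lwr[e], 1e-300)) \
                - math.log(max(p.lwr[p.best_edge], 1e-300))
            rows.append([e, ll, p.lwr[e], 0.5 * tree.edge_length(e),
                         p.pendant_length if e == p.best_edge else 0.0])
        mult = (multiplicities or {}).get(p.asv_id, 1)
        records.append({"p": rows, "nm": [[p.asv_id, mult]]})
    doc = {
        "version": 3,
        "tree": tree.newick(edge_numbers=True),
        "fields": ["edge_num", "likelihood", "like_weight_ratio",
                   "distal_length", "pendant_length"],
        "placements": records,
        "metadata": {"software": "sqamp"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def place_peptides(peptides: dict[str, str], resource: ReferenceResource,
                   model_config: ModelConfig = ModelConfig(),
                   optimizer_config: OptimizerConfig = OptimizerConfig(),
                   aligner_config: AlignerConfig = AlignerConfig()
                   ) -> tuple[list[Placement], dict[str, str]]:
    """Align and place a batch of peptides; returns placements and a map of
    unplaceable ids to the failure reason."""
    engine = PlacementEngine(resource, model_config, optimizer_config)
    placements, failed = [], {}
    for asv_id in sorted(peptides):
        try:
            q = align_query(peptides[asv_id], resource, aligner_config)
            q.asv_id = asv_id
            placements.append(engine.place(q))
        except UnplaceableQueryError as exc:
            failed[asv_id] = str(exc)
    return placements, failed
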