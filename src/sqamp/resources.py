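"""Reference bundle: marker-protein database, alignment, tree, target clade.

The reference resource is the ground truth every downstream stage consumes:
a set of reference proteins (validated marker sequences plus related decoy
family members), their multiple alignment, an unrooted maximum-likelihood
tree over them with branch lengths, and the set of leaf ids that form the
target (marker) clade.

Edge numbering convention
-------------------------
The unrooted tree's edges are numbered by a depth-first preorder traversal
anchored at the first leaf appearing in the Newick file; children are
visited in file order.  The edge between the anchor leaf and its neighbour
receives number 0.  This makes edge numbers a deterministic function of the
Newick text, so placement output (jplace) is reproducible and round-trips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

AA_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ReferenceEntry:
    """One reference protein (optionally with its coding sequence)."""

    id: str
    protein_seq: str
    label: str  # "target" or "non_target"
    taxonomy: tuple[str, ...] = ()
    nt_seq: Optional[str] = None
    source: str = ""

    def validate(self) -> None:
        if not self.protein_seq:
            raise ValueError(f"{self.id}: empty protein sequence")
        bad = set(self.protein_seq.upper()) - AA_VALID
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        if self.label not in ("target", "non_target"):
            raise ValueError(f"{self.id}: label must be target/non_target")
        if self.nt_seq is not None:
            aa = str(Seq(self.nt_seq).translate(table=11))
            if aa.endswith("*"):
                aa = aa[:-1]
            if aa != self.protein_seq.upper():
                raise ValueError(
                    f"{self.id}: nucleotide sequence does not translate to "
                    f"the protein sequence in frame 1")


class RefTree:
    """Unrooted tree with deterministic preorder edge numbering.

    Internally the tree is anchored (rooted) at the first leaf of the Newick
    file purely for traversal; likelihood computations are invariant to this
    choice for reversible models.
    """

    def __init__(self, newick: str):
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        # adjacency in file order
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}
        nid = {}

        def get_id(nd):
            if id(nd) not in nid:
                nid[id(nd)] = len(nid)
                adj[nid[id(nd)]] = []
            return nid[id(nd)]

        first_leaf = None
        for nd in tree.preorder_node_iter():
            u = get_id(nd)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("tree contains an unlabeled leaf")
                names[u] = nd.taxon.label
                if first_leaf is None:
                    first_leaf = u
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise ValueError("tree edge without branch length")
                if nd.edge.length < 0:
                    raise ValueError("negative branch length in tree")
                p = get_id(nd.parent_node)
                adj[p].append((u, float(nd.edge.length)))
                adj[u].append((p, float(nd.edge.length)))
        if first_leaf is None:
            raise ValueError("tree has no leaves")
        # collapse a bifurcating seed node: unrooted interpretation
        seed = get_id(tree.seed_node)
        if seed not in names and len(adj[seed]) == 2:
            (a, la), (b, lb) = adj[seed]
            adj[a] = [(b, la + lb) if x == seed else (x, l) for x, l in adj[a]]
            adj[b] = [(a, la + lb) if x == seed else (x, l) for x, l in adj[b]]
            del adj[seed]

        # depth-first relabeling from the anchor leaf
        self.parent: list[Optional[int]] = []
        self.parent_length: list[float] = []
        self.edge_above: list[Optional[int]] = []
        self.children: list[list[int]] = []
        self.node_name: dict[int, str] = {}
        old2new: dict[int, int] = {}

        def add_node(old, parent, length):
            new = len(self.parent)
            old2new[old] = new
            self.parent.append(parent)
            self.children.append([])
            if parent is None:
                self.parent_length.append(0.0)
                self.edge_above.append(None)
            else:
                self.children[parent].append(new)
                self.parent_length.append(length)
                self.edge_above.append(len(self.parent) - 2)  # preorder count
            if old in names:
                self.node_name[new] = names[old]
            return new

        stack = [(first_leaf, None, None, 0.0)]
        while stack:
            old, old_parent, parent_new, length = stack.pop()
            new = add_node(old, parent_new, length)
            # push children in reverse file order so DFS visits in file order
            kids = [(v, l) for v, l in adj[old] if v != old_parent]
            for v, l in reversed(kids):
                stack.append((v, old, new, l))

        # edge id above each node: assigned in preorder = creation order - 1
        self.n_nodes = len(self.parent)
        self.n_edges = self.n_nodes - 1
        self.anchor = 0
        self.name_to_node = {n: i for i, n in self.node_name.items()}
        if len(self.name_to_node) != len(self.node_name):
            raise ValueError("duplicate leaf labels in tree")
        self.edge_child = [None] * self.n_edges  # node below each edge
        for v in range(self.n_nodes):
            e = self.edge_above[v]
            if e is not None:
                self.edge_child[e] = v
        self.postorder = self._postorder()

    def _postorder(self) -> list[int]:
        order, stack = [], [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    @property
    def leaf_names(self) -> list[str]:
        return [self.node_name[v] for v in range(self.n_nodes)
                if v in self.node_name]

    def edge_length(self, edge: int) -> float:
        return self.parent_length[self.edge_child[edge]]

    def edges_adjacent(self, edge: int) -> set[int]:
        """Edges sharing an endpoint with `edge`."""
        v = self.edge_child[edge]
        p = self.parent[v]
        out = set()
        for u in self.children[v]:
            out.add(self.edge_above[u])
        if p is not None:
            if self.edge_above[p] is not None:
                out.add(self.edge_above[p])
            for u in self.children[p]:
                if u != v:
                    out.add(self.edge_above[u])
        out.discard(None)
        out.discard(edge)
        return out

    def leaves_below(self, ) -> list[set[str]]:
        """Per edge, the set of leaf names on the child side."""
        below: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for v in self.postorder:
            if v in self.node_name:
                below[v].add(self.node_name[v])
            for c in self.children[v]:
                below[v] |= below[c]
        return [below[self.edge_child[e]] for e in range(self.n_edges)]

    def newick(self, edge_numbers: bool = False) -> str:
        """Render the tree; the anchor leaf is written as the first child so
        the numbering convention round-trips."""
        if not self.children[0]:
            raise ValueError("degenerate single-node tree")
        top = self.children[0][0]

        def tag(v):
            return "{%d}" % self.edge_above[v] if edge_numbers else ""

        def render(v):
            if not self.children[v]:
                return f"{self.node_name[v]}:{self.parent_length[v]:.10g}{tag(v)}"
            inner = ",".join(render(c) for c in self.children[v])
            return f"({inner}):{self.parent_length[v]:.10g}{tag(v)}"

        anchor = (f"{self.node_name[0]}:{self.parent_length[top]:.10g}"
                  + ("{%d}" % self.edge_above[top] if edge_numbers else ""))
        kids = ",".join(render(c) for c in self.children[top])
        return f"({anchor},{kids});"


@dataclass
class ReferenceResource:
    """Validated bundle of reference entries, alignment, tree and target set."""

    entries: list[ReferenceEntry]
    alignment: dict[str, str]
    tree: RefTree
    target_leaves: set[str]

    def __post_init__(self):
        self.by_id = {}
        for e in self.entries:
            e.validate()
            if e.id in self.by_id:
                raise ValueError(f"duplicate reference id {e.id}")
            self.by_id[e.id] = e
        cols = {len(r) for r in self.alignment.values()}
        if len(cols) > 1:
            raise ValueError("alignment rows have differing column counts")
        missing = sorted(set(self.alignment) - set(self.by_id))
        if missing:
            raise ValueError(f"alignment ids not in database: {missing}")
        for rid, row in self.alignment.items():
            if row.replace("-", "").upper() != self.by_id[rid].protein_seq.upper():
                raise ValueError(
                    f"alignment row {rid} does not ungap to its database "
                    f"protein sequence")
        leaves = set(self.tree.leaf_names)
        missing = sorted(leaves - set(self.by_id))
        if missing:
            raise ValueError(f"tree leaves not in database: {missing}")
        missing = sorted(leaves - set(self.alignment))
        if missing:
            raise ValueError(f"tree leaves without alignment row: {missing}")
        if not self.target_leaves <= leaves:
            bad = sorted(self.target_leaves - leaves)
            raise ValueError(f"target leaves not in tree: {bad}")
        for t in sorted(self.target_leaves):
            if self.by_id[t].label != "target":
                raise ValueError(f"target leaf {t} not labeled 'target'")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.alignment.values())))


def target_edges(resource: ReferenceResource) -> set[int]:
    """Edges of the minimal spanning subtree connecting the target leaves,
    plus the stem edge of that subtree when the targets form a proper,
    clade-like subset of the leaves.

    An edge is on the spanning subtree iff both of its sides contain at
    least one target leaf.  The stem edge is the unique edge (if any) for
    which one side's leaf set equals the target set exactly.
    """
    targets = resource.target_leaves
    if not targets:
        raise ValueError("target_leaves is empty")
    tree = resource.tree
    below = tree.leaves_below()
    all_leaves = set(tree.leaf_names)
    T = len(targets)
    out = set()
    for e in range(tree.n_edges):
        k = len(below[e] & targets)
        if 1 <= k <= T - 1:
            out.add(e)
        if targets < all_leaves and (below[e] == targets
                                     or (all_leaves - below[e]) == targets):
            out.add(e)
    return out


# ---------------------------------------------------------------------------
# I/O

def _read_fasta(path) -> dict[str, str]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate id {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def parse_taxonomy(s: str) -> tuple[str, ...]:
    """Semicolon-separated GTDB-style rank strings; empty ranks preserved."""
    if not s or pd.isna(s):
        return ()
    return tuple(part.strip() for part in str(s).split(";"))


def load_reference(protein_fasta, alignment_fasta, tree_newick, metadata_tsv,
                   nt_fasta=None) -> ReferenceResource:
    """Load and validate a reference bundle from its file set.

    metadata_tsv needs columns id, label, taxonomy (semicolon-separated);
    an optional source column is carried through.  Target leaves are the
    entries labeled 'target' that appear in the tree.
    """
    proteins = _read_fasta(protein_fasta)
    alignment = _read_fasta(alignment_fasta)
    nts = _read_fasta(nt_fasta) if nt_fasta else {}
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str).fillna("")
    for col in ("id", "label"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    rows = {r["id"]: r for _, r in meta.iterrows()}
    missing = sorted(set(proteins) - set(rows))
    if missing:
        raise ValueError(f"proteins without metadata: {missing}")
    entries = []
    for pid, seq in proteins.items():
        r = rows[pid]
        entries.append(ReferenceEntry(
            id=pid, protein_seq=seq, label=r["label"],
            taxonomy=parse_taxonomy(r.get("taxonomy", "")),
            nt_seq=nts.get(pid), source=r.get("source", "")))
    newick = Path(tree_newick).read_text()
    tree = RefTree(newick)
    targets = {e.id for e in entries if e.label == "target"} & set(tree.leaf_names)
    return ReferenceResource(entries=entries, alignment=alignment,
                             tree=tree, target_leaves=targets)


def write_reference(resource: ReferenceResource, outdir) -> dict[str, Path]:
    """Write the bundle back to FASTA/Newick/TSV; inverse of load_reference."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_fasta": outdir / "reference_proteins.faa",
        "nt_fasta": outdir / "reference_cds.fna",
        "alignment_fasta": outdir / "reference_alignment.afa",
        "tree_newick": outdir / "reference_tree.nwk",
        "metadata_tsv": outdir / "reference_metadata.tsv",
    }
    with open(paths["protein_fasta"], "w") as fh:
        for e in resource.entries:
            fh.write(f">{e.id}\n{e.protein_seq}\n")
    have_nt = [e for e in resource.entries if e.nt_seq]
    if have_nt:
        with open(paths["nt_fasta"], "w") as fh:
            for e in have_nt:
                fh.write(f">{e.id}\n{e.nt_seq}\n")
    else:
        del paths["nt_fasta"]
    with open(paths["alignment_fasta"], "w") as fh:
        for rid, row in resource.alignment.items():
            fh.write(f">{rid}\n{row}\n")
    paths["tree_newick"].write_text(resource.tree.newick() + "\n")
    meta = pd.DataFrame({
        "id": [e.id for e in resource.entries],
        "label": [e.label for e in resource.entries],
        "taxonomy": [";".join(e.taxonomy) for e in resource.entries],
        "source": [e.source for e in resource.entries],
    })
    meta.to_csv(paths["metadata_tsv"], sep="\t", index=False)
    return paths
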