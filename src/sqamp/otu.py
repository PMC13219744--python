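"""Greedy abundance-sorted centroid clustering of ASVs into OTUs.

Mirrors vsearch's cluster_size behaviour: ASVs are processed in decreasing
total-count order (ties broken lexicographically by id) and each joins the
first existing centroid whose global-alignment identity reaches the
threshold, otherwise it founds a new cluster.  The default threshold of
0.90 approximates species-level groups for the marker gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .verify import Asv


@dataclass(frozen=True)
class NtAlignerConfig:
    """Global nucleotide alignment scoring (vsearch-like)."""

    match: float = 2.0
    mismatch: float = -4.0
    open_gap: float = -10.0
    extend_gap: float = -1.0


def _nt_aligner(cfg: NtAlignerConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    aligner.open_gap_score = cfg.open_gap
    aligner.extend_gap_score = cfg.extend_gap
    aligner.mode = "global"
    return aligner


def pairwise_identity(a: str, b: str,
                      config: NtAlignerConfig = NtAlignerConfig()) -> float:
    """Fraction of matching positions in the global alignment of a and b,
    over all alignment columns except terminal-gap columns."""
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    aligner = _nt_aligner(config)
    aln = next(iter(aligner.align(a, b)))
    c = aln.counts()
    cols = c.identities + c.mismatches + c.internal_gaps
    return c.identities / cols if cols else 0.0


@dataclass
class OtuCluster:
    otu_id: int
    centroid: str
    members: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)


def cluster_greedy(asvs: list[Asv], threshold: float = 0.9,
                   config: NtAlignerConfig = NtAlignerConfig(),
                   best_match: bool = False) -> list[OtuCluster]:
    """Partition ASVs into OTUs at the given identity threshold.

    With best_match=False (default, vsearch-like) an ASV joins the first
    centroid reaching the threshold in cluster-founding order; with
    best_match=True it joins the highest-identity centroid above threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(asvs, key=lambda a: (-a.total_count, a.id))
    clusters: list[OtuCluster] = []
    seqs = {a.id: a.nt_seq for a in asvs}
    for asv in order:
        chosen, chosen_ident = None, -1.0
        for cl in clusters:
            ident = pairwise_identity(asv.nt_seq, seqs[cl.centroid], config)
            if ident >= threshold:
                if not best_match:
                    chosen, chosen_ident = cl, ident
                    break
                if ident > chosen_ident:
                    chosen, chosen_ident = cl, ident
        if chosen is None:
            chosen = OtuCluster(otu_id=len(clusters), centroid=asv.id)
            clusters.append(chosen)
            chosen_ident = 1.0
        chosen.members.append(asv.id)
        chosen.identities[asv.id] = chosen_ident
    return clusters


def otu_count_table(clusters: list[OtuCluster], asvs: list[Asv]) -> pd.DataFrame:
    """Clusters x samples count table (member counts summed)."""
    by_id = {a.id: a for a in asvs}
    samples = sorted({s for a in asvs for s in a.counts})
    rows = {}
    for cl in clusters:
        tot = {s: 0 for s in samples}
        for m in cl.members:
            for s, c in by_id[m].counts.items():
                tot[s] += c
        rows[f"OTU{cl.otu_id}"] = tot
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples).fillna(0).astype(int)


def membership_table(clusters: list[OtuCluster]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        for m in cl.members:
            rows.append({"otu_id": f"OTU{cl.otu_id}", "asv_id": m,
                         "centroid": cl.centroid,
                         "identity_to_centroid": cl.identities[m]})
    return pd.DataFrame(rows)
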