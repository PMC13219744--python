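"""Best-hit taxonomy of verified marker peptides with a hard identity floor.

Queries are matched against a genome-derived protein database by local
alignment; the top-scoring hit assigns its taxonomy only when the amino-acid
identity over the aligned span reaches the floor (default 90%), otherwise
the query is reported as unclassified — a deliberately conservative rule for
species-resolution claims from a single marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .align import AlignerConfig, best_local_hit
from .place import Placement

UNCLASSIFIED = "unclassified"

RANK_INDEX = {"domain": 0, "phylum": 1, "class": 2, "order": 3,
              "family": 4, "genus": 5}


@dataclass
class TaxDbEntry:
    id: str
    protein_seq: str
    taxonomy: tuple[str, ...]  # ordered ranks, domain -> genus


@dataclass
class TaxAssignment:
    asv_id: str
    hit_id: Optional[str] = None
    identity: Optional[float] = None
    ranks: tuple[str, ...] = (UNCLASSIFIED,)

    @property
    def classified(self) -> bool:
        return self.ranks != (UNCLASSIFIED,)


def classify(peptide: str, db: Sequence[TaxDbEntry], floor: float = 0.9,
             aligner: AlignerConfig = AlignerConfig(),
             asv_id: str = "") -> TaxAssignment:
    """Assign the best hit's taxonomy if span identity >= floor.

    The best hit is chosen by alignment score, ties broken by higher
    identity then lexicographic id (the tie-break order of
    :func:`sqamp.align.best_local_hit`).  Multi-copy marker genes are
    distinct db entries sharing a taxonomy string; best-hit logic is per
    entry.
    """
    if not db:
        raise ValueError("empty taxonomy database")
    refs = {e.id: e.protein_seq for e in db}
    hit = best_local_hit(peptide, refs, aligner)
    if hit is None:
        return TaxAssignment(asv_id=asv_id)
    tax = {e.id: e.taxonomy for e in db}
    if hit.identity >= floor:
        return TaxAssignment(asv_id=asv_id, hit_id=hit.ref_id,
                             identity=hit.identity, ranks=tax[hit.ref_id])
    return TaxAssignment(asv_id=asv_id, hit_id=hit.ref_id,
                         identity=hit.identity)


def classify_all(peptides: dict[str, str], db: Sequence[TaxDbEntry],
                 floor: float = 0.9,
                 aligner: AlignerConfig = AlignerConfig()) -> list[TaxAssignment]:
    return [classify(peptides[a], db, floor, aligner, asv_id=a)
            for a in sorted(peptides)]


def _taxon_at(assignment: TaxAssignment, rank: str) -> str:
    if not assignment.classified:
        return UNCLASSIFIED
    idx = RANK_INDEX[rank]
    if idx < len(assignment.ranks) and assignment.ranks[idx]:
        return assignment.ranks[idx]
    return UNCLASSIFIED


def clade_composition(placements: Sequence[Placement],
                      assignments: Sequence[TaxAssignment],
                      rank: str = "class") -> pd.DataFrame:
    """Per placement clade, the taxon distribution of its ASVs at `rank`.

    Returns a long-format table (clade_id, taxon, count, percent); percents
    sum to 100 within each clade, with unclassified as its own category.
    """
    if rank not in RANK_INDEX:
        raise ValueError(f"unsupported rank {rank!r}")
    by_id = {a.asv_id: a for a in assignments}
    missing = sorted({p.asv_id for p in placements} - set(by_id))
    if missing:
        raise ValueError(f"placements without taxonomy assignment: {missing}")
    rows: dict[tuple[int, str], int] = {}
    for p in placements:
        taxon = _taxon_at(by_id[p.asv_id], rank)
        rows[(p.clade_id, taxon)] = rows.get((p.clade_id, taxon), 0) + 1
    df = pd.DataFrame([{"clade_id": c, "taxon": t, "count": n}
                       for (c, t), n in sorted(rows.items())])
    totals = df.groupby("clade_id")["count"].transform("sum")
    df["percent"] = 100.0 * df["count"] / totals
    return df


def load_tax_db(protein_fasta, taxonomy_tsv) -> list[TaxDbEntry]:
    """Protein FASTA plus TSV (id, taxonomy) with semicolon-separated ranks."""
    from .resources import _read_fasta, parse_taxonomy

    seqs = _read_fasta(protein_fasta)
    meta = pd.read_csv(taxonomy_tsv, sep="\t", dtype=str).fillna("")
    tax = dict(zip(meta["id"], meta["taxonomy"]))
    missing = sorted(set(seqs) - set(tax))
    if missing:
        raise ValueError(f"proteins without taxonomy: {missing}")
    return [TaxDbEntry(id=i, protein_seq=s, taxonomy=parse_taxonomy(tax[i]))
            for i, s in seqs.items()]
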