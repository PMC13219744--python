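"""Thin wrappers around Biopython's pairwise aligner used across modules."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignerConfig:
    """Protein local-alignment scoring (BLAST-like defaults)."""

    matrix: str = "BLOSUM62"
    open_gap: float = -11.0
    extend_gap: float = -1.0


@lru_cache(maxsize=8)
def _protein_aligner(matrix: str, open_gap: float, extend_gap: float,
                     mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.mode = mode
    return aligner


def protein_aligner(config: AlignerConfig = AlignerConfig(),
                    mode: str = "local") -> Align.PairwiseAligner:
    return _protein_aligner(config.matrix, config.open_gap, config.extend_gap,
                            mode)


@dataclass
class LocalHit:
    """Best local alignment of a query against one reference sequence."""

    ref_id: str
    score: float
    identity: float          # identities / aligned columns (incl. internal gaps)
    aligned_columns: int
    query_start: int         # query span of the local alignment
    query_end: int


def best_local_hit(query: str, refs: dict[str, str],
                   config: AlignerConfig = AlignerConfig()) -> LocalHit | None:
    """Highest-scoring local alignment of `query` against any reference.

    Ties are broken by higher identity, then lexicographic reference id.
    Returns None when no alignment has positive score.
    """
    aligner = protein_aligner(config, "local")
    best: LocalHit | None = None
    for rid in sorted(refs):
        ref = refs[rid]
        score = aligner.score(ref, query)
        if score <= 0:
            continue
        if best is not None and score < best.score:
            continue
        aln = next(iter(aligner.align(ref, query)))
        c = aln.counts()
        cols = c.identities + c.mismatches + c.internal_gaps
        identity = c.identities / cols if cols else 0.0
        qblocks = aln.aligned[1]
        hit = LocalHit(ref_id=rid, score=float(score), identity=identity,
                       aligned_columns=int(cols),
                       query_start=int(qblocks[0][0]),
                       query_end=int(qblocks[-1][1]))
        if (best is None or hit.score > best.score
                or (hit.score == best.score and hit.identity > best.identity)):
            best = hit
    return best


def best_local_score(query: str, refs: dict[str, str],
                     config: AlignerConfig = AlignerConfig()) -> float:
    """Max local alignment score only (cheaper: no traceback)."""
    aligner = protein_aligner(config, "local")
    return max((float(aligner.score(ref, query)) for ref in refs.values()),
               default=0.0)
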