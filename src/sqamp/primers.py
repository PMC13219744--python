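"""Degenerate primers: expansion, binding-site search, in-silico PCR,
database coverage, melting temperature, and conserved-window primer design.

Primer/template matching is positional set membership (no indels): a primer
position matches a template base when the base belongs to the primer's IUPAC
set; an ambiguous template code counts as a match only when the primer set
is a superset of the template set (conservative coverage).  Optional 5'-head
(adapter) sequences never participate in matching.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {c: sum(_BASE_BIT[b] for b in s) for c, s in IUPAC.items()}
_MASK_CODE = {m: c for c, m in _CODE_MASK.items()}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _validate_iupac(seq: str) -> str:
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in IUPAC:
            raise ValueError(f"illegal IUPAC character {c!r} at position {i}")
    return seq


def degeneracy(seq: str) -> int:
    return math.prod(len(IUPAC[c]) for c in _validate_iupac(seq))


def expand_degenerate(seq: str) -> set[str]:
    """All concrete sequences encoded by an IUPAC string."""
    seq = _validate_iupac(seq)
    return {"".join(p) for p in itertools.product(*(IUPAC[c] for c in seq))}


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-encoded oligo, 5'->3', with orientation and optional 5' head."""

    name: str
    seq: str
    orientation: str  # 'forward' or 'reverse'
    head: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "seq", _validate_iupac(self.seq))
        if len(self.seq) < 10:
            raise ValueError(f"{self.name}: primer shorter than 10 nt")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"{self.name}: orientation must be forward/reverse")
        if self.head is not None:
            object.__setattr__(self, "head", _validate_iupac(self.head))

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    start: int        # 0-based on the + strand
    strand: str       # '+' or '-'
    mismatches: int


def _mask_array(seq: str) -> np.ndarray:
    return np.array([_CODE_MASK[c] for c in seq.upper()], dtype=np.uint8)


def _scan(primer_masks: np.ndarray, template_masks: np.ndarray,
          max_mismatches: int) -> list[tuple[int, int]]:
    """(start, mismatches) for every window; a position matches when the
    primer set covers the template set (template_mask & ~primer_mask == 0)."""
    k, n = len(primer_masks), len(template_masks)
    if k > n:
        return []
    mm = np.zeros(n - k + 1, dtype=np.int32)
    for off in range(k):
        mm += (template_masks[off:n - k + 1 + off] & ~primer_masks[off]) != 0
    return [(int(s), int(m)) for s, m in enumerate(mm) if m <= max_mismatches]


def find_binding_sites(primer: DegeneratePrimer, template: str,
                       max_mismatches: int = 0,
                       template_id: str = "") -> list[BindingSite]:
    """All binding sites within the mismatch budget, sorted by start.

    Forward primers are scanned on the + strand; reverse primers are scanned
    as their reverse complement on the + strand and reported with strand '-'
    (start remains the + strand coordinate of the site's left end).
    """
    template = _validate_iupac(template)
    tmask = _mask_array(template)
    if primer.orientation == "forward":
        pmask = _mask_array(primer.seq)
        strand = "+"
    else:
        pmask = _mask_array(reverse_complement(primer.seq))
        strand = "-"
    return [BindingSite(template_id=template_id, start=s, strand=strand,
                        mismatches=m)
            for s, m in _scan(pmask, tmask, max_mismatches)]


def in_silico_pcr(fwd: DegeneratePrimer, rev: DegeneratePrimer, template: str,
                  max_mismatches: int = 0,
                  size_range: tuple[int, int] = (50, 5000),
                  template_id: str = "") -> list[tuple[str, BindingSite, BindingSite]]:
    """(amplicon, fwd site, rev site) for every properly oriented primer pair
    within the size range; the amplicon includes both primer sites, and
    products are sorted by start position."""
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("in_silico_pcr needs a forward and a reverse primer")
    template = _validate_iupac(template)
    f_sites = find_binding_sites(fwd, template, max_mismatches, template_id)
    r_sites = find_binding_sites(rev, template, max_mismatches, template_id)
    lo, hi = size_range
    out = []
    for fs in f_sites:
        for rs in r_sites:
            end = rs.start + len(rev)
            length = end - fs.start
            if rs.start >= fs.start + len(fwd) and lo <= length <= hi:
                out.append((template[fs.start:end], fs, rs))
    out.sort(key=lambda t: (t[1].start, t[2].start))
    return out


@dataclass
class CoverageReport:
    n_templates: int
    n_perfect: int          # amplified with zero mismatches in both primers
    n_amplified: int        # amplified within the mismatch budget
    fraction_perfect: float
    per_template: dict[str, tuple[Optional[int], Optional[int], Optional[int]]]
    # id -> (best fwd mismatches, best rev mismatches, amplicon length or None)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": k, "fwd_mismatches": f, "rev_mismatches": r,
                 "amplicon_length": a}
                for k, (f, r, a) in self.per_template.items()]
        return pd.DataFrame(rows)


def primer_pair_coverage(fwd: DegeneratePrimer, rev: DegeneratePrimer,
                         db: Sequence[tuple[str, str]],
                         max_mismatches: int = 0,
                         size_range: tuple[int, int] = (50, 5000)) -> CoverageReport:
    """Fraction of database templates amplified with zero mismatches.

    A template counts as perfect iff a properly oriented zero-mismatch
    product exists within the size range; per_template additionally records
    the best (fewest-mismatch) site of each primer within max_mismatches and
    the shortest product length found at that budget."""
    if not db:
        raise ValueError("empty template database")
    per = {}
    n_perfect = n_amplified = 0
    budget = max(max_mismatches, 0)
    for tid, seq in db:
        f_sites = find_binding_sites(fwd, seq, budget, tid)
        r_sites = find_binding_sites(rev, seq, budget, tid)
        f_best = min((s.mismatches for s in f_sites), default=None)
        r_best = min((s.mismatches for s in r_sites), default=None)
        products = in_silico_pcr(fwd, rev, seq, budget, size_range, tid)
        length = min((len(a) for a, _, _ in products), default=None)
        n_amplified += bool(products)
        n_perfect += any(f.mismatches == 0 and r.mismatches == 0
                         for _, f, r in products)
        per[tid] = (f_best, r_best, length)
    return CoverageReport(n_templates=len(db), n_perfect=n_perfect,
                          n_amplified=n_amplified,
                          fraction_perfect=n_perfect / len(db),
                          per_template=per)


def primer_tm(primer: DegeneratePrimer, cap: int = 4096) -> tuple[float, float, float]:
    """(min, mean, max) Wallace-rule melting temperature over all expansions:
    Tm = 2(A+T) + 4(G+C) degrees C."""
    if primer.degeneracy > cap:
        raise ValueError(
            f"{primer.name}: degeneracy {primer.degeneracy} exceeds cap {cap}; "
            "sample expansions instead of exact enumeration")
    tms = [2.0 * (e.count("A") + e.count("T")) + 4.0 * (e.count("G") + e.count("C"))
           for e in expand_degenerate(primer.seq)]
    return min(tms), sum(tms) / len(tms), max(tms)


def iupac_consensus(rows: Sequence[str]) -> str:
    """Minimal IUPAC string covering every row position-wise."""
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows differ in length")
    out = []
    for col in zip(*(r.upper() for r in rows)):
        mask = 0
        for c in col:
            mask |= _CODE_MASK[c]
        out.append(_MASK_CODE[mask])
    return "".join(out)


def propose_primers(alignment: dict[str, str], window: int = 20,
                    max_degeneracy: int = 512,
                    orientation: str = "forward") -> list[tuple[DegeneratePrimer, float]]:
    """Candidate primers from conserved, gap-free alignment windows.

    Slides a window over the nucleotide alignment; windows containing a gap
    in any row are skipped.  Each window's minimal IUPAC consensus is kept
    when its degeneracy is within max_degeneracy, reported together with the
    fraction of rows it matches with zero mismatches.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 alignment rows")
    if window < 15:
        raise ValueError("window must be >= 15")
    rows = {k: v.upper() for k, v in alignment.items()}
    ncol = len(next(iter(rows.values())))
    out = []
    for start in range(0, ncol - window + 1):
        cols = [r[start:start + window] for r in rows.values()]
        if any("-" in c for c in cols):
            continue
        cons = iupac_consensus(cols)
        if degeneracy(cons) > max_degeneracy:
            continue
        seq = cons if orientation == "forward" else reverse_complement(cons)
        primer = DegeneratePrimer(name=f"win{start}", seq=seq,
                                  orientation=orientation)
        cmask = _mask_array(cons)
        hits = sum(
            int(not np.any(_mask_array(c) & ~cmask)) for c in cols)
        out.append((primer, hits / len(rows)))
    return out


def read_primer_tsv(path) -> list[DegeneratePrimer]:
    """TSV with columns name, sequence, orientation and optional head."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        out.append(DegeneratePrimer(name=r["name"], seq=r["sequence"],
                                    orientation=r["orientation"],
                                    head=r["head"] or None))
    return out
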