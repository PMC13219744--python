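"""Synthetic data emulating a functional-gene amplicon study end to end.

The generator produces (i) a reference bundle — a marker-gene orthologous
group plus a related paralogous decoy clade, evolved along a random tree
under the placement substitution model, with coding sequences carrying
degenerate-primer sites; (ii) error-bearing amplicon ASVs cut from those
coding sequences at the primer-delimited window; and (iii) a multi-sample
count table with condition labels and spiked enrichment.  Every record is
tracked in a truth table so downstream verification, placement, diversity
and enrichment can be scored against known ground truth.

All randomness flows from a single integer seed; outputs are byte-identical
across runs for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .diversity import CountMatrix
from .models import AA_ALPHABET, ModelConfig, N_STATES
from .primers import DegeneratePrimer, iupac_consensus, reverse_complement
from .resources import ReferenceEntry, ReferenceResource, RefTree
from .verify import Asv

# codons per amino acid, bacterial code, fixed order for determinism
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE11.forward_table.items()):
    _AA_CODONS.setdefault(aa, []).append(codon)

_TARGET_CLASSES = ["c__Clostridia", "c__Bacilli", "c__Gammaproteobacteria"]
_DECOY_CLASSES = ["c__Actinomycetia", "c__Bacteroidia"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the real assay's shape: a ~340 bp amplicon (primers
    included) amplified out of marker coding sequences, 1% per-base
    substitution error, triplicate samples per condition, a log-series
    community, and a handful of 8-fold spiked features in the treated
    condition.
    """

    seed: int = 42
    # reference family
    n_target_leaves: int = 24
    n_decoy_leaves: int = 12
    tree_branch_scale: float = 0.08     # mean branch length, subs/site
    clade_separation: float = 1.0       # length of each half of the stem
    protein_length: int = 240           # aa
    evolution_model: str = "LG"         # set != placement model to stress-test
    # primer window (nt coordinates on the CDS)
    amplicon_start: int = 361
    amplicon_length: int = 340          # includes both primers
    primer_length: int = 21
    primer_design_fraction: float = 0.75  # fraction of target rows used in design
    primer_head: str = "GCTATGCGCGAGCTGC"  # generic 16 nt 5' adapter
    # amplicons
    n_target_asvs: int = 50
    n_decoy_asvs: int = 20
    nt_error_rate: float = 0.01
    # community / samples
    n_samples_per_condition: int = 3
    community_model: str = "log_series"  # or "uniform"
    library_size: int = 20000
    biological_dispersion: float = 0.2   # gamma overdispersion between samples
    spike: tuple[tuple[int, float], ...] = ((0, 8.0), (1, 8.0), (2, 8.0))
    # (target-ASV index, fold change in treated)

    def __post_init__(self):
        if not 0 <= self.nt_error_rate <= 0.2:
            raise ValueError("nt_error_rate must be in [0, 0.2]")
        if self.community_model not in ("log_series", "uniform"):
            raise ValueError("community_model must be log_series or uniform")
        if self.amplicon_start + self.amplicon_length > 3 * self.protein_length:
            raise ValueError("amplicon window exceeds the coding sequence")


@dataclass
class SynthTruth:
    """Ground truth for every emitted record."""

    leaves: pd.DataFrame     # leaf id, is_target
    asvs: pd.DataFrame       # asv_id, source_leaf, is_target, strand, frame_offset
    folds: pd.DataFrame      # asv_id, true_fold


@dataclass
class SynthDataset:
    resource: ReferenceResource
    fwd_primer: DegeneratePrimer
    rev_primer: DegeneratePrimer
    asvs: list[Asv]
    counts: CountMatrix
    truth: SynthTruth


# ---------------------------------------------------------------------------
# reference simulation

def _random_clade_newick(rng: np.random.Generator, names: list[str],
                         scale: float) -> str:
    """Random topology by sequential pairwise joining, exponential lengths."""
    frags = list(names)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        a, b = frags[i], frags[j]
        la, lb = rng.exponential(scale, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)]
        frags.append(merged)
    return frags[0]


def _evolve_states(tree: RefTree, model, root_states: np.ndarray,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Simulate site-wise substitution along the tree; returns leaf states."""
    states = {0: root_states}
    nsites = root_states.size
    for v in range(1, tree.n_nodes):  # preorder: parents first
        P = model.transition_matrix(tree.parent_length[v])
        cum = P.cumsum(axis=1)
        u = rng.random(nsites)
        parent = states[tree.parent[v]]
        states[v] = (u[:, None] > cum[parent]).sum(axis=1)
    return {tree.node_name[v]: states[v] for v in range(tree.n_nodes)
            if v in tree.node_name}


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_AA_CODONS[a][rng.integers(len(_AA_CODONS[a]))]
                   for a in protein)


def _taxonomy(i: int, classes: list[str]) -> str:
    cls = classes[i % len(classes)]
    return (f"d__Bacteria;p__P{i % 2};{cls};o__O{i % 4};"
            f"f__F{i % 6};g__G{i:03d}")


def simulate_reference(config: SynthConfig) -> tuple[ReferenceResource, SynthTruth]:
    """Marker family (monophyletic target clade) plus paralogous decoys.

    Proteins evolve by per-site substitution under the configured model, so
    the placement model is well-specified by default; coding sequences are
    uniform-codon back-translations.  The alignment is gap-free (substitution-
    only evolution), and the two clades are joined by a long stem so the
    target group is monophyletic and decoys are distant homologs.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    t_names = [f"T{i:03d}" for i in range(config.n_target_leaves)]
    d_names = [f"D{i:03d}" for i in range(config.n_decoy_leaves)]
    t_frag = _random_clade_newick(rng, t_names, config.tree_branch_scale)
    d_frag = _random_clade_newick(rng, d_names, config.tree_branch_scale)
    newick = (f"({t_frag}:{config.clade_separation:.6f},"
              f"{d_frag}:{config.clade_separation:.6f});")
    tree = RefTree(newick)
    model = ModelConfig(config.evolution_model).build()
    root = rng.choice(N_STATES, size=config.protein_length,
                      p=model.frequencies)
    leaf_states = _evolve_states(tree, model, root, rng)

    entries, alignment = [], {}
    for i, name in enumerate(t_names + d_names):
        is_target = name.startswith("T")
        protein = "".join(AA_ALPHABET[s] for s in leaf_states[name])
        nt = _back_translate(protein, rng)
        classes = _TARGET_CLASSES if is_target else _DECOY_CLASSES
        entries.append(ReferenceEntry(
            id=name, protein_seq=protein, nt_seq=nt,
            label="target" if is_target else "non_target",
            taxonomy=tuple(_taxonomy(i, classes).split(";")),
            source="synthetic"))
        alignment[name] = protein
    resource = ReferenceResource(entries=entries, alignment=alignment,
                                 tree=tree, target_leaves=set(t_names))
    truth = SynthTruth(
        leaves=pd.DataFrame({"leaf": t_names + d_names,
                             "is_target": [n.startswith("T")
                                           for n in t_names + d_names]}),
        asvs=pd.DataFrame(), folds=pd.DataFrame())
    return resource, truth


def design_primers(resource: ReferenceResource,
                   config: SynthConfig) -> tuple[DegeneratePrimer, DegeneratePrimer]:
    """Degenerate primer pair from the consensus of a subset of target CDSs
    at the amplicon window's two ends (emulating design from an alignment of
    representative sequences: primers match most but not all targets)."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    targets = sorted(resource.target_leaves)
    k = max(2, int(round(config.primer_design_fraction * len(targets))))
    chosen = sorted(rng.choice(targets, size=k, replace=False))
    s, alen, plen = (config.amplicon_start, config.amplicon_length,
                     config.primer_length)
    fwd_rows = [resource.by_id[t].nt_seq[s:s + plen] for t in chosen]
    rev_rows = [resource.by_id[t].nt_seq[s + alen - plen:s + alen]
                for t in chosen]
    fwd = DegeneratePrimer(name="SYNF", seq=iupac_consensus(fwd_rows),
                           orientation="forward", head=config.primer_head)
    rev = DegeneratePrimer(name="SYNR",
                           seq=reverse_complement(iupac_consensus(rev_rows)),
                           orientation="reverse", head=config.primer_head)
    return fwd, rev


# ---------------------------------------------------------------------------
# amplicon + community simulation

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_amplicons(resource: ReferenceResource, config: SynthConfig
                       ) -> tuple[list[Asv], CountMatrix, SynthTruth]:
    """Error-bearing amplicon ASVs with a spiked multi-sample count table.

    Reads are cut from source CDSs at the primer-delimited window, mutated
    at the per-base error rate, and emitted on a random strand.  Identical
    sequences are merged (as a denoiser would).  Counts follow the
    community model with multiplicative gamma noise between samples
    (negative-binomial marginals) and multinomial sampling to the library
    size; spiked features are multiplied in the treated condition.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    targets = sorted(resource.target_leaves)
    decoys = sorted(set(resource.tree.leaf_names) - resource.target_leaves)
    s, alen = config.amplicon_start, config.amplicon_length
    frame_offset = (3 - s % 3) % 3  # first in-frame codon start within the read

    recs = []
    for kind, pool, n in (("target", targets, config.n_target_asvs),
                          ("decoy", decoys, config.n_decoy_asvs)):
        if not pool or n == 0:
            continue
        sources = rng.choice(pool, size=n, replace=True)
        for src in sources:
            read = resource.by_id[src].nt_seq[s:s + alen]
            read = _mutate(read, config.nt_error_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            emitted = read if strand == "+" else reverse_complement(read)
            recs.append({"seq": emitted, "source_leaf": src,
                         "is_target": kind == "target", "strand": strand})

    # merge identical sequences (denoised ASVs are unique by definition)
    merged: dict[str, dict] = {}
    for r in recs:
        merged.setdefault(r["seq"], r)
    asv_ids = {}
    rows = []
    for i, (seq, r) in enumerate(merged.items()):
        aid = f"asv{i + 1:04d}"
        asv_ids[seq] = aid
        rows.append({"asv_id": aid, "source_leaf": r["source_leaf"],
                     "is_target": r["is_target"], "strand": r["strand"],
                     "frame_offset": frame_offset})
    truth_asvs = pd.DataFrame(rows)

    n_asv = len(rows)
    if config.community_model == "log_series":
        weights = rng.logseries(0.98, size=n_asv).astype(float)
    else:
        weights = np.ones(n_asv)
    spike_map = np.ones(n_asv)
    target_rows = truth_asvs.index[truth_asvs.is_target].to_numpy()
    for idx, fold in config.spike:
        if idx < target_rows.size:
            spike_map[target_rows[idx]] = fold
    folds = pd.DataFrame({"asv_id": truth_asvs.asv_id,
                          "true_fold": spike_map})

    nspc = config.n_samples_per_condition
    samples, condition = [], {}
    counts = {}
    disp = config.biological_dispersion
    for cond, fold_vec in (("control", np.ones(n_asv)), ("treated", spike_map)):
        for r in range(nspc):
            name = f"{cond}_{r + 1}"
            samples.append(name)
            condition[name] = cond
            w = weights * fold_vec
            if disp > 0:
                w = w * rng.gamma(1.0 / disp, disp, size=n_asv)
            counts[name] = rng.multinomial(config.library_size, w / w.sum())
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=truth_asvs.asv_id.tolist()),
        condition=condition)

    asvs = []
    for seq, aid in asv_ids.items():
        per_sample = {sm: int(cm.counts.at[aid, sm]) for sm in samples}
        asvs.append(Asv(id=aid, nt_seq=seq, counts=per_sample))
    truth = SynthTruth(leaves=pd.DataFrame(), asvs=truth_asvs, folds=folds)
    return asvs, cm, truth


def simulate_dataset(config: SynthConfig = SynthConfig()) -> SynthDataset:
    """Full bundle: reference, primers, ASVs, counts and truth."""
    resource, ref_truth = simulate_reference(config)
    fwd, rev = design_primers(resource, config)
    asvs, counts, amp_truth = simulate_amplicons(resource, config)
    truth = SynthTruth(leaves=ref_truth.leaves, asvs=amp_truth.asvs,
                       folds=amp_truth.folds)
    return SynthDataset(resource=resource, fwd_primer=fwd, rev_primer=rev,
                        asvs=asvs, counts=counts, truth=truth)


def simulate_community_counts(n_features: int, model: str, library_size: int,
                              n_samples: int, seed: int) -> CountMatrix:
    """Counts-only community generator (for diversity/rarefaction studies):
    a species-poor 'gut-like' community is uniform over few features, a
    species-rich 'rumen-like' one is a log-series over many."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    if model == "log_series":
        weights = rng.logseries(0.98, size=n_features).astype(float)
    elif model == "uniform":
        weights = np.ones(n_features)
    else:
        raise ValueError("model must be log_series or uniform")
    counts = {f"s{i + 1}": rng.multinomial(library_size, weights / weights.sum())
              for i in range(n_samples)}
    feats = [f"f{i + 1:04d}" for i in range(n_features)]
    return CountMatrix(counts=pd.DataFrame(counts, index=feats))


def simulate_nb_matrix(n_features: int, n_per_group: int, mean: float,
                       dispersion: float, seed: int,
                       fold: float = 1.0, n_spiked: int = 0) -> CountMatrix:
    """Independent negative-binomial counts for two conditions; the first
    n_spiked features have `fold`-times the mean in the treated group.
    Used for calibration studies of the differential-abundance test."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 5)))
    r = 1.0 / dispersion
    means = np.full(n_features, float(mean))
    t_means = means.copy()
    t_means[:n_spiked] *= fold
    cols, condition = {}, {}
    for g, mu in (("control", means), ("treated", t_means)):
        for i in range(n_per_group):
            name = f"{g}_{i + 1}"
            p = r / (r + mu)
            cols[name] = rng.negative_binomial(r, p)
            condition[name] = g
    feats = [f"f{i + 1:04d}" for i in range(n_features)]
    return CountMatrix(counts=pd.DataFrame(cols, index=feats),
                       condition=condition)
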