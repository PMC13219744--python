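# Methods

This note documents the models and procedures implemented in `sqamp`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic data generator does and does not emulate.

## Reference bundle and edge numbering

A reference resource couples a protein database (validated marker sequences
labeled `target`, related family members labeled `non_target`), a gap-aware
multiple alignment, an unrooted tree with branch lengths, and the set of
target leaves. Loading validates all cross-references: every tree leaf and
alignment row must exist in the database, alignment rows must ungap to
their database protein, coding sequences must translate to their protein in
frame 1 (bacterial code, trailing stop allowed), and branch lengths must be
non-negative.

Placement output is only reproducible if edge numbers are a pure function
of the input file. Edges are therefore numbered by depth-first preorder
anchored at the first leaf in the Newick text, visiting children in file
order; the edge between the anchor leaf and its neighbour is edge 0. A
bifurcating root in the input is collapsed (branch lengths summed) so the
tree is treated as unrooted; writing a bundle back to disk and reloading it
reproduces entries, alignment, topology and edge numbers exactly.

The *target clade* is the edge set of the minimal spanning subtree
connecting the target leaves, plus the stem edge whenever one side of some
edge contains exactly the target leaves (i.e. the targets are clade-like).
A query whose best placement lands on the stem is counted as verified:
stem placements are target-adjacent by construction. For non-clade target
sets no stem exists and only the path edges are used.

## Primer model

Primer/template matching is positional set membership with no indels — the
PCR-realistic model that keeps the search exact. A template position
matches when its base is in the primer position's IUPAC set; an ambiguous
template code matches only when the primer set is a superset of the
template set (conservative: an `R` in the template is only "covered" by a
primer position that allows both A and G). Reverse primers are scanned as
their reverse complement on the plus strand and reported with strand `-`.
In-silico PCR reports every properly oriented forward/reverse site pair
within the size window; amplicon lengths include both primer footprints,
matching how product sizes are read off a gel. Coverage of a primer pair
over a database is the fraction of templates with a zero-mismatch product
(reported to 0.1%), alongside the fraction amplified within the mismatch
budget. Melting temperatures use the Wallace rule, 2(A+T) + 4(G+C) °C, over
exact enumeration of expansions (capped at degeneracy 4096);
nearest-neighbor thermodynamics is out of scope. Candidate primers are
proposed as the minimal IUPAC consensus of gap-free alignment windows,
filtered by a degeneracy cap.

## Verification: translation and homology

Amplicons are gene-internal fragments, so all six conceptual translations
are computed with start-codon handling disabled; stops render as `*`, codons
containing N as `X`. The frame/strand whose peptide best locally aligns to
any reference protein wins (BLOSUM62, gap open −11, extend −1); ties break
toward fewer internal stops, then the plus strand, then the lower frame.

The homology filter accepts a peptide as a marker *candidate* when its best
local hit against the reference database (target or decoy — clade
membership is decided later by placement) reaches 40% identity over the
aligned span and a normalized score of 0.8. The normalized score is the
local alignment score divided by the query peptide length: per-query-residue
normalization cleanly separates family members (≈ 2–5 per residue) from the
short, high-scoring chance alignments of unrelated sequences (≈ 0.3 per
residue), which a per-aligned-column score cannot do. Both thresholds were
calibrated once on simulated reads versus random-sequence nulls (false
candidate rate < 1%) and frozen as defaults.

Internal stop codons are a pseudogene/frameshift signal, but at a 1%
per-base error rate more than 10% of genuine marker reads of ~340 nt acquire
an error-induced stop, so a zero-tolerance rule would cost over ten points
of sensitivity. The filter therefore tolerates one stop inside the aligned
span (configurable `max_span_stops`, default 1) and excludes at two or
more. Failure reasons are evaluated in the order too_short (< 100 nt /
< 33 aa), internal_stop, no_homology.

## Phylogenetic placement

Candidate peptides are mapped into reference coordinates by a global
profile alignment: the profile score of residue *a* at column *c* is the
mean BLOSUM62 score of *a* against the column's non-gap residues; skipping
a column costs affine penalties scaled by the column's non-gap fraction
(mostly-gap columns are nearly free to skip); query residues inserted
relative to the reference are discarded. Queries with fewer than half their
residues mapped are flagged unplaceable.

Placement follows the evolutionary placement algorithm's structure: the
query is attached by a pendant branch to the midpoint of each reference
edge in turn, the pendant length is optimized by golden-section search on
[1e-8, 5.0] substitutions/site (tolerance 1e-5, with an explicit
lower-boundary check so self-placements hit the floor), and the best edge
wins; like-weight ratios are the softmax of per-edge log-likelihoods.
Deviating from full EPA, the attachment point is fixed at the edge midpoint
rather than optimized along the edge — for verification-grade placement the
extra parameter changes almost nothing, and the brute-force comparisons in
the test suite confirm best-edge agreement and log-likelihoods within 1e-3.

Likelihoods use the LG amino-acid replacement model by default (equilibrium
frequencies of the model; an equal-rates Poisson model is available, and a
4-category Γ is deliberately left as an extension since the assay's
verification decision is insensitive to rate heterogeneity at these
divergences). Gaps and X are missing data (a vector of ones), never a 21st
state. The engine computes two-pass conditional likelihoods — "down"
partials below each edge and "up" partials for the rest of the tree, with
per-site scaling against underflow — so each edge × pendant evaluation
costs O(states² × sites) and a 70-edge tree places a query in ~10 ms.
Reversibility makes the anchored traversal direction irrelevant (pulley
principle); this is property-tested against a naive implementation that
rebuilds the whole tree per evaluation.

A query is *verified* when its best edge lies in the target clade (best-edge
rule; accumulating LWR over the clade is a possible alternative but the
best-edge rule is simpler and performed identically on synthetic data).
Clades for reporting are contiguous runs of edges sharing target status,
numbered by smallest edge id. jplace v3 output carries the edge-annotated
tree, fields `[edge_num, likelihood, like_weight_ratio, distal_length,
pendant_length]` (distal = half the attachment edge, by the midpoint
convention), and each ASV's read multiplicity.

## OTU clustering

Greedy abundance-sorted centroid clustering, as vsearch does it: ASVs in
decreasing total-count order (ties lexicographic by id) join the first
centroid whose global-alignment identity reaches the threshold, else found
a new cluster. Identity is matches over alignment columns excluding
terminal-gap columns — one of several definitions in circulation, stated
here explicitly; a best-match variant is available behind a flag.
Nucleotide (not peptide) identity is used, matching common vsearch usage;
the default threshold 0.90 approximates species-level groups for this
marker.

## Alpha diversity

Counts are rarefied without replacement (multivariate hypergeometric draw),
matching the "subsample to fixed depths" convention; depths default to 100,
1000 and 10000 with 10 replicates (replicate count is a free choice; 10
gives sub-1% SE on richness at these depths). Shannon uses natural log;
Simpson is reported as Gini–Simpson 1 − Σp². Samples shallower than a
requested depth are skipped with a warning, not an error, so one shallow
library cannot abort a run. Replicate seeds are spawned deterministically
from the base seed, making profiles bit-reproducible.

## Taxonomy

Best-hit classification with a hard floor: the top-scoring local alignment
against the genome-protein database assigns its taxonomy only when span
identity ≥ 90% (ties: higher identity, then lexicographic id), otherwise
the query is `unclassified`. Identity is computed over the local alignment
span, consistent with the homology filter. Multi-copy marker genes are
separate database entries sharing a taxonomy string. Per-clade composition
tables report taxon percentages per placement clade, with unclassified as
its own category, summing to 100 within each clade.

## Differential abundance

A deliberately simplified negative-binomial test, not a DESeq2 wrapper:
median-of-ratios size factors (median over all-positive features of
count/geometric mean; total-count fallback with a warning when no feature
is positive everywhere), per-feature method-of-moments dispersion from the
within-group variance of normalized counts pooled across both groups, a
delta-method Wald statistic on the log2 fold-change, two-sided normal
p-values, significance at raw p < alpha (default 0.01), and BH q-values
reported for FDR-minded users.

Two numerical choices matter. First, with triplicates the raw per-feature
dispersion estimate has ~4 degrees of freedom and a normal Wald test built
on it is badly anti-conservative (measured type-I ≈ 0.06 at nominal 0.01);
each feature's dispersion is therefore floored at the across-feature mean
dispersion — a conservative pooling in the spirit of edgeR's common
dispersion, not an empirical-Bayes shrinkage. Measured on 2000-feature null
simulations (mean 50, dispersion 0.2, 3 vs 3) the type-I error is
0.006–0.011 across seeds, with power ≥ 0.9 for 8-fold spikes at mean 50.
Second, the 0.5 pseudocount in the fold-change exists to handle zero
groups, so it is applied only when a group mean is zero; fold-changes on
all-positive features are then exactly invariant to rescaling any single
sample's counts (size factors absorb the rescaling).

## Synthetic data

The generator emulates the study's inputs end to end so every stage is
testable offline. A target clade and a decoy clade are simulated as random
sequentially-joined topologies (exponential branch lengths, mean 0.08
substitutions/site) joined by a long stem (1.0 per side), making the
targets monophyletic and the decoys distant-but-detectable homologs — the
GH31 situation that makes placement necessary. Proteins (240 aa) evolve by
per-site substitution under the placement model itself, so the model is
well-specified for recovery tests; a misspecification stress-test is
available by evolving under the Poisson model instead
(`evolution_model="poisson"`). Coding sequences are uniform-codon
back-translations; the alignment is gap-free because evolution is
substitution-only.

A degenerate primer pair is designed from the consensus of a random 75%
subset of target coding sequences at the two ends of a 340 nt window
(21 nt primers, generic 16 nt 5′ head), emulating design from an alignment
of representatives: primers match most but not all targets, so coverage is
realistically below 100%. Amplicons are cut at the window (the window start
is deliberately not a codon boundary, so frame recovery is exercised),
mutated at a per-base substitution rate (default 1%), and emitted on a
random strand; identical sequences are merged as a denoiser would. Counts
follow a log-series (species-rich) or uniform (species-poor) community,
with per-sample gamma multiplicative noise (dispersion 0.2, giving
negative-binomial marginals) and multinomial sampling to a 20000-read
library; spiked features (default: the first three target ASVs at 8-fold)
are multiplied in the treated condition. Defaults: 24 target + 12 decoy
leaves, 50 target + 20 decoy-derived ASVs, 3 samples per condition,
seed 42.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: indel sequencing errors and homopolymer
artifacts, PCR chimeras, primer-biased amplification efficiency, quality
scores (FASTQ emission is out of scope), compositional biases beyond
closure, reference databases with alignment gaps/fragments, and
rate-heterogeneous or covarion-like protein evolution. Real-data thresholds
(homology floors, the 90% identity floors) should be re-examined against
curated references rather than taken from the simulation.

## Pipeline

`run(config)` executes resources → verify → place → otu → diversity →
taxonomy → enrich single-process and deterministically given the config
seeds. The YAML config is schema-validated with unknown keys rejected.
Outputs include per-stage TSVs, a jplace file, a per-sample
verified/excluded summary (percent of reads and of ASVs verified — read
counts are conserved across every stage boundary, with exclusions
itemized), a clade × taxon composition table, and a JSON manifest carrying
the tool version, a hash of the analysis parameters (the output path is
excluded so reruns compare equal) and per-stage record counts. In synthetic
mode the reference entries double as the taxonomy database; with real
inputs a separate genome-protein FASTA + taxonomy TSV is supplied.

## Problem sizes used in the checks

The automated checks run the default synthetic conditions (36 reference
proteins, 70 ASVs), 8–20 random 8-leaf bundles for brute-force placement
comparisons, 2000-feature null/power simulations for the test calibration,
and 100 randomized instances per combinatorial oracle (degenerate matching,
greedy clustering, taxonomy identity) — sizes at which the brute-force
oracles remain exact and fast while exercising every code path.
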