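# Methods

## Genome distance

The distance between two phage genomes is one minus the fraction of their
combined length covered by ORFs with reciprocal best hits (RBH) in the
partner genome. ORFs are called per stop-to-stop segment in each of the six
reading frames: the longest ORF of a segment (earliest start codon among
ATG/GTG/TTG after the previous stop) is emitted if its length, stop codon
included, is at least 75 nt. Nested shorter ORFs are not emitted — the
convention of standard prokaryotic ORF callers — while ORFs in different
frames may overlap freely. Genomes are treated as linear, and a trailing
ORF that reaches the sequence end without a stop codon is kept, since phage
genome records are often circularly permuted mid-gene. Codons containing N
match neither start nor stop; they translate to X.

Alignment is Smith–Waterman under BLOSUM62 with affine gaps costing
11 + k for a gap of length k (the NCBI convention for "open 11, extend 1").
Bit scores use fixed Karlin–Altschul constants (λ = 0.267, K = 0.041, the
standard gapped BLOSUM62-11-1 values) and e-values the per-pair m·n search
space, with n the residue total of the subject proteome. These e-values
are thresholds, not calibrated significance: the RBH stage admits hits with
e ≤ 1e-3 and query coverage ≥ 0.5, and best hits are chosen by bit score
with deterministic tie-breaks (longer alignment, then lexicographically
smaller subject id).

Two interchangeable engines implement the all-vs-all search. The exact
engine runs the full dynamic programme over every ORF pair (numba kernels:
a score-only pass, plus a span-tracking pass evaluated only for candidate
best hits, so the coverage filter never needs a traceback matrix). The
default engine pools all proteomes into a single BLASTP run
(`-comp_based_stats 0 -seg no`, one thread) and re-derives per-pair
e-values from the BLAST raw scores under the package's own convention, so
qualification rules are identical; its report cutoff is widened by the
ratio of pooled to per-proteome search space so no per-pair-qualifying hit
is lost at report time. On simulated data the engines agree exactly on all
within-clade pairs; the heuristic engine may miss marginal hits between
deeply diverged genomes, shifting distances already near saturation by a
few percent. Coverage terms take the union of ORF intervals on genome
coordinates across both strands, and the matrix diagonal is fixed at zero
(the raw formula would give a genome's intergenic fraction against itself,
which has no phylogenetic meaning).

## Tree construction, ultrametrization, clades

The tree is classic neighbor joining on the distance matrix — exact on
additive inputs and deterministic given taxon order — followed by midpoint
rooting, which is parameter-free. Negative branch-length estimates are
clamped to zero. Ultrametrization then proceeds in one post-order pass: at
each internal node the stem-inclusive child heights `H_i` are averaged to
`H_0` and all edges of child subtree *i*, including its stem edge, are
multiplied by `H_0/H_i`. Scaling the stem edge along with the subtree is
forced by the goal of the operation — rescaling only internal edges cannot
equalize leaf depths at the parent. A zero-height child branch cannot be
rescaled, so its stem is set to `H_0` directly, the limiting behaviour.
Multifurcations average over all children. The operation is idempotent,
topology-preserving and leaves all leaf depths equal to machine precision
(observed relative spread < 1e-15).

Clades are the maximal subtrees of height ≤ d on the ultrametric tree,
found by descending from the root and stopping at the first node whose
subtree fits; d defaults to 0.15, about one third of typical tree height.
Height comparisons carry a 1e-9 relative tolerance, used consistently for
both the height and the parent-maximality condition, so the clade sets are
stable against rounding. Singleton clades are kept but flagged;
heterogeneity analysis uses only clades with at least two genomes.

## DNAP classification and subgrouping

Classification is a single best-hit pass against a labeled reference FASTA
(family = last |-separated header token): an ORF whose best reference hit
reaches e ≤ 1e-4 inherits that reference's family, one call per ORF.
Within a family, calls are clustered single-linkage on global pairwise
identity (matches / alignment columns, Needleman–Wunsch with the same
scoring as the local search) at a 0.5 threshold; subgroup labels are the
family letter plus an ordinal by decreasing cluster size. Subgroups of
deeply diverged collections can fragment — two proteins of the same
ancestral lineage separated by enough divergence fall below 0.5 identity
and land in different subgroups unless intermediates chain them — so
subgroup-level swap counts are upper bounds that include this fragmentation
alongside genuine intra-family replacements.

## Heterogeneity, swapping clades, event counting

Within each multi-genome clade, two heterogeneity types are distinguished:
type I — at least two families among genomes carrying exactly one DNAP
(the swap signature); type II — one genome carrying two DNAPs of different
families. Each type-I clade is extended upward while a sister subtree
contains at least one DNAP-encoding genome, the most conservative reading
of sister grouping; overlapping groups are deduplicated to maximal ones.

Events are counted by Fitch small parsimony on the genome tree over the
swapping clade: leaves carry their called family (or family:subgroup), a
genome with two different-family DNAPs carries both as admissible states,
and genomes without a call carry the full state set — absence of a
polymerase is not evidence of a transition. Multifurcating nodes merge
child state sets sequentially in child order, counting each empty
intersection as one change; on binary trees this is the classic algorithm,
and both cases are validated against an exhaustive minimum over ancestral
labelings. Counting on the genome tree alone is a deliberate
simplification of reconciling genome and polymerase trees by hand: it
equals the number of independently planted events whenever each event
occupies its own branch, but can undercount reticulate histories in which
the same donor lineage seeded multiple acquisitions.

## Synthetic data

The simulator emulates the statistical structure the analysis assumes, at
desk scale. Defaults: 32 genomes of 20 genes × 300 nt with 100-nt spacers
(~8 kb per genome — an order of magnitude below real phage genomes, with
proportionally fewer genes), Yule topology rescaled to height 0.4 expected
substitutions/site, Jukes–Cantor substitution at rate 1 per site per unit
height. With these values, protein identities between genomes span the
full detectability range of the RBH search: within shallow clades nearly
every ORF keeps its ortholog (distances near the intergenic floor), while
across the tree hits progressively drop out, which is what gives the
distance matrix its signal. Real inter-genome distances are driven largely
by gene-content turnover; the simulator does not model gene gain/loss,
recombination or rearrangement, so divergence-driven hit dropout and the
decay of spurious spacer ORFs stand in for it. Passing tests therefore
demonstrate correctness of the inference machinery under the model's
assumptions, not robustness to mosaic genome evolution.

Genes are kept intact along the whole tree: substitutions that would write
an internal in-frame stop are redrawn among the remaining alternatives, and
the start codon and terminal stop are confined to their codon classes
(violating draws reverted). This biases observed divergence below the
Jukes–Cantor expectation by well under one standard error at the simulated
sizes. DNAP families are mutually unrelated random genes (~5% expected
protein identity); subgroups are variants of the family exemplar at ~40%
protein identity — unambiguous family members that still fall below the
0.5 subgrouping threshold, so intra-family swaps are observable.

A planted swap replaces the DNAP gene slot at the top of a chosen branch
with the new family/subgroup exemplar, which then continues to evolve
through the subtree below; flanking genes are untouched (the in-situ
property). Swap branches for the validation study are chosen
deterministically: small internal subtrees (≥ 2 leaves), pairwise disjoint
and non-sister, preferring branches whose parent subtree is shallow
(≤ 0.2 × tree height) so swapped genomes keep unswapped relatives inside
one fixed-depth clade, and spread to maximize separation — planted events
then remain independent changes on the reconstructed tree, with the
repeated family assigned to the most distant branch pair. An optional
second DNAP slot (the next gene slot) produces two-polymerase genomes for
exercising type-II heterogeneity.

All generation is driven by one seeded NumPy generator in fixed traversal
order; identical configurations reproduce identical files byte for byte.

## Validation study sizes

The standard planted-swap study runs 20 replicates of 32 genomes / 20
genes / 3 inter-family swaps — small enough that the whole suite and the
acceptance script each finish in minutes on one CPU while every stage
(distances, tree, clades, classification, counting) is exercised at
realistic clade structure. Oracle comparisons use 200 random sequences
(ORFs), 100 random 80-aa pairs (alignment), 100 random additive matrices
of 5–8 taxa (neighbor joining), 200 random trees of up to 20 leaves
(ultrametrization) and 200 random trees of up to 10 leaves with up to 4
states and wildcard leaves (Fitch).

## Known limitations

- Best-hit classification replaces iterative profile search; very remote
  DNAP homologs that only profiles would find are out of reach, which is
  immaterial on simulated data with controlled reference divergence but
  matters for real divergent families.
- The heuristic BLAST engine slightly underestimates coverage between
  near-saturated genome pairs (distances already > ~0.4).
- Subgroup-level swap counts include subgroup fragmentation of deeply
  diverged backgrounds (see above); family-level counts are unaffected.
- Direction of swaps, donor identification and synteny verification of the
  in-situ property are outside the package's scope.
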