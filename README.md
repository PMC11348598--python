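# polswap

Detection of DNA-polymerase gene swapping in tailed-phage genomes.

Tailed bacteriophages (*Caudoviricetes*) replicate their genomes with a DNA
polymerase (DNAP) from one of three essentially unrelated families — PolA,
PolB or PolC. Replicative polymerases are among the most conserved proteins
known, yet closely related phages sometimes carry DNAPs of *different*
families in otherwise conserved genomic contexts: the polymerase gene was
replaced "in situ" during evolution. `polswap` is a whole-genome
comparative pipeline for finding and counting such replacements, together
with a synthetic genome simulator that plants swaps with known ground truth
so every stage can be validated without downloading real data.

## Method

For genomes *A*, *B*, all ORFs ≥ 75 nt (six frames, genetic code 11,
prokaryotic start codons) are compared by local alignment; reciprocal best
hits (RBH) covering ≥ 50% of the query define orthologs, and the genome
distance is

```
D(A,B) = 1 − (C_AB + C_BA) / (L_A + L_B)
```

where `C_AB` is the length of genome *A* covered by ORFs with an RBH in
genome *B* and `L_A` is the genome length. A neighbor-joining tree built
from `D` is midpoint-rooted and **ultrametrized** by iteratively balancing
subtrees from the leaves toward the root: at a node with child subtree
heights `H_i` (stem edge included), every edge of subtree *i* is scaled by
`q_i = H_0 / H_i` with `H_0 = mean(H_i)`, so all leaves end up exactly
equidistant from the root. The tree is then cut into its maximal subtrees
of height ≤ 0.15 (≈ genus level; about 1/3 of the tree depth).

Each genome's ORFs are classified into DNAP families by best hit against a
labeled reference set (e-value ≤ 1e-4) and subgrouped by single-linkage
clustering of global identity at 0.5. Clades whose genomes carry
single-copy DNAPs of different families are swap hotspots (type-I
heterogeneity; a genome carrying two different-family DNAPs is type-II).
Hotspots are extended through DNAP-bearing sister subtrees into maximal
swapping clades, and the minimum number of replacement events in each is
counted by Fitch small parsimony on the genome tree — on family states for
inter-family swaps, and on family+subgroup states to include replacement by
a divergent polymerase of the same family. Genomes without a recognized
DNAP are wildcards and never force a change.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_tree_and_clades.py` prints:

```
NJ tree: leaf depths 0.306 .. 0.389 (not ultrametric)
after balancing: all leaf depths = 0.363701 (spread 5.55e-17)
tree height: 0.364

clades at depth 0.15 (3 subtrees):
  clade0000: height 0.017, 2 genomes ['G000', 'G001']
  clade0001: height 0.085, 3 genomes ['G002', 'G003', 'G004']
  clade0002: height 0.090, 5 genomes ['G006', 'G005', 'G007', 'G009', 'G008']
```

i.e. after balancing, every leaf sits exactly 0.364 distance units below
the root, and cutting at 0.15 splits the ten simulated genomes into three
shallow clades. `examples/04_detect_swaps.py` then runs the full analysis
on a dataset with one planted inter-family and one intra-family swap and
reports the hotspot clade and its parsimony swap counts.

From the shell, the same pipeline runs as
`polswap run --config run.json` (see `polswap --help` for the per-stage
subcommands `find-orfs`, `distance`, `tree`, `clades`, `classify`,
`detect`, `simulate`).

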