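"""Synthetic phage-genome datasets with planted DNA-polymerase swaps.

The generator emulates the statistical structure the analysis assumes:
collections of gene-dense genomes related by an ultrametric phylogeny, with
high nucleotide identity inside shallow clades, and a designated DNAP gene
slot that is replaced *in situ* (flanking genes untouched) by a polymerase
of an unrelated family, or of a divergent subgroup of the same family, on
selected branches.

Design of the sequence model:

* Topologies are Yule (pure-birth) trees rescaled to a fixed height, so
  clade structure spans the whole range from near-identical genomes to pairs
  whose proteins fall below alignment detectability — which is what gives
  the RBH-coverage distance its signal.
* Sequences evolve by Jukes–Cantor substitution; the per-branch probability
  that a site differs from its ancestor is p = 3/4·(1 − exp(−4/3·r·t)).
  Substitutions that would write an internal stop codon into a gene are
  redrawn, and the start and terminal stop codons are confined to their
  codon classes, so every gene remains one intact ORF in every genome.
* DNAP families are represented by mutually unrelated random genes
  (expected protein identity a few percent, far below detection thresholds);
  subgroups within a family are divergent variants of the family exemplar
  (~40% protein identity: clearly the same family to a best-hit search, but
  below the 0.5 identity threshold that separates subgroups).

Gene gain/loss, recombination and rearrangement are deliberately absent;
divergence-driven loss of alignment detectability stands in for the gene
content turnover that drives distances between real phage genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .orfs import GenomeRecord
from .classify import ReferenceDb, RefProtein
from .align import encode_protein  # noqa: F401  (re-exported convenience)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_tree",
    "evolve_genomes",
    "plant_swaps",
    "emit_dataset",
    "simulate_dataset",
    "choose_swap_branches",
    "jc_p",
]

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA
_STARTS = {(0, 3, 2), (2, 3, 2), (3, 3, 2)}  # ATG, GTG, TTG
FAMILY_NAMES = ("PolA", "PolB", "PolC")


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a desk-scale stand-in for a family-level collection of
    tailed-phage genomes: 32 genomes of 20 genes x 300 nt with 100-nt
    spacers (~8 kb), tree height 0.4 expected substitutions/site so that
    protein identities span the detectability range of the RBH search.
    """

    n_leaves: int = 32
    tree_height: float = 0.4
    n_genes: int = 20
    gene_len: int = 300
    spacer_len: int = 100
    sub_rate: float = 1.0
    n_families: int = 3
    root_family: str = "PolA"
    dnap_slot: int | None = None  # gene index; default: middle gene
    #: (branch name, new family, new subgroup ordinal) replacement events
    swap_events: list[tuple[str, str, int]] = field(default_factory=list)
    #: like swap_events but inserting a second DNAP at slot dnap_slot+1,
    #: producing genomes that carry two DNAPs of different families
    dual_dnap_events: list[tuple[str, str, int]] = field(default_factory=list)
    #: Jukes-Cantor per-site difference probability between a family
    #: exemplar and its subgroup variants (~40% protein identity)
    subgroup_nt_div: float = 0.27
    n_subgroups: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ConfigError("n_leaves must be >= 3")
        if self.gene_len < 75 or self.gene_len % 3:
            raise ConfigError("gene_len must be >= 75 and a multiple of 3")
        if min(self.n_genes, self.spacer_len) <= 0 or self.tree_height <= 0:
            raise ConfigError("counts and tree height must be positive")
        if not 1 <= self.n_families <= 3:
            raise ConfigError("n_families must be in 1..3")
        if self.dnap_slot is None:
            self.dnap_slot = self.n_genes // 2
        branches = [e[0] for e in self.swap_events]
        if len(set(branches)) != len(branches):
            raise ConfigError("conflicting swap events on the same branch")

    @property
    def families(self) -> tuple[str, ...]:
        return FAMILY_NAMES[: self.n_families]

    def gene_span(self, slot: int) -> tuple[int, int]:
        """Genome coordinates [start, end) of gene ``slot`` (fixed layout:
        spacer, gene, spacer, gene, ..., spacer)."""
        start = self.spacer_len + slot * (self.gene_len + self.spacer_len)
        return start, start + self.gene_len

    @property
    def genome_len(self) -> int:
        return self.n_genes * self.gene_len + (self.n_genes + 1) * self.spacer_len


def jc_p(rate: float, t: float) -> float:
    """Jukes–Cantor probability that a site differs after time t."""
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * t))


# ---------------------------------------------------------------------------
# Tree simulation


def simulate_tree(n_leaves: int, tree_height: float, seed: int | np.random.Generator) -> TreeNode:
    """Yule pure-birth topology rescaled to an exact ultrametric height.

    The root is the first split; after the n-th leaf appears the present is
    set one further exponential waiting time later.  Leaves are named
    G000..; internal nodes N00.. in preorder (stable branch identifiers for
    planting swap events).
    """
    if n_leaves < 3:
        raise ConfigError("n_leaves must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = TreeNode()
    birth: dict[int, float] = {id(root): 0.0}
    active = [root]
    t = 0.0
    # root splits at time zero
    for _ in range(2):
        c = TreeNode()
        birth[id(c)] = 0.0
        root.append(c)
    active = list(root.children)
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        for _ in range(2):
            c = TreeNode()
            birth[id(c)] = t
            node.append(c)
        active.extend(node.children)
    t += rng.exponential(1.0 / len(active))
    scale = tree_height / t if t > 0 else 1.0
    for node in root.traverse(include_self=True):
        if node.is_tip():
            node.length = (t - birth[id(node)]) * scale
        elif node is root:
            node.length = 0.0
        else:
            child_birth = birth[id(node.children[0])]
            node.length = (child_birth - birth[id(node)]) * scale
    n_int = 0
    n_leaf = 0
    for node in root.preorder(include_self=True):
        if node.is_tip():
            node.name = f"G{n_leaf:03d}"
            n_leaf += 1
        else:
            node.name = f"N{n_int:02d}"
            n_int += 1
    return root


# ---------------------------------------------------------------------------
# Sequence evolution


def _random_gene(gene_len: int, rng: np.random.Generator) -> np.ndarray:
    """ATG + stop-free interior codons + TAA, encoded 0..3 = ACGT."""
    n_codons = gene_len // 3
    gene = np.empty(gene_len, np.uint8)
    gene[:3] = (0, 3, 2)  # ATG
    for k in range(1, n_codons - 1):
        while True:
            codon = tuple(rng.integers(0, 4, 3))
            if codon not in _STOPS:
                break
        gene[3 * k : 3 * k + 3] = codon
    gene[-3:] = (3, 0, 0)  # TAA
    return gene


def _mutate_free(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Unconstrained Jukes–Cantor step: each site differs with probability p,
    changed sites uniform over the other three nucleotides."""
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.shape[0]) < p)[0]
    if hit.size:
        out[hit] = (out[hit] + 1 + rng.integers(0, 3, hit.size)) % 4
    return out


def _mutate_gene(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """JC step on a gene, keeping the reading frame intact.

    Internal codons that become stops are redrawn (the mutated positions get
    fresh alternatives until the codon is not a stop); the start codon must
    stay in {ATG, GTG, TTG} and the terminal codon a stop, otherwise those
    mutations are reverted.
    """
    out = _mutate_free(seq, p, rng)
    n = seq.shape[0]
    # start codon: confined to the start-codon class
    if tuple(out[:3]) not in _STARTS:
        out[:3] = seq[:3]
    # terminal codon: stays a stop
    if tuple(out[-3:]) not in _STOPS:
        out[-3:] = seq[-3:]
    # internal codons: redraw until stop-free
    for k in range(1, n // 3 - 1):
        codon = out[3 * k : 3 * k + 3]
        if tuple(codon) in _STOPS:
            changed = np.nonzero(codon != seq[3 * k : 3 * k + 3])[0]
            while tuple(codon) in _STOPS:
                for j in changed:
                    codon[j] = (seq[3 * k + j] + 1 + rng.integers(0, 3)) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return _NT[arr].tobytes().decode()


_AA_TABLE: dict[tuple[int, int, int], str] = {}


def _translate(gene: np.ndarray) -> str:
    """Protein of an encoded gene (initiator -> M, terminal stop dropped)."""
    from .orfs import translate_cds

    return translate_cds(_decode(gene))


def evolve_genomes(
    tree: TreeNode, config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, GenomeRecord]:
    """Evolve a root genome down the tree; one GenomeRecord per leaf.

    The root genome is ``n_genes`` random intact genes separated by random
    spacers; genes evolve under the frame-preserving JC step and spacers
    freely.  With sub_rate = 0 every leaf equals the root genome.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    segs = _root_segments(config, rng)
    leaves: dict[str, GenomeRecord] = {}

    def descend(node: TreeNode, segments: list[tuple[str, np.ndarray]]) -> None:
        if node.parent is not None:
            p = jc_p(config.sub_rate, node.length or 0.0)
            segments = [
                (kind, (_mutate_gene if kind == "gene" else _mutate_free)(s, p, rng))
                for kind, s in segments
            ]
        if node.is_tip():
            leaves[node.name] = GenomeRecord(
                id=node.name, seq="".join(_decode(s) for _, s in segments)
            )
        else:
            for child in node.children:
                descend(child, segments)

    descend(tree, segs)
    return leaves


def _root_segments(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, np.ndarray]]:
    segs: list[tuple[str, np.ndarray]] = []
    for i in range(config.n_genes):
        segs.append(("spacer", rng.integers(0, 4, config.spacer_len).astype(np.uint8)))
        segs.append(("gene", _random_gene(config.gene_len, rng)))
    segs.append(("spacer", rng.integers(0, 4, config.spacer_len).astype(np.uint8)))
    return segs


# ---------------------------------------------------------------------------
# Swap planting


@dataclass
class SimTruth:
    """Planted ground truth of one simulated dataset."""

    newick: str
    leaf_states: dict[str, dict]  # leaf -> {"family": .., "subgroup": ..}
    swap_events: list[dict]  # {"branch", "family", "subgroup", "leaves"}
    dual_events: list[dict]
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "newick": self.newick,
                "leaf_states": self.leaf_states,
                "swap_events": self.swap_events,
                "dual_events": self.dual_events,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


def _family_pool(
    config: SimConfig, rng: np.random.Generator
) -> dict[tuple[str, int], np.ndarray]:
    """One exemplar gene per (family, subgroup): unrelated genes across
    families, divergent variants within a family."""
    pool: dict[tuple[str, int], np.ndarray] = {}
    for fam in config.families:
        base = _random_gene(config.gene_len, rng)
        pool[(fam, 1)] = base
        for sub in range(2, config.n_subgroups + 1):
            pool[(fam, sub)] = _mutate_gene(base, config.subgroup_nt_div, rng)
    return pool


def plant_swaps(
    tree: TreeNode,
    genomes: dict[str, GenomeRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, GenomeRecord], SimTruth, ReferenceDb]:
    """Replace the DNAP gene slot in situ along the planted branches.

    The DNAP slot is re-simulated from the root down: the root carries the
    root family's first subgroup; on each swap branch the slot content is
    replaced by the new family/subgroup exemplar, which then continues to
    evolve in the subtree below.  Flanking genes and spacers are untouched.
    Optional dual events place a second, different-family DNAP in the next
    gene slot of the affected subtree, producing two-polymerase genomes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    node_names = {n.name for n in tree.traverse(include_self=True)}
    for ev in list(config.swap_events) + list(config.dual_dnap_events):
        branch, fam, sub = ev
        if branch not in node_names:
            raise ConfigError(f"swap branch {branch!r} not in the tree")
        if fam not in config.families or not 1 <= sub <= config.n_subgroups:
            raise ConfigError(f"unknown family/subgroup in event {ev!r}")
    pool = _family_pool(config, rng)
    swap_by_branch = {e[0]: e for e in config.swap_events}
    dual_by_branch = {e[0]: e for e in config.dual_dnap_events}
    s0, s1 = config.gene_span(config.dnap_slot)
    dual_slot = config.dnap_slot + 1
    if dual_by_branch and dual_slot >= config.n_genes:
        raise ConfigError("no gene slot available for a second DNAP")
    d0, d1 = config.gene_span(dual_slot)

    leaf_states: dict[str, dict] = {}
    new_genomes: dict[str, GenomeRecord] = {}
    ev_leaves: dict[str, list[str]] = {e[0]: [] for e in config.swap_events}
    dual_leaves: dict[str, list[str]] = {e[0]: [] for e in config.dual_dnap_events}

    def descend(node, slot_seq, state, dual_seq, dual_state, path_events, path_duals):
        if node.name in swap_by_branch:
            _, fam, sub = swap_by_branch[node.name]
            slot_seq = pool[(fam, sub)]
            state = (fam, sub)
            path_events = path_events + [node.name]
        if node.name in dual_by_branch:
            _, fam, sub = dual_by_branch[node.name]
            dual_seq = pool[(fam, sub)]
            dual_state = (fam, sub)
            path_duals = path_duals + [node.name]
        if node.parent is not None:
            p = jc_p(config.sub_rate, node.length or 0.0)
            slot_seq = _mutate_gene(slot_seq, p, rng)
            if dual_seq is not None:
                dual_seq = _mutate_gene(dual_seq, p, rng)
        if node.is_tip():
            g = genomes[node.name]
            seq = g.seq[:s0] + _decode(slot_seq) + g.seq[s1:]
            if dual_seq is not None:
                seq = seq[:d0] + _decode(dual_seq) + seq[d1:]
            new_genomes[node.name] = GenomeRecord(id=g.id, seq=seq)
            leaf_states[node.name] = {
                "family": state[0],
                "subgroup": f"{state[0][3:]}{state[1]}",
                "dual_family": dual_state[0] if dual_state else None,
            }
            for b in path_events:
                ev_leaves[b].append(node.name)
            for b in path_duals:
                dual_leaves[b].append(node.name)
        else:
            for child in node.children:
                descend(child, slot_seq, state, dual_seq, dual_state, path_events, path_duals)

    root_state = (config.root_family, 1)
    descend(tree, pool[root_state], root_state, None, None, [], [])

    refs = ReferenceDb(
        [
            RefProtein(
                id=f"ref_{fam}_{fam[3:]}{sub}",
                family=fam,
                seq=_translate(gene),
            )
            for (fam, sub), gene in sorted(pool.items())
        ]
    )
    truth = SimTruth(
        newick=str(tree).strip(),
        leaf_states=leaf_states,
        swap_events=[
            {"branch": b, "family": f, "subgroup": s, "leaves": sorted(ev_leaves[b])}
            for b, f, s in config.swap_events
        ],
        dual_events=[
            {"branch": b, "family": f, "subgroup": s, "leaves": sorted(dual_leaves[b])}
            for b, f, s in config.dual_dnap_events
        ],
        config=asdict(config),
    )
    return new_genomes, truth, refs


# ---------------------------------------------------------------------------
# High-level drivers


def choose_swap_branches(
    tree: TreeNode,
    n_events: int,
    min_leaves: int = 2,
    max_leaves: int | None = None,
    embed_frac: float = 0.2,
) -> list[str]:
    """Deterministically pick ``n_events`` disjoint, non-sister internal
    branches subtending small subtrees — suitable swap sites whose clades
    retain unswapped relatives.

    Branches are spread out: after the first (smallest, earliest-named)
    candidate, each further branch maximizes its minimum path distance to
    the ones already chosen, and the returned list is ordered so its first
    and last elements are the most mutually distant pair.  Well-separated
    swap sites keep independently planted events independent on the
    reconstructed tree as well.

    Candidates whose parent subtree is shallow (height <= ``embed_frac``
    times the tree height) are preferred: a swap planted there stays inside
    a fixed-depth clade together with unswapped relatives, so the resulting
    heterogeneity is observable at clade level.  If the tree offers too few
    such branches the constraint is relaxed.
    """
    n_total = len(list(tree.tips()))
    if max_leaves is None:
        max_leaves = max(min_leaves, n_total // 4)
    depth: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    height: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            height[id(node)] = 0.0
        else:
            height[id(node)] = max((c.length or 0.0) + height[id(c)] for c in node.children)
    embed_height = embed_frac * height[id(tree)]

    def path_dist(u: TreeNode, v: TreeNode) -> float:
        au = {id(a) for a in [u] + list(u.ancestors())}
        w = v
        while id(w) not in au:
            w = w.parent
        return depth[id(u)] + depth[id(v)] - 2.0 * depth[id(w)]

    cands = []
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        k = len(list(node.tips()))
        if min_leaves <= k <= max_leaves:
            embedded = (
                node.parent is not None
                and height[id(node.parent)] <= embed_height
            )
            cands.append((0 if embedded else 1, k, node.name, node))
    cands.sort()
    embed_rank = {id(node): e for e, _, _, node in cands}
    cands = [(k, name, node) for _, k, name, node in cands]

    def compatible(node: TreeNode, chosen: list[TreeNode]) -> bool:
        return not any(
            node in c.ancestors() or c in node.ancestors() or node.parent is c.parent
            for c in chosen
        )

    chosen: list[TreeNode] = []
    if cands:
        chosen.append(cands[0][2])
    while len(chosen) < n_events:
        valid = [(k, name, n) for k, name, n in cands if n not in chosen and compatible(n, chosen)]
        if not valid:
            break
        best = max(
            valid,
            key=lambda c: (
                -embed_rank[id(c[2])],
                min(path_dist(c[2], x) for x in chosen),
                -c[0],
                c[1],
            ),
        )
        chosen.append(best[2])
    if len(chosen) < n_events:
        raise ConfigError(
            f"tree offers only {len(chosen)} disjoint swap branches, "
            f"{n_events} requested"
        )
    # order so the first and last entries are the farthest apart
    besti, bestj, bestd = 0, len(chosen) - 1, -1.0
    for i in range(len(chosen)):
        for j in range(i + 1, len(chosen)):
            d = path_dist(chosen[i], chosen[j])
            if d > bestd:
                besti, bestj, bestd = i, j, d
    mid = [n for k, n in enumerate(chosen) if k not in (besti, bestj)]
    ordered = [chosen[besti]] + mid + [chosen[bestj]]
    return [n.name for n in ordered]


def simulate_dataset(
    config: SimConfig,
) -> tuple[TreeNode, dict[str, GenomeRecord], SimTruth, ReferenceDb]:
    """Tree + genomes + planted swaps + references in one deterministic run."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_leaves, config.tree_height, rng)
    genomes = evolve_genomes(tree, config, rng)
    genomes, truth, refs = plant_swaps(tree, genomes, config, rng)
    return tree, genomes, truth, refs


def emit_dataset(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Write genomes.fna, refs.faa, truth.json, config.json, tree.nwk.

    Re-running with the same config reproduces identical files byte for
    byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, genomes, truth, refs = simulate_dataset(config)
    paths = {
        "genomes": outdir / "genomes.fna",
        "refs": outdir / "refs.faa",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
        "tree": outdir / "tree.nwk",
    }
    with open(paths["genomes"], "w") as fh:
        for name in sorted(genomes):
            fh.write(f">{name}\n{genomes[name].seq}\n")
    with open(paths["refs"], "w") as fh:
        for r in refs.records:
            fh.write(f">{r.id}|{r.family}\n{r.seq}\n")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
        fh.write("\n")
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(paths["tree"], "w") as fh:
        fh.write(str(tree).strip() + "\n")
    return paths
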