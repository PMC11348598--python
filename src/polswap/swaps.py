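"""Detection and counting of DNA-polymerase swaps on the genome tree.

Within each fixed-depth clade of the ultrametric genome tree, the DNAP
family content of the member genomes is profiled.  Two kinds of
heterogeneity are distinguished: type I, closely related genomes carrying
single DNAPs of *different* families (the signature of a gene swap), and
type II, a single genome carrying two DNAPs of different families.  Type-I
hotspot clades are extended through DNAP-bearing sister subtrees into
maximal swapping clades, and the minimum number of replacement events in
each is counted by Fitch small parsimony on the genome tree — once on family
states (inter-family swaps) and once on family+subgroup states, which
additionally exposes replacements by a divergent polymerase of the same
family.  Genomes without a recognized DNAP are wildcards: absence of a
polymerase call is not evidence of a transition.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from skbio import TreeNode

from .classify import DnapCall
from .orfs import InputError
from .tree import Clade, CladePartition

__all__ = [
    "CladeProfile",
    "SwapClade",
    "SwapReport",
    "profile_clades",
    "group_sister_clades",
    "count_swaps_fitch",
    "swap_report",
]


@dataclass
class CladeProfile:
    clade_id: str
    n_genomes: int
    families_present: set[str]
    n_single_dnap_genomes: int
    n_multi_dnap_genomes: int
    het_type_i: bool
    het_type_ii: bool
    is_singleton: bool


@dataclass
class SwapClade:
    """A maximal group of sister subtrees exhibiting DNAP diversity."""

    member_clades: list[str]
    mrca: TreeNode
    leaves: list[str]
    min_swaps_family: int | None = None
    min_swaps_subgroup: int | None = None


def profile_clades(
    partition: CladePartition, calls: Sequence[DnapCall]
) -> list[CladeProfile]:
    """DNAP family profile and heterogeneity flags for every clade.

    Singleton clades are profiled but flagged; heterogeneity is only
    meaningful for clades with at least two genomes.
    """
    leaf_to_clade = partition.leaf_to_clade
    calls_by_genome: dict[str, list[DnapCall]] = defaultdict(list)
    for c in calls:
        if c.genome_id not in leaf_to_clade:
            raise InputError(f"call references genome {c.genome_id!r} absent from the tree")
        calls_by_genome[c.genome_id].append(c)
    profiles = []
    for clade in partition.clades:
        families: set[str] = set()
        single_fams: set[str] = set()
        n_single = 0
        n_multi = 0
        type_ii = False
        for g in clade.leaves:
            gcalls = calls_by_genome.get(g, [])
            fams = {c.family for c in gcalls}
            families |= fams
            if len(gcalls) == 1:
                n_single += 1
                single_fams |= fams
            elif len(gcalls) >= 2:
                n_multi += 1
                if len(fams) >= 2:
                    type_ii = True
        profiles.append(
            CladeProfile(
                clade_id=clade.clade_id,
                n_genomes=len(clade.leaves),
                families_present=families,
                n_single_dnap_genomes=n_single,
                n_multi_dnap_genomes=n_multi,
                het_type_i=len(single_fams) >= 2,
                het_type_ii=type_ii,
                is_singleton=clade.is_singleton,
            )
        )
    return profiles


def _subtree_has_dnap(node: TreeNode, dnap_genomes: set[str]) -> bool:
    if node.is_tip():
        return node.name in dnap_genomes
    return any(tip.name in dnap_genomes for tip in node.tips())


def group_sister_clades(
    tree: TreeNode,
    partition: CladePartition,
    profiles: Sequence[CladeProfile],
    calls: Sequence[DnapCall],
) -> list[SwapClade]:
    """Extend each type-I hotspot clade through DNAP-bearing sisters.

    Starting at a hotspot clade's subtree root, the group is merged with its
    sister subtree(s) while at least one sister contains a DNAP-encoding
    genome; the merged group is the subtree of the last accepted ancestor.
    Overlapping groups are deduplicated to maximal ones.
    """
    dnap_genomes = {c.genome_id for c in calls}
    hot = {p.clade_id for p in profiles if p.het_type_i and not p.is_singleton}
    node_by_id = {c.clade_id: c.node for c in partition.clades}
    groups: list[TreeNode] = []
    for cid in sorted(hot):
        node = node_by_id[cid]
        while node.parent is not None:
            sisters = [s for s in node.parent.children if s is not node]
            if any(_subtree_has_dnap(s, dnap_genomes) for s in sisters):
                node = node.parent
            else:
                break
        groups.append(node)
    # deduplicate nested/identical groups, keep maximal
    result: list[SwapClade] = []
    seen: set[frozenset[str]] = set()
    leafsets = [frozenset(t.name for t in (g.tips() if not g.is_tip() else [g])) for g in groups]
    for g, ls in zip(groups, leafsets):
        if ls in seen or any(ls < other for other in leafsets):
            continue
        seen.add(ls)
        members = sorted(
            c.clade_id for c in partition.clades if set(c.leaves) <= ls
        )
        result.append(
            SwapClade(member_clades=members, mrca=g, leaves=sorted(ls))
        )
    return result


def count_swaps_fitch(
    tree: TreeNode, leaf_states: Mapping[str, str | frozenset[str] | set[str]]
) -> int:
    """Minimum number of state changes on the tree (Fitch small parsimony).

    ``leaf_states`` maps leaf names to a state label or a set of admissible
    labels (a genome with two DNAPs of different families admits either).
    Leaves absent from the mapping are wildcards carrying the full state set
    and never force a change.  Multifurcations are resolved by merging child
    state sets sequentially in child order, counting each empty intersection
    as one change.
    """
    universe: set[str] = set()
    for leaf, v in leaf_states.items():
        s = {v} if isinstance(v, str) else set(v)
        if not s:
            raise InputError(f"leaf {leaf!r} labeled with an empty state set")
        universe |= s
    if not universe:
        return 0
    universe_f = frozenset(universe)
    changes = 0
    stateset: dict[int, frozenset[str]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name in leaf_states:
                v = leaf_states[node.name]
                s = frozenset({v} if isinstance(v, str) else v)
                if not s:
                    raise InputError(f"leaf {node.name!r} labeled with an empty state set")
            else:
                s = universe_f
            stateset[id(node)] = s
        else:
            cur = stateset[id(node.children[0])]
            for child in node.children[1:]:
                nxt = stateset[id(child)]
                inter = cur & nxt
                if inter:
                    cur = inter
                else:
                    cur = cur | nxt
                    changes += 1
            stateset[id(node)] = cur
    return changes


@dataclass
class SwapReport:
    """Summary of DNAP distribution and swap counts over one tree partition."""

    n_clades: int
    n_multi_genome_clades: int
    n_clades_with_dnap: int  # multi-genome clades with >= 1 DNAP call
    n_genomes_multi_dnap: int
    n_hotspots_type_i: int
    n_hotspots_type_ii: int
    profiles: list[CladeProfile]
    swap_clades: list[SwapClade]
    truth_comparison: dict | None = None

    @property
    def total_min_swaps_family(self) -> int:
        return sum(s.min_swaps_family or 0 for s in self.swap_clades)

    @property
    def total_min_swaps_subgroup(self) -> int:
        return sum(s.min_swaps_subgroup or 0 for s in self.swap_clades)

    def to_dict(self) -> dict:
        return {
            "n_clades": self.n_clades,
            "n_multi_genome_clades": self.n_multi_genome_clades,
            "n_clades_with_dnap": self.n_clades_with_dnap,
            "n_genomes_multi_dnap": self.n_genomes_multi_dnap,
            "n_hotspots_type_i": self.n_hotspots_type_i,
            "n_hotspots_type_ii": self.n_hotspots_type_ii,
            "total_min_swaps_family": self.total_min_swaps_family,
            "total_min_swaps_subgroup": self.total_min_swaps_subgroup,
            "clades": [
                {
                    "clade_id": p.clade_id,
                    "n_genomes": p.n_genomes,
                    "families": sorted(p.families_present),
                    "het_type_i": p.het_type_i,
                    "het_type_ii": p.het_type_ii,
                }
                for p in self.profiles
            ],
            "swap_clades": [
                {
                    "member_clades": s.member_clades,
                    "n_leaves": len(s.leaves),
                    "leaves": s.leaves,
                    "min_swaps_family": s.min_swaps_family,
                    "min_swaps_subgroup": s.min_swaps_subgroup,
                }
                for s in self.swap_clades
            ],
            "truth_comparison": self.truth_comparison,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "clade_id\tn_genomes\tfamilies\thet_type_i\thet_type_ii\tis_singleton\n"
            )
            for p in self.profiles:
                fh.write(
                    f"{p.clade_id}\t{p.n_genomes}\t{','.join(sorted(p.families_present)) or '.'}"
                    f"\t{int(p.het_type_i)}\t{int(p.het_type_ii)}\t{int(p.is_singleton)}\n"
                )


def swap_report(
    tree: TreeNode,
    partition: CladePartition,
    profiles: Sequence[CladeProfile],
    swap_clades: Sequence[SwapClade],
    calls: Sequence[DnapCall],
    truth: dict | None = None,
) -> SwapReport:
    """Assemble the summary report and count swap events per swapping clade.

    Each swapping clade's minimum event count is computed twice: on family
    states (inter-family swaps only) and on family+subgroup states (total
    swaps, including replacement by a divergent same-family polymerase).
    Subgroup counts are always >= family counts because refining states can
    only add forced changes.
    """
    fam_states: dict[str, set[str]] = defaultdict(set)
    sub_states: dict[str, set[str]] = defaultdict(set)
    for c in calls:
        fam_states[c.genome_id].add(c.family)
        sub_states[c.genome_id].add(f"{c.family}:{c.subgroup or '?'}")
    for sc in swap_clades:
        leaves = set(sc.leaves)
        sc.min_swaps_family = count_swaps_fitch(
            sc.mrca, {g: frozenset(s) for g, s in fam_states.items() if g in leaves}
        )
        sc.min_swaps_subgroup = count_swaps_fitch(
            sc.mrca, {g: frozenset(s) for g, s in sub_states.items() if g in leaves}
        )
    multi = [p for p in profiles if not p.is_singleton]
    truth_cmp = None
    if truth is not None:
        truth_cmp = _compare_truth(truth, profiles, swap_clades, partition)
    return SwapReport(
        n_clades=len(profiles),
        n_multi_genome_clades=len(multi),
        n_clades_with_dnap=sum(1 for p in multi if p.families_present),
        n_genomes_multi_dnap=sum(p.n_multi_dnap_genomes for p in profiles),
        n_hotspots_type_i=sum(1 for p in multi if p.het_type_i),
        n_hotspots_type_ii=sum(1 for p in multi if p.het_type_ii),
        profiles=list(profiles),
        swap_clades=list(swap_clades),
        truth_comparison=truth_cmp,
    )


def _compare_truth(
    truth: dict,
    profiles: Sequence[CladeProfile],
    swap_clades: Sequence[SwapClade],
    partition: CladePartition,
) -> dict:
    """Compare detected hotspots/counts with a simulator truth record."""
    leaf_to_clade = partition.leaf_to_clade
    planted = truth.get("swap_events", [])
    n_planted = len(planted)
    swapped_leaves = {leaf for ev in planted for leaf in ev["leaves"]}
    # clades where a planted swap is visible at family level: they contain a
    # swapped leaf AND genomes of >= 2 true families (an intra-family swap
    # or a swap spanning a whole clade leaves no family heterogeneity there)
    true_family = {
        leaf: state.get("family")
        for leaf, state in truth.get("leaf_states", {}).items()
    }
    clade_families: dict[str, set[str]] = defaultdict(set)
    if true_family:
        for leaf, cid in leaf_to_clade.items():
            fam = true_family.get(leaf)
            if fam:
                clade_families[cid].add(fam)
    affected = sorted(
        {
            leaf_to_clade[l]
            for l in swapped_leaves
            if l in leaf_to_clade
            and (not true_family or len(clade_families[leaf_to_clade[l]]) >= 2)
        }
    )
    hot = {p.clade_id for p in profiles if p.het_type_i}
    detected_leaves = {l for sc in swap_clades for l in sc.leaves}
    return {
        "n_planted_swaps": n_planted,
        "affected_clades": affected,
        "affected_clades_detected": sorted(set(affected) & hot),
        "planted_leaves_in_swap_clades": sorted(swapped_leaves & detected_leaves),
        "n_planted_leaves": len(swapped_leaves),
        "total_min_swaps_family": sum(s.min_swaps_family or 0 for s in swap_clades),
    }
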