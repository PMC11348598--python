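"""Planted-swap recovery study: the package's standard validation experiment.

One replicate simulates a 32-genome, 20-gene dataset with three inter-family
DNAP swaps planted on distinct, well-separated branches, runs the full
pipeline on the simulated genomes, and compares the detected hotspots and
parsimony swap counts against the planted truth.  The replicate is fully
determined by its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .classify import assign_subgroups, classify_dnaps
from .rbh import distance_matrix
from .simulate import SimConfig, choose_swap_branches, simulate_dataset, simulate_tree
from .swaps import count_swaps_fitch, group_sister_clades, profile_clades, swap_report
from .tree import build_tree, cut_clades, ultrametrize

__all__ = ["SwapRecovery", "planted_swap_replicate", "classification_recovery"]


@dataclass
class SwapRecovery:
    """Outcome of one planted-swap replicate."""

    seed: int
    n_planted: int
    n_affected_clades: int  # clades where a planted swap is visible
    n_detected_clades: int  # of those, flagged as type-I hotspots
    min_swaps_family: int  # total over swapping clades, inferred tree
    min_swaps_subgroup: int
    fitch_true_tree: int  # family changes on the true tree, true states
    fitch_inferred_tree: int  # family changes on the inferred tree, true states

    @property
    def all_clades_detected(self) -> bool:
        return self.n_detected_clades == self.n_affected_clades


def planted_swap_replicate(
    seed: int,
    n_leaves: int = 32,
    n_genes: int = 20,
    n_swaps: int = 3,
    clade_depth: float = 0.15,
    engine: str = "blast",
) -> SwapRecovery:
    """Simulate, analyse and score one planted-swap dataset.

    The three planted events replace the DNAP slot with PolB, PolC and a
    second PolB subgroup; the two PolB events go to the most separated
    branch pair so each planted event is an independent change.
    """
    base = SimConfig(n_leaves=n_leaves, n_genes=n_genes, seed=seed)
    rng = np.random.default_rng(seed)
    tree0 = simulate_tree(n_leaves, base.tree_height, rng)
    branches = choose_swap_branches(tree0, n_swaps)
    families = [("PolB", 1), ("PolC", 1), ("PolB", 2)]
    events = [
        (b, *families[i % len(families)]) for i, b in enumerate(branches)
    ]
    cfg = SimConfig(n_leaves=n_leaves, n_genes=n_genes, seed=seed, swap_events=events)
    tree, genomes, truth, refs = simulate_dataset(cfg)

    result = distance_matrix(list(genomes.values()), engine=engine)
    inferred = ultrametrize(build_tree(result.matrix))
    partition = cut_clades(inferred, depth=clade_depth)
    all_orfs = [o for g in genomes for o in result.orfs[g]]
    calls = assign_subgroups(classify_dnaps(all_orfs, refs))
    profiles = profile_clades(partition, calls)
    swap_clades = group_sister_clades(inferred, partition, profiles, calls)
    report = swap_report(
        inferred, partition, profiles, swap_clades, calls,
        truth=json.loads(truth.to_json()),
    )

    true_states = {l: s["family"] for l, s in truth.leaf_states.items()}
    tc = report.truth_comparison
    return SwapRecovery(
        seed=seed,
        n_planted=n_swaps,
        n_affected_clades=len(tc["affected_clades"]),
        n_detected_clades=len(tc["affected_clades_detected"]),
        min_swaps_family=report.total_min_swaps_family,
        min_swaps_subgroup=report.total_min_swaps_subgroup,
        fitch_true_tree=count_swaps_fitch(tree, true_states),
        fitch_inferred_tree=count_swaps_fitch(inferred, true_states),
    )


def classification_recovery(
    n_replicates: int = 200,
    identity: float = 0.6,
    seed: int = 0,
    evalue_max: float = 1e-4,
) -> float:
    """Fraction of diverged DNAP genes assigned their correct family.

    Each replicate mutates one reference protein to the target identity and
    classifies it against the full reference set.
    """
    from .classify import ReferenceDb, RefProtein
    from .orfs import OrfRecord

    rng = np.random.default_rng(seed)
    aas = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", np.uint8)
    refs = ReferenceDb(
        [
            RefProtein(
                f"ref{f}", f"Pol{f}", bytes(rng.choice(aas, 100)).decode()
            )
            for f in "ABC"
        ]
    )
    correct = 0
    for i in range(n_replicates):
        ref = refs.records[int(rng.integers(3))]
        prot = bytearray(ref.seq.encode())
        k = round(len(prot) * (1 - identity))
        for pos in rng.choice(len(prot), size=k, replace=False):
            choices = aas[aas != prot[pos]]
            prot[pos] = int(rng.choice(choices))
        orf = OrfRecord("g", 0, 3 * (len(prot) + 1), "+", 0, prot.decode())
        calls = classify_dnaps([orf], refs, evalue_max=evalue_max)
        correct += bool(calls) and calls[0].family == ref.family
    return correct / n_replicates
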