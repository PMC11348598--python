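"""Independent reference implementations used only by the tests.

Each oracle is written from the definition of the quantity it checks, with
no code shared with the package paths it validates: ORF enumeration by
explicit (start, stop) pairing, local alignment by a full-matrix dynamic
programme, Fitch counts by exhaustive enumeration of ancestral labelings,
and translation by a hard-coded genetic-code table.
"""

from __future__ import annotations

import itertools
import random

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

# genetic code 11 written out: codon order TTT, TTC, TTA, TTG, TCT, ... (T,C,A,G)
_CODE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ORDER = "TCAG"
CODON_TABLE_11 = {
    a + b + c: _CODE[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def translate_table11(cds: str) -> str:
    """Straight codon-table lookup; initiator forced to M; terminal stop
    dropped; N-containing codons give X."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            aas.append("X")
            continue
        aa = CODON_TABLE_11[codon]
        if aa == "*" and i == len(cds) - 3:
            break
        aas.append(aa)
    if aas:
        aas[0] = "M"
    return "".join(aas)


def brute_force_orfs(seq: str, min_len: int = 75, starts=("ATG", "GTG", "TTG")):
    """Every (start codon, next in-frame stop) pair, keeping the earliest
    start per stop segment; returns a set of (start, end, strand) genome
    coordinates (end exclusive, stop codon included)."""
    L = len(seq)
    out = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            limit = frame + 3 * ((L - frame) // 3)
            codon_pos = list(range(frame, limit, 3))
            stops = [
                p
                for p in codon_pos
                if "N" not in s[p : p + 3] and CODON_TABLE_11.get(s[p : p + 3]) == "*"
            ]
            start_pos = [
                p for p in codon_pos if "N" not in s[p : p + 3] and s[p : p + 3] in starts
            ]
            # segment boundaries: (-inf, stop1], (stop1, stop2], ..., (stopK, end)
            prev = -1
            for stop in stops + [None]:
                if stop is None:
                    cand = [p for p in start_pos if p > prev]
                    if cand:
                        a, b = cand[0], limit  # runs off the end
                        if b - a >= min_len:
                            out.add(_to_genome(a, b, strand, L))
                else:
                    cand = [p for p in start_pos if prev < p < stop]
                    if cand:
                        a, b = cand[0], stop + 3
                        if b - a >= min_len:
                            out.add(_to_genome(a, b, strand, L))
                    prev = stop
    return out


def _to_genome(a: int, b: int, strand: str, L: int):
    if strand == "+":
        return (a, b, "+")
    return (L - b, L - a, "-")


def dp_local_score(q: str, s: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Full-matrix affine-gap Smith-Waterman score; a gap of length k costs
    gap_open + k*gap_extend."""
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            sub = H[i - 1][j - 1] + _B62[q[i - 1], s[j - 1]]
            H[i][j] = max(0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def _state_sets(tree, leaf_states: dict):
    universe = set()
    for v in leaf_states.values():
        universe |= {v} if isinstance(v, str) else set(v)
    admissible = {}
    for tip in tree.tips():
        if tip.name in leaf_states:
            v = leaf_states[tip.name]
            admissible[tip.name] = sorted({v} if isinstance(v, str) else set(v))
        else:
            admissible[tip.name] = sorted(universe)  # wildcard
    return sorted(universe), admissible


def fitch_brute_force(tree, leaf_states: dict) -> int:
    """Minimum change count over all assignments of states to internal
    nodes; each leaf then independently takes its cheapest admissible state
    given its parent (wildcards cost nothing)."""
    universe, admissible = _state_sets(tree, leaf_states)
    if not universe:
        return 0
    internal = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
    best = None
    for combo in itertools.product(universe, repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        cost = 0
        for node in internal:
            if node.parent is not None:
                cost += assign[id(node)] != assign[id(node.parent)]
        for tip in tree.tips():
            pst = assign[id(tip.parent)]
            cost += pst not in admissible[tip.name]
        if best is None or cost < best:
            best = cost
    return best


def sankoff_min_changes(tree, leaf_states: dict) -> int:
    """Exact minimum change count by min-cost dynamic programming over the
    tree (unit change costs); handles multifurcations and wildcards."""
    universe, admissible = _state_sets(tree, leaf_states)
    if not universe:
        return 0
    INF = 10**9
    cost: dict[int, dict[str, int]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            adm = set(admissible[node.name])
            cost[id(node)] = {s: (0 if s in adm else INF) for s in universe}
        else:
            c = {}
            for s in universe:
                total = 0
                for child in node.children:
                    cc = cost[id(child)]
                    total += min(cc[t] + (s != t) for t in universe)
                c[s] = total
            cost[id(node)] = c
    return min(cost[id(tree)].values())


def random_additive_tree(n_taxa: int, rng: random.Random):
    """Random rooted binary topology with branch lengths in [0.01, 1];
    returns (newick string, {(a, b): path length} distances)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [(lab, {lab: 0.0}) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        (nwk_b, d_b) = nodes.pop(j)
        (nwk_a, d_a) = nodes.pop(i)
        la = round(rng.uniform(0.01, 1.0), 6)
        lb = round(rng.uniform(0.01, 1.0), 6)
        merged = {}
        for leaf, d in d_a.items():
            merged[leaf] = d + la
        for leaf, d in d_b.items():
            merged[leaf] = d + lb
        nodes.append((f"({nwk_a}:{la},{nwk_b}:{lb})", merged))
    nwk, _ = nodes[0]
    return nwk + ";", _leaf_dists_from_newick(nwk + ";")


def _leaf_dists_from_newick(nwk: str):
    from io import StringIO

    from skbio import TreeNode

    t = TreeNode.read(StringIO(nwk))
    tips = list(t.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[(a.name, b.name)] = a.distance(b)
    return out
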