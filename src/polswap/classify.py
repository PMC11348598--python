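"""DNA-polymerase family assignment and within-family subgrouping.

Phage replicative DNA polymerases fall into three essentially unrelated
families (PolA, PolB, PolC).  Each ORF is searched against a labeled
reference protein set by local alignment; if the best hit is significant
(e-value <= 1e-4 by default) the ORF inherits the reference's family label.
Within a family, calls are subgrouped by single-linkage clustering of global
pairwise identity at a 0.5 threshold, giving labels like A1, A2 (ordinals by
decreasing cluster size), which distinguish divergent same-family groups —
the unit in which intra-family swaps are counted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .align import align_pair, global_identity
from .orfs import InputError, OrfRecord

__all__ = [
    "ReferenceDb",
    "RefProtein",
    "DnapCall",
    "classify_dnaps",
    "assign_subgroups",
    "read_reference_fasta",
    "write_calls_tsv",
    "read_calls_tsv",
]

FAMILIES = ("PolA", "PolB", "PolC")


@dataclass(frozen=True)
class RefProtein:
    id: str
    family: str
    seq: str


@dataclass
class ReferenceDb:
    """Labeled reference DNAP proteins.  Extra user-supplied family labels
    (e.g. divergent PolA groups) are accepted alongside PolA/PolB/PolC."""

    records: list[RefProtein]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("empty reference database")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate reference protein ids")

    @property
    def n_residues(self) -> int:
        return sum(len(r.seq) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DnapCall:
    """One classified DNAP ORF.  A genome may carry 0, 1 or several calls."""

    genome_id: str
    orf_id: str
    family: str
    best_ref_id: str
    evalue: float
    bit_score: float
    protein: str
    subgroup: str | None = None


def classify_dnaps(
    orfs: Sequence[OrfRecord],
    refdb: ReferenceDb,
    evalue_max: float = 1e-4,
) -> list[DnapCall]:
    """Best-hit family classification of ORFs against the reference set.

    Each ORF is aligned to every reference; the e-value uses the whole
    reference database as the search space.  At most one call per ORF (the
    single best reference decides the family); ties broken by bit score,
    then reference id.
    """
    if not isinstance(refdb, ReferenceDb):
        raise InputError("refdb must be a ReferenceDb")
    space = refdb.n_residues
    calls: list[DnapCall] = []
    for orf in orfs:
        best = None
        for ref in refdb.records:
            hit = align_pair(
                orf.protein,
                ref.seq,
                query_id=orf.orf_id,
                subject_id=ref.id,
                search_space=space,
            )
            key = (-hit.bit_score, ref.id)
            if best is None or key < best[0]:
                best = (key, hit, ref)
        _, hit, ref = best
        if hit.evalue <= evalue_max:
            calls.append(
                DnapCall(
                    genome_id=orf.genome_id,
                    orf_id=orf.orf_id,
                    family=ref.family,
                    best_ref_id=ref.id,
                    evalue=hit.evalue,
                    bit_score=hit.bit_score,
                    protein=orf.protein,
                )
            )
    return calls


def assign_subgroups(
    calls: Sequence[DnapCall],
    identity_threshold: float = 0.5,
) -> list[DnapCall]:
    """Single-linkage subgroups of same-family calls at a global-identity
    threshold.

    Labels are the family letter plus an ordinal by decreasing cluster size
    (ties broken by the smallest member orf_id), so A1 is the largest PolA
    subgroup.  Calls of different families never share a subgroup.
    """
    by_family: dict[str, list[int]] = defaultdict(list)
    for i, c in enumerate(calls):
        by_family[c.family].append(i)
    out = list(calls)
    for family, idxs in sorted(by_family.items()):
        # union-find over same-family calls
        parent = {i: i for i in idxs}

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                if find(i) == find(j):
                    continue
                if global_identity(calls[i].protein, calls[j].protein) >= identity_threshold:
                    parent[find(j)] = find(i)
        clusters: dict[int, list[int]] = defaultdict(list)
        for i in idxs:
            clusters[find(i)].append(i)
        letter = family[3:] if family.startswith("Pol") else family
        ordered = sorted(
            clusters.values(),
            key=lambda mem: (-len(mem), min(calls[i].orf_id for i in mem)),
        )
        for rank, members in enumerate(ordered, start=1):
            for i in members:
                out[i] = replace(out[i], subgroup=f"{letter}{rank}")
    return out


# ---------------------------------------------------------------------------
# I/O


def read_reference_fasta(path: str | Path) -> ReferenceDb:
    """Reference FASTA; the family is the last |-separated header token
    (e.g. ``>refX|PolA``)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise InputError(
                f"reference header {rec.id!r} lacks a |-separated family label"
            )
        rid, family = rec.id.rsplit("|", 1)
        records.append(RefProtein(id=rid, family=family, seq=str(rec.seq)))
    return ReferenceDb(records)


def write_calls_tsv(calls: Iterable[DnapCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\torf_id\tfamily\tsubgroup\tbest_ref_id\tevalue\tbit_score\n")
        for c in calls:
            fh.write(
                f"{c.genome_id}\t{c.orf_id}\t{c.family}\t{c.subgroup or '.'}"
                f"\t{c.best_ref_id}\t{c.evalue:.3g}\t{c.bit_score:.2f}\n"
            )


def read_calls_tsv(path: str | Path) -> list[DnapCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            g, o, fam, sub, ref, ev, bs = line.rstrip("\n").split("\t")
            calls.append(
                DnapCall(
                    genome_id=g,
                    orf_id=o,
                    family=fam,
                    best_ref_id=ref,
                    evalue=float(ev),
                    bit_score=float(bs),
                    protein="",
                    subgroup=None if sub == "." else sub,
                )
            )
    return calls
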