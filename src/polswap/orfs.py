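"""Six-frame ORF extraction and translation under the bacterial genetic code.

Phage genomes are gene-dense, with protein-coding genes on both strands and
frequent overlaps between reading frames.  The ORF caller here follows the
conventions of standard prokaryotic ORF finders: within every stop-to-stop
segment of each of the six reading frames, the longest open reading frame
(first start codon after the previous stop, through the next stop codon
inclusive) is reported if it reaches a minimum length, 75 nt by default.
Genomes are treated as linear; a trailing ORF that runs off the sequence end
without a stop codon is kept, because phage genome records are often
circularly permuted mid-gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "GenomeRecord",
    "OrfRecord",
    "find_orfs",
    "translate_cds",
    "translate_orf",
    "reverse_complement",
    "read_genomes_fasta",
    "write_orf_proteins",
    "write_orf_table",
]

#: Genetic code 11 (bacterial/archaeal/plant plastid).
_TABLE11 = unambiguous_dna_by_id[11]
_CODON_TO_AA = dict(_TABLE11.forward_table)
_STOP_CODONS = frozenset(_TABLE11.stop_codons)  # TAA, TAG, TGA
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID = frozenset("ACGTN")


class InputError(ValueError):
    """Malformed user input (bad characters, duplicate ids, missing files)."""


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


@dataclass(frozen=True)
class GenomeRecord:
    """A phage genome: identifier plus nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = next((i for i, c in enumerate(self.seq) if c not in _VALID), None)
        if bad is not None:
            raise InputError(
                f"genome {self.id!r}: invalid character {self.seq[bad]!r} "
                f"at position {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class OrfRecord:
    """A predicted ORF in 0-based half-open genome coordinates.

    ``nt_len`` includes the stop codon when one terminates the ORF; the
    translated protein omits the stop symbol.  ``frame`` is 0..2 on the ORF's
    own strand.
    """

    genome_id: str = field(compare=False)
    start: int
    end: int
    strand: str
    frame: int = field(compare=False)
    protein: str = field(compare=False)

    @property
    def nt_len(self) -> int:
        return self.end - self.start

    @property
    def orf_id(self) -> str:
        return f"{self.genome_id}|{self.start}|{self.end}|{self.strand}"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, *, initiator_to_m: bool = True) -> str:
    """Translate a coding sequence under genetic code 11.

    The initiator codon is rendered M whatever its identity (bacterial
    initiator tRNA carries fMet regardless of the start codon); a terminal
    stop codon is omitted; any codon containing N yields X.
    """
    if len(cds) % 3 != 0:
        raise InvariantError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _STOP_CODONS:
            if i == len(cds) - 3:
                break
            aas.append("*")  # internal stop: surfaced, caller decides
        else:
            aas.append(_CODON_TO_AA[codon])
    if initiator_to_m and aas:
        aas[0] = "M"
    return "".join(aas)


def translate_orf(orf: OrfRecord, genome: GenomeRecord) -> str:
    """Translate an ORF given its source genome (strand-aware)."""
    if not (0 <= orf.start <= orf.end <= genome.length):
        raise InvariantError(
            f"ORF {orf.orf_id} coordinates outside genome of length {genome.length}"
        )
    cds = genome.seq[orf.start : orf.end]
    if orf.strand == "-":
        cds = reverse_complement(cds)
    return translate_cds(cds)


def _scan_frame(seq: str, frame: int, min_len: int, starts: frozenset[str]) -> list[tuple[int, int]]:
    """Longest ORF per stop-to-stop segment in one forward frame.

    Returns (start, end) offsets on the given sequence, end exclusive and
    including the stop codon; a trailing segment with no stop is emitted if a
    start codon was seen and the truncated ORF reaches ``min_len``.
    """
    out: list[tuple[int, int]] = []
    pending: int | None = None  # first start codon of the current segment
    i = frame
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if "N" in codon:
            pass  # N-containing codons match neither start nor stop
        elif codon in _STOP_CODONS:
            if pending is not None and (i + 3 - pending) >= min_len:
                out.append((pending, i + 3))
            pending = None
        elif pending is None and codon in starts:
            pending = i
        i += 3
    if pending is not None and (i - pending) >= min_len:
        out.append((pending, i))  # runs off the end, no stop codon
    return out


def find_orfs(
    genome: GenomeRecord,
    min_len: int = 75,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> list[OrfRecord]:
    """All qualifying ORFs of a genome across the six reading frames.

    One ORF per stop-to-stop segment per frame (the longest, i.e. the one
    with the earliest start codon); ORFs in different frames may overlap.
    Output is sorted by (start, end, strand).
    """
    if not genome.seq:
        raise InputError(f"genome {genome.id!r}: empty sequence")
    if min_len < 6 or min_len % 3 != 0:
        raise ValueError("min_len must be >= 6 and divisible by 3")
    starts = frozenset(start_codons)
    L = genome.length
    rc = reverse_complement(genome.seq)
    orfs: list[OrfRecord] = []
    for strand, seq in (("+", genome.seq), ("-", rc)):
        for frame in range(3):
            for s, e in _scan_frame(seq, frame, min_len, starts):
                if strand == "+":
                    g0, g1 = s, e
                else:
                    g0, g1 = L - e, L - s
                cds = seq[s:e]
                orfs.append(
                    OrfRecord(
                        genome_id=genome.id,
                        start=g0,
                        end=g1,
                        strand=strand,
                        frame=frame,
                        protein=translate_cds(cds),
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# FASTA / table I/O


def read_genomes_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a multi-record nucleotide FASTA; ids must be unique."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate genome id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def write_orf_proteins(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.orf_id}\n{orf.protein}\n")


def write_orf_table(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    """BED-like TSV: genome_id, start, end, orf_id, nt_len, strand."""
    with open(path, "w") as fh:
        fh.write("genome_id\tstart\tend\torf_id\tnt_len\tstrand\n")
        for o in orfs:
            fh.write(f"{o.genome_id}\t{o.start}\t{o.end}\t{o.orf_id}\t{o.nt_len}\t{o.strand}\n")
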