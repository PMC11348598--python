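"""Protein local alignment: Smith–Waterman with affine gaps under BLOSUM62.

All-vs-all comparison of ORF complements is the computational bottleneck of
the whole-genome distance, so the dynamic programme is implemented twice:

* :func:`sw_score` — score-only kernel (numba), used for the dense scoring
  pass over every ORF pair of a genome pair;
* :func:`sw_score_span` — score plus the query interval of the optimal local
  path, tracked through the DP without a traceback matrix; used only for
  candidate best hits where the query-coverage filter must be evaluated.

Scoring follows the NCBI convention for "open 11, extend 1": a gap of length
k costs 11 + k.  Bit scores use fixed Karlin–Altschul constants
(lambda = 0.267, K = 0.041, the standard gapped BLOSUM62-11-1 values) and
e-values the m*n search-space formula; they are only used as thresholds, not
reported as calibrated significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AlignmentHit",
    "align_pair",
    "bit_score",
    "evalue",
    "encode_protein",
    "sw_score",
    "sw_score_span",
    "global_identity",
    "BLOSUM62",
    "ALPHABET",
    "GAP_OPEN",
    "GAP_EXTEND",
    "KA_LAMBDA",
    "KA_K",
]

_B62 = substitution_matrices.load("BLOSUM62")
#: Residue ordering of the score matrix ("ARNDCQEGHILKMFPSTWYVBZX*").
ALPHABET: str = str(_B62.alphabet)
BLOSUM62: np.ndarray = np.array(_B62, dtype=np.int32)
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_X_INDEX = _INDEX["X"]

GAP_OPEN = 11
GAP_EXTEND = 1
KA_LAMBDA = 0.267
KA_K = 0.041
_LN2 = math.log(2.0)


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject protein."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_cover: float  # aligned query span / query length, in [0, 1]
    aln_len: int  # query residues spanned by the optimal path


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string as BLOSUM62 row indices (uint8).

    Unknown symbols (selenocysteine etc.) map to X.
    """
    return np.frombuffer(
        bytes(_INDEX.get(c, _X_INDEX) for c in seq), dtype=np.uint8
    ).copy()


@njit(cache=True)
def sw_score(q, s, mat, gap_open, gap_extend):  # pragma: no cover - jit
    """Smith–Waterman optimal local score, affine gaps (length-k gap costs
    gap_open + k*gap_extend).  Linear memory, no traceback."""
    m = q.shape[0]
    n = s.shape[0]
    NEG = np.int32(-(10**9))
    H = np.zeros(n + 1, np.int32)
    E = np.full(n + 1, NEG, np.int32)
    best = np.int32(0)
    first = gap_open + gap_extend
    for i in range(m):
        diag = np.int32(0)
        F = NEG
        row = mat[q[i]]
        for j in range(1, n + 1):
            e = E[j] - gap_extend
            t = H[j] - first
            if t > e:
                e = t
            E[j] = e
            f = F - gap_extend
            t = H[j - 1] - first
            if t > f:
                f = t
            F = f
            h = diag + row[s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_score_span(q, s, mat, gap_open, gap_extend):  # pragma: no cover - jit
    """As :func:`sw_score`, also returning the query interval [q0, q1) of the
    optimal path.  Each DP cell carries the query row where its best path
    started, so no traceback matrix is needed."""
    m = q.shape[0]
    n = s.shape[0]
    NEG = np.int32(-(10**9))
    H = np.zeros(n + 1, np.int32)
    E = np.full(n + 1, NEG, np.int32)
    Hs = np.zeros(n + 1, np.int32)
    Es = np.zeros(n + 1, np.int32)
    best = np.int32(0)
    bq0 = np.int32(0)
    bq1 = np.int32(0)
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        diag = H[0]
        diag_s = Hs[0]
        F = NEG
        Fs = np.int32(0)
        Hs[0] = np.int32(i - 1)
        row = mat[q[i - 1]]
        for j in range(1, n + 1):
            e1 = H[j] - first
            e2 = E[j] - gap_extend
            if e1 >= e2:
                E[j] = e1
                Es[j] = Hs[j]
            else:
                E[j] = e2
            f1 = H[j - 1] - first
            f2 = F - gap_extend
            if f1 >= f2:
                F = f1
                Fs = Hs[j - 1]
            else:
                F = f2
            h = diag + row[s[j - 1]]
            hs = diag_s
            if E[j] > h:
                h = E[j]
                hs = Es[j]
            if F > h:
                h = F
                hs = Fs
            if h < 0:
                h = np.int32(0)
                hs = np.int32(i)
            diag = H[j]
            diag_s = Hs[j]
            H[j] = h
            Hs[j] = hs
            if h > best:
                best = h
                bq0 = hs
                bq1 = np.int32(i)
    return best, bq0, bq1


def bit_score(raw_score: float) -> float:
    """Normalized score: (lambda*S - ln K) / ln 2."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / _LN2


def evalue(raw_score: float, query_len: int, search_space: int) -> float:
    """Expected hit count: m * n * 2^(-bit); n is the subject search space
    (total residues in the subject proteome)."""
    return query_len * search_space * 2.0 ** (-bit_score(raw_score))


def align_pair(
    query: str,
    subject: str,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    search_space: int | None = None,
) -> AlignmentHit:
    """Align two proteins and report score, coverage and significance.

    ``search_space`` defaults to the subject length, i.e. a single-sequence
    search; reciprocal-best-hit searches pass the full subject-proteome
    residue count instead.
    """
    if not query or not subject:
        raise AlignmentError("empty protein sequence")
    q = encode_protein(query)
    s = encode_protein(subject)
    raw, q0, q1 = sw_score_span(q, s, BLOSUM62, GAP_OPEN, GAP_EXTEND)
    raw = int(raw)
    span = int(q1) - int(q0)
    n = search_space if search_space is not None else len(subject)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bit_score=bit_score(raw),
        evalue=evalue(raw, len(query), n),
        query_cover=span / len(query),
        aln_len=span,
    )


# ---------------------------------------------------------------------------
# Global alignment identity (for within-family subgrouping)

_GLOBAL = PairwiseAligner()
_GLOBAL.mode = "global"
_GLOBAL.substitution_matrix = _B62
_GLOBAL.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
_GLOBAL.extend_gap_score = -GAP_EXTEND


def global_identity(a: str, b: str) -> float:
    """Pairwise global identity: matches / alignment columns (gaps count as
    columns).  Needleman–Wunsch under BLOSUM62 with the same gap costs as the
    local search."""
    if not a or not b:
        raise AlignmentError("empty protein sequence")
    aln = _GLOBAL.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns
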