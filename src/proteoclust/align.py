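"""Pairwise local alignment and homology-edge acceptance.

Candidate pairs are scored by optimal Smith-Waterman local alignment with
affine gap penalties (a gap of length L costs ``gap_open + (L-1) *
gap_extend``).  A pair becomes a homology edge when the alignment satisfies
all three acceptance criteria: it spans at least 80% of the longer sequence,
at least 40% of its columns are exact residue matches, and its score reaches
at least 30% of the longer sequence's self-alignment score.

"Alignment length" here counts *all* alignment columns — matches,
mismatches, and gap columns — which makes the identity criterion well
defined.  Traceback is deterministic: the highest-scoring cell with the
smallest (row, column) wins, and ties among moves prefer diagonal, then up
(gap in the second sequence), then left, with gap-open preferred over
gap-extend.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .cluster import HomologyGraph
from .model import ProteomeSet
from .prefilter import FilterParams, candidate_pairs

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i

_NEG = -(2**30)


@lru_cache(maxsize=8)
def _load_matrix(name: str) -> np.ndarray:
    m = substitution_matrices.load(name)
    out = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(ALPHABET[:20]):
        for j, b in enumerate(ALPHABET[:20]):
            out[i, j] = int(m[a, b])
    out[20, :] = 0
    out[:, 20] = 0
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix and affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open < 1 or self.gap_extend < 1:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    def matrix(self) -> np.ndarray:
        """21x21 integer matrix over ACDEFGHIKLMNPQRSTVWYX; X scores 0
        against everything, including itself."""
        return _load_matrix(self.matrix_name)


@dataclass(frozen=True)
class EdgeCriteria:
    min_len_frac: float = 0.80
    min_identity_frac: float = 0.40
    min_score_frac: float = 0.30

    def __post_init__(self) -> None:
        for v in (self.min_len_frac, self.min_identity_frac, self.min_score_frac):
            if not (0.0 < v <= 1.0):
                raise ValueError("edge criteria fractions must lie in (0, 1]")


@dataclass(frozen=True)
class AlignmentResult:
    seq_id_a: str
    seq_id_b: str
    score: int
    align_len: int          # all alignment columns incl. gap columns
    n_identical: int
    self_score_longer: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_identical <= max(self.align_len, 0)):
            raise ValueError("n_identical outside [0, align_len]")


def encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({c for c in seq if _CODE[ord(c)] < 0})
        raise ValueError(f"invalid residues {bad}")
    return arr


@njit(cache=True)
def _sw_fill(a, b, S, go, ge):  # pragma: no cover - exercised via local_align
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - go
            e2 = E[i, j - 1] - ge
            if e2 > e:
                e = e2
            f = H[i - 1, j] - go
            f2 = F[i - 1, j] - ge
            if f2 > f:
                f = f2
            E[i, j] = e
            F[i, j] = f
            d = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            # preference on ties: diagonal > up (F) > left (E)
            h = d
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(a, b, S, go, ge, H, E, F, bi, bj):
    """Walk back from the best cell; returns (align_len, n_identical)."""
    cols = 0
    ident = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=F (up), 2=E (left)
    while True:
        if state == 0:
            v = H[i, j]
            if v == 0:
                break
            d = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            if v == d:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif v == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap column consuming a[i-1]
            cols += 1
            if F[i, j] == H[i - 1, j] - go:  # gap open preferred on tie
                state = 0
            i -= 1
        else:  # gap column consuming b[j-1]
            cols += 1
            if E[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
    return cols, ident


def self_score(seq: str, scoring: ScoringParams = ScoringParams()) -> int:
    """Optimal score of a sequence aligned against itself: the sum of the
    diagonal matrix entries of its residues (gaps are never optimal when the
    diagonal is non-negative)."""
    if not seq:
        raise ValueError("empty sequence")
    codes = encode(seq)
    S = scoring.matrix()
    return int(S[codes, codes].sum())


def local_align(seq_a: str, seq_b: str, scoring: ScoringParams = ScoringParams(),
                seq_id_a: str = "A", seq_id_b: str = "B") -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two sequences."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a = encode(seq_a)
    b = encode(seq_b)
    S = scoring.matrix()
    H, E, F, best, bi, bj = _sw_fill(a, b, S, scoring.gap_open, scoring.gap_extend)
    if best == 0:
        cols, ident = 0, 0
    else:
        cols, ident = _traceback(a, b, S, scoring.gap_open, scoring.gap_extend,
                                 H, E, F, bi, bj)
    longer = seq_a if len(seq_a) >= len(seq_b) else seq_b
    return AlignmentResult(seq_id_a=seq_id_a, seq_id_b=seq_id_b, score=int(best),
                           align_len=cols, n_identical=ident,
                           self_score_longer=self_score(longer, scoring))


def accept_edge(result: AlignmentResult, len_a: int, len_b: int,
                criteria: EdgeCriteria = EdgeCriteria()) -> bool:
    """Apply the three edge-acceptance criteria to one alignment result."""
    if result.self_score_longer <= 0:
        raise ValueError("degenerate input: non-positive self score")
    longer = max(len_a, len_b)
    if result.align_len < criteria.min_len_frac * longer:
        return False
    if result.n_identical < criteria.min_identity_frac * result.align_len:
        return False
    return result.score >= criteria.min_score_frac * result.self_score_longer


def build_homology_graph(proteome: ProteomeSet,
                         filter_params: FilterParams = FilterParams(),
                         scoring: ScoringParams = ScoringParams(),
                         criteria: EdgeCriteria = EdgeCriteria(),
                         ) -> tuple[HomologyGraph, list[AlignmentResult]]:
    """Run prefilter + alignment over a proteome and assemble the weighted
    homology graph (edge weight = alignment length in columns).

    Every seq_id becomes a vertex, so sequences with no accepted alignment
    surface later as singleton clusters.  Also returns the accepted
    alignment results, in pair order.
    """
    sequences = {sid: rec.sequence for sid, rec in proteome.records.items()}
    graph = HomologyGraph(vertices=sorted(sequences))
    accepted: list[AlignmentResult] = []
    for ida, idb in candidate_pairs(sequences, filter_params):
        res = local_align(sequences[ida], sequences[idb], scoring, ida, idb)
        if res.align_len == 0:
            continue
        if accept_edge(res, len(sequences[ida]), len(sequences[idb]), criteria):
            graph.add_edge(ida, idb, float(res.align_len))
            accepted.append(res)
    return graph, accepted


def write_edge_tsv(results: list[AlignmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_idA\tseq_idB\tweight\tscore\tn_identical\n")
        for r in results:
            fh.write(f"{r.seq_id_a}\t{r.seq_id_b}\t{r.align_len}\t{r.score}\t"
                     f"{r.n_identical}\n")
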