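"""Pre-alignment filters: drop sequence pairs that cannot become edges.

Two conservative filters run before any alignment is attempted: a length
ratio filter (the edge criterion requires the alignment to span 80% of the
longer sequence, so wildly different lengths cannot qualify) and an exact
k-mer filter (pairs sharing no exact subsequence of a minimum length — seven
works well for proteins — cannot reach the identity criterion).  Candidate
enumeration uses a k-truncated generalized suffix array over the
concatenated sequences rather than scanning all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np


@dataclass(frozen=True)
class FilterParams:
    length_ratio_min: float = 0.8
    exact_match_k: int = 7

    def __post_init__(self) -> None:
        if not (0.0 < self.length_ratio_min <= 1.0):
            raise ValueError("length_ratio_min must lie in (0, 1]")
        if self.exact_match_k < 1:
            raise ValueError("exact_match_k must be >= 1")


def length_compatible(len_a: int, len_b: int,
                      params: FilterParams = FilterParams()) -> bool:
    """True iff min/max length ratio reaches ``length_ratio_min``."""
    if len_a < 1 or len_b < 1:
        raise ValueError("sequence lengths must be positive")
    return min(len_a, len_b) / max(len_a, len_b) >= params.length_ratio_min


def shared_exact_match(seq_a: str, seq_b: str, k: int = 7) -> bool:
    """True iff the sequences share some exact substring of length ``k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) < k or len(seq_b) < k:
        return False
    if len(seq_b) < len(seq_a):
        seq_a, seq_b = seq_b, seq_a
    kmers = {seq_a[i:i + k] for i in range(len(seq_a) - k + 1)}
    return any(seq_b[i:i + k] in kmers for i in range(len(seq_b) - k + 1))


def _suffix_groups(sequences: list[str], k: int) -> Iterable[np.ndarray]:
    """Yield, for every distinct k-mer of the concatenated text, the array of
    sequence indices containing it (with multiplicity collapsed).

    Built as a generalized suffix array truncated at depth k: all suffix
    windows of length k are radix-sorted with numpy lexsort; runs of equal
    windows are one k-mer group.
    """
    text = "\x00".join(sequences)
    arr = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
    n = arr.size
    if n < k:
        return
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = ~(win == 0).any(axis=1)
    pos = np.nonzero(valid)[0]
    if pos.size == 0:
        return
    win = win[valid]
    order = np.lexsort(win.T[::-1])
    win = win[order]
    pos = pos[order]
    # map text position -> sequence index
    starts = np.cumsum([0] + [len(s) + 1 for s in sequences[:-1]])
    seq_of = np.searchsorted(starts, pos, side="right") - 1
    boundary = np.nonzero((win[1:] != win[:-1]).any(axis=1))[0] + 1
    edges = np.concatenate(([0], boundary, [len(pos)]))
    for i in range(len(edges) - 1):
        grp = np.unique(seq_of[edges[i]:edges[i + 1]])
        if grp.size > 1:
            yield grp


def candidate_pairs(sequences: Mapping[str, str],
                    params: FilterParams = FilterParams()) -> list[tuple[str, str]]:
    """All unordered pairs passing both the length and exact-match filters.

    Pairs are returned once each, no self-pairs, ordered lexicographically
    within and across pairs for deterministic downstream processing.
    """
    ids = sorted(sequences)
    if len(ids) < 2:
        return []
    seqs = [sequences[i] for i in ids]
    lens = [len(s) for s in seqs]
    if min(lens) < 1:
        raise ValueError("sequences must be non-empty")
    pair_idx: set[tuple[int, int]] = set()
    for grp in _suffix_groups(seqs, params.exact_match_k):
        g = grp.tolist()
        for a, b in combinations(g, 2):
            if length_compatible(lens[a], lens[b], params):
                pair_idx.add((a, b))
    return sorted((ids[a], ids[b]) for a, b in pair_idx)


def write_pairs_tsv(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_idA\tseq_idB\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
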