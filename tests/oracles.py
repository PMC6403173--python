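"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles in plain Python (no numpy
DP, no shared code with src/) so that agreement with the package is a real
two-route check.
"""

from itertools import combinations

from Bio.Align import substitution_matrices

NEG = float("-inf")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def score_lookup(a: str, b: str) -> int:
    """BLOSUM62 with X scoring 0 against everything."""
    if a == "X" or b == "X":
        return 0
    return int(_BLOSUM62[a, b])


def sw_score(seq_a: str, seq_b: str, gap_open: int = 10, gap_extend: int = 1) -> int:
    """Optimal local affine-gap score by the textbook Gotoh recursion.

    Gap of length L costs open + (L-1)*extend.
    """
    n, m = len(seq_a), len(seq_b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            d = H[i - 1][j - 1] + score_lookup(seq_a[i - 1], seq_b[j - 1])
            H[i][j] = max(0.0, d, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def brute_force_pairs(sequences: dict[str, str], ratio_min: float, k: int
                      ) -> set[tuple[str, str]]:
    """All-pairs evaluation of the length + shared-k-mer double filter."""
    out = set()
    for a, b in combinations(sorted(sequences), 2):
        sa, sb = sequences[a], sequences[b]
        if min(len(sa), len(sb)) / max(len(sa), len(sb)) < ratio_min:
            continue
        ka = {sa[i:i + k] for i in range(len(sa) - k + 1)}
        kb = {sb[i:i + k] for i in range(len(sb) - k + 1)}
        if ka & kb:
            out.add((a, b))
    return out


def set_partitions(items):
    """All set partitions of a list (restricted growth strings)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return

    def rec(i, parts):
        if i == n:
            yield [list(p) for p in parts]
            return
        for p in parts:
            p.append(items[i])
            yield from rec(i + 1, parts)
            p.pop()
        parts.append([items[i]])
        yield from rec(i + 1, parts)
        parts.pop()

    yield from rec(0, [])


def exhaustive_best_modularity(edges: list[tuple[str, str, float]],
                               vertices: list[str]) -> float:
    """Maximum modularity over every partition of the vertex set."""
    m = sum(w for _, _, w in edges)
    deg = {v: 0.0 for v in vertices}
    for u, v, w in edges:
        deg[u] += w
        deg[v] += w
    best = -1.0
    for parts in set_partitions(vertices):
        com = {}
        for ci, p in enumerate(parts):
            for v in p:
                com[v] = ci
        intra = sum(w for u, v, w in edges if com[u] == com[v])
        dtot = {}
        for v in vertices:
            dtot[com[v]] = dtot.get(com[v], 0.0) + deg[v]
        q = intra / m - sum(d * d for d in dtot.values()) / (4 * m * m)
        best = max(best, q)
    return best
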