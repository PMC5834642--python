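"""Independent brute-force oracles, deliberately naive and self-contained.

Nothing here imports the package's alignment or normalization code: these
are the reference computations the fast implementations are checked against.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def dp_semiglobal_score(
    query: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> float:
    """Exhaustive affine-gap DP over the full score matrix.

    The query is aligned end-to-end; terminal reference overhangs are free;
    a gap of length k costs ``gap_open + k * gap_extend``.  Three-state
    Gotoh recursion, no shortcuts.
    """
    n, m = len(ref), len(query)
    first = gap_open + gap_extend  # cost of the first base of a gap

    # state[i][j]: best score having consumed i ref chars and j query chars,
    # ending in a match/mismatch column (M), a ref-consuming gap column (D),
    # or a query-consuming gap column (I).
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    D = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    I = [[NEG_INF] * (m + 1) for _ in range(n + 1)]

    def start(i: int, j: int) -> float:
        # free consumption of any reference prefix before the query begins
        return 0.0 if j == 0 else NEG_INF

    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if ref[i - 1] == query[j - 1] else mismatch
                M[i][j] = s + max(
                    M[i - 1][j - 1],
                    D[i - 1][j - 1],
                    I[i - 1][j - 1],
                    start(i - 1, j - 1),
                )
            if i > 0 and j > 0:
                # internal deletion (ref consumed against a query gap); at
                # j == 0 the free start dominates, so restrict to j >= 1
                D[i][j] = max(
                    M[i - 1][j] + first,
                    I[i - 1][j] + first,
                    D[i - 1][j] + gap_extend,
                )
            if j > 0:
                I[i][j] = max(
                    M[i][j - 1] + first,
                    D[i][j - 1] + first,
                    I[i][j - 1] + gap_extend,
                    start(i, j - 1) + first,
                )

    # trailing reference overhang is free: best over all ref prefixes
    return max(
        max(M[i][m], D[i][m], I[i][m]) for i in range(n + 1)
    )


def enumerate_deletion_placements(ref: str, start: int, length: int) -> list[int]:
    """All 1-based start positions whose length-``length`` deletion yields
    the same mutated sequence as deleting at ``start``."""
    target = ref[: start - 1] + ref[start - 1 + length :]
    placements = []
    for s in range(1, len(ref) - length + 2):
        if ref[: s - 1] + ref[s - 1 + length :] == target:
            placements.append(s)
    return placements


def enumerate_insertion_placements(
    ref: str, position: int, bases: str
) -> list[tuple[int, str]]:
    """All (insert-before position, inserted bases) pairs reproducing the
    mutated sequence of inserting ``bases`` before ``position``."""
    target = ref[: position - 1] + bases + ref[position - 1 :]
    k = len(bases)
    placements = []
    for p in range(1, len(ref) + 2):
        x = target[p - 1 : p - 1 + k]
        if ref[: p - 1] + x + ref[p - 1 :] == target:
            placements.append((p, x))
    return placements
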