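"""Independent reference implementations used only to check the package.

Each oracle is deliberately written with a different formulation than the
implementation it validates: the aligner oracle enumerates offsets
naively, the alignment-score oracle is a top-down memoized recursion, the
Fisher oracle goes through scipy, and the clustering oracle is an
all-pairs union-find.
"""

from __future__ import annotations

from functools import lru_cache

NEG = float("-inf")


def brute_force_alignments(query: str, ref) -> list[tuple[str, str, int, int]]:
    """All best-stratum ungapped alignments (<=3 mismatches) by direct
    per-offset character comparison over every reference form."""
    hits = []
    for eid, form, seq in ref.iter_forms():
        L = len(query)
        for off in range(len(seq) - L + 1):
            mm = sum(1 for a, b in zip(query, seq[off : off + L]) if a != b)
            if mm <= 3:
                hits.append((mm, eid, form, off, off + L))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    return sorted((eid, form, s, e) for mm, eid, form, s, e in hits if mm == best)


def gotoh_score_recursive(tsrna: str, window: str, params) -> float:
    """Best local complementarity-alignment score via top-down recursion.

    States: (i, j, state) = best score of an alignment *ending* at query
    position i / window position j in match (M), query-gap (E) or
    window-gap (F) state. The local maximum is the max over all cells.
    """
    q = tsrna[::-1]
    m, n = len(q), len(window)
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "T"), ("T", "G")}

    def sub(i: int, j: int) -> float:
        pos1 = m - (i - 1)  # 1-based tsRNA position
        w = params.seed_scale if params.seed_start <= pos1 <= params.seed_end else 1.0
        pair = (q[i - 1], window[j - 1])
        if pair in pairs:
            return params.match * w
        if pair in wobble:
            return params.gu_wobble * w
        return params.mismatch * w

    import sys

    sys.setrecursionlimit(100000)

    @lru_cache(maxsize=None)
    def M(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return NEG
        prev = max(0.0, M(i - 1, j - 1), E(i - 1, j - 1), F(i - 1, j - 1))
        return prev + sub(i, j)

    @lru_cache(maxsize=None)
    def E(i: int, j: int) -> float:  # gap consuming window
        if j == 0:
            return NEG
        h_prev = max(0.0, M(i, j - 1), E(i, j - 1), F(i, j - 1))
        return max(h_prev + params.gap_open, E(i, j - 1) + params.gap_extend)

    @lru_cache(maxsize=None)
    def F(i: int, j: int) -> float:  # gap consuming query
        if i == 0:
            return NEG
        return max(
            max(0.0, M(i - 1, j), E(i - 1, j), F(i - 1, j)) + params.gap_open,
            F(i - 1, j) + params.gap_extend,
        )

    best = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            best = max(best, M(i, j), E(i, j), F(i, j))
    M.cache_clear(), E.cache_clear(), F.cache_clear()
    return best


def fisher_greater_scipy(a: int, b: int, c: int, d: int) -> float:
    from scipy import stats

    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))


def cluster_all_pairs(seqs) -> dict[str, int]:
    """Transitive closure of one-terminal-nt extension via explicit
    all-pairs union-find."""
    seqs = sorted(set(seqs))
    parent = {s: s for s in seqs}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for x in seqs:
        for y in seqs:
            if len(x) == len(y) + 1 and (x[:-1] == y or x[1:] == y):
                rx, ry = find(x), find(y)
                if rx != ry:
                    parent[rx] = ry
    roots = sorted({find(s) for s in seqs})
    root_id = {r: i for i, r in enumerate(roots)}
    return {s: root_id[find(s)] for s in seqs}
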