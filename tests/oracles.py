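"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's interval engine internals: all-pairs
scans, per-base boolean masks, union-find, and direct enumeration.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom

Triple = Tuple[str, int, int]


def brute_intersect(a: Sequence[Triple], b: Sequence[Triple]) -> List[Triple]:
    """All-pairs overlap pieces of a truncated to b."""
    out = []
    for ca, sa, ea in a:
        for cb, sb, eb in b:
            if ca == cb and sa < eb and sb < ea:
                out.append((ca, max(sa, sb), min(ea, eb)))
    return sorted(out)


def mask_subtract(
    a: Sequence[Triple], b: Sequence[Triple], genome_len: int = 20_000
) -> List[Triple]:
    """Per-base boolean-mask subtraction on a toy genome, applied to each
    a-interval independently (no merging of adjacent a pieces)."""
    chroms = sorted({c for c, _, _ in a} | {c for c, _, _ in b})
    covered: Dict[str, np.ndarray] = {
        c: np.zeros(genome_len, dtype=bool) for c in chroms
    }
    for c, s, e in b:
        covered[c][s:e] = True
    out: List[Triple] = []
    for c, s, e in a:
        keep = ~covered[c][s:e]
        # runs of kept bases
        idx = np.flatnonzero(np.diff(np.concatenate(([0], keep.view(np.int8), [0]))))
        for lo, hi in zip(idx[0::2], idx[1::2]):
            out.append((c, s + int(lo), s + int(hi)))
    return sorted(out)


def allpairs_closest(
    a: Sequence[Triple], b: Sequence[Triple]
) -> List[Tuple[Triple, Optional[Triple], int]]:
    """Exhaustive min-over-all-pairs distances; ties -> smallest b start."""
    out = []
    for ca, sa, ea in a:
        best: Optional[Triple] = None
        best_d = None
        for cb, sb, eb in sorted(b):
            if cb != ca:
                continue
            d = max(sb - ea, sa - eb, 0)
            if best_d is None or d < best_d:
                best, best_d = (cb, sb, eb), d
        out.append(((ca, sa, ea), best, -1 if best_d is None else best_d))
    return out


def unionfind_merge(intervals: Sequence[Triple], gap: int) -> List[Triple]:
    """Union-find over the pairwise distance graph, then component hulls."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci == cj and max(sj - ei, si - ej, 0) <= gap:
                union(i, j)
    comps: Dict[int, List[Triple]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    return sorted(
        (members[0][0], min(s for _, s, _ in members), max(e for _, _, e in members))
        for members in comps.values()
    )


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric-tail enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    pmfs = hypergeom.pmf(np.arange(lo, hi + 1), n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(pmfs[pmfs <= p_obs * (1 + 1e-7)].sum())


def single_linkage_tiles(
    dmcpgs: Sequence[Tuple[str, int, float]], merge_gap: int = 500, min_size: int = 100
) -> Tuple[List[Tuple[str, int, int, float, int]], int]:
    """Independent tiling oracle: single-linkage clustering at ``merge_gap``
    on an all-pairs distance graph, ambiguity removal, then symmetric
    extension. Returns (chrom, start, end, mean_diff, n) tuples."""
    n = len(dmcpgs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        ci, pi, _ = dmcpgs[i]
        for j in range(i + 1, n):
            cj, pj, _ = dmcpgs[j]
            if ci == cj and abs(pi - pj) <= merge_gap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: Dict[int, List[Tuple[str, int, float]]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(dmcpgs[i])
    tiles = []
    n_ambiguous = 0
    for members in comps.values():
        if len({d > 0 for _, _, d in members}) != 1:
            n_ambiguous += 1
            continue
        chrom = members[0][0]
        start = min(p for _, p, _ in members) - 1
        end = max(p for _, p, _ in members)
        deficit = min_size - (end - start)
        if deficit > 0:
            grow = -(-deficit // 2)
            start -= grow
            end += grow
            if end - start > min_size:
                end -= (end - start) - min_size
            if start < 0:
                end -= start
                start = 0
        diffs = [d for _, _, d in members]
        tiles.append((chrom, start, end, sum(diffs) / len(diffs), len(members)))
    return sorted(tiles), n_ambiguous
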