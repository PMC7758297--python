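"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own alignment/graph machinery: the
Smith-Waterman oracle is a direct affine-gap dynamic program over numpy
rows, interval merging is a transitive-closure loop, grouping is a tiny
disjoint-set union, and circular ORF calling enumerates rotations.
"""

from __future__ import annotations

import numpy as np


def sw_score(query: str, subject: str, matrix, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal local alignment score, affine gaps costing open + k*extend."""
    m, n = len(query), len(subject)
    if m == 0 or n == 0:
        return 0.0
    sub = np.empty((m, n))
    for i, qa in enumerate(query):
        row = matrix[qa]
        for j, sa in enumerate(subject):
            sub[i, j] = row[sa]
    NEG = -1e18
    first = gap_open + gap_extend
    M_prev = np.full(n + 1, NEG)
    Ix_prev = np.full(n + 1, NEG)
    Iy_prev = np.full(n + 1, NEG)
    M_prev[:] = NEG
    best = 0.0
    ks = np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        base = np.maximum.reduce([M_prev, Ix_prev, Iy_prev, np.zeros(n + 1)])
        M_row = np.full(n + 1, NEG)
        M_row[1:] = sub[i - 1, :] + base[:-1]
        Ix_row = np.maximum(M_prev - first, Ix_prev - gap_extend)
        c = np.maximum(M_row, Ix_row) + gap_extend * ks
        run = np.maximum.accumulate(c)
        Iy_row = np.full(n + 1, NEG)
        Iy_row[1:] = run[:-1] - gap_open - gap_extend * ks[1:]
        best = max(best, float(M_row.max()))
        M_prev, Ix_prev, Iy_prev = M_row, Ix_row, Iy_row
    return best


def merge_closure(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Transitive closure of >=1-base interval overlap, O(n^2)."""
    groups: list[list[tuple[int, int]]] = []
    for iv in intervals:
        hit = [g for g in groups if any(iv[0] < b and a < iv[1] for a, b in g)]
        merged = [iv] + [x for g in hit for x in g]
        groups = [g for g in groups if g not in hit]
        groups.append(merged)
    # closure may need repetition: iterate until stable
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                lo_i = min(a for a, _ in groups[i]); hi_i = max(b for _, b in groups[i])
                lo_j = min(a for a, _ in groups[j]); hi_j = max(b for _, b in groups[j])
                if lo_i < hi_j and lo_j < hi_i:
                    groups[i] += groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((min(a for a, _ in g), max(b for _, b in g)) for g in groups)


class DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def circular_orfs_by_rotation(sequence: str, min_aa: int = 75) -> set[tuple[str, int, int]]:
    """All ATG-to-stop ORFs on a circular sequence by explicit enumeration.

    For every start position on either strand, read codons around the
    circle until a stop (at most one full turn).  Returns (strand,
    forward_start, forward_start + nt_length) keys comparable to find_orfs
    output, keeping only the longest ORF per stop position.
    """
    from egvscan.search import revcomp
    from egvscan.selection import translate_cds

    L = len(sequence)
    by_stop: dict[tuple[str, int], tuple[int, int]] = {}
    for strand, s in (("+", sequence), ("-", revcomp(sequence))):
        ss = s + s
        for p in range(L):
            if ss[p : p + 3] != "ATG":
                continue
            q = p
            found = None
            while q + 3 <= p + L:
                codon = ss[q : q + 3]
                if translate_cds(codon) == "*":
                    found = q + 3
                    break
                q += 3
            if found is None:
                continue
            n_aa = (found - p) // 3 - 1
            if n_aa <= min_aa:
                continue
            if strand == "+":
                f_start = p % L
            else:
                f_start = (L - (found % L)) % L
            key = (strand, found % L)
            length = found - p
            if key not in by_stop or length > by_stop[key][1]:
                by_stop[key] = (f_start, length)
    return {(strand, st, st + ln) for (strand, _), (st, ln) in
            ((k, v) for k, v in by_stop.items())}
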