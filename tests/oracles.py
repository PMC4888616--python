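"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available
(exhaustive enumeration, closed form, tiny dynamic programme) and is
kept free of the package's own search/shortcut code paths.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


# --------------------------------------------------------------------------
# N50: try every candidate length.
def n50_exhaustive(lengths) -> int:
    total = sum(lengths)
    return max(L for L in lengths
               if sum(x for x in lengths if x >= L) >= total / 2)


# --------------------------------------------------------------------------
# Canonical motif class: enumerate every rotation of the motif and of its
# reverse complement, take the lexicographic minimum.
def canonical_enumerated(motif: str) -> str:
    cands = []
    for m in (motif, rc(motif)):
        for i in range(len(m)):
            cands.append(m[i:] + m[:i])
    return min(cands)


# --------------------------------------------------------------------------
# SSR scan: test every (position, unit length) pair.
def ssr_bruteforce(s: str, min_repeats: dict[int, int]) -> set[tuple]:
    """Set of (start_1based, end_1based, unit) for every maximal perfect
    tract of a primitive N-free unit meeting the class minimum.

    A repeat region is reported once per unit length under its leftmost
    phase: candidate runs from every (position, unit length) pair are
    enumerated, then runs starting inside an earlier-starting run of
    the same unit length are suppressed.
    """
    def primitive(u: str) -> bool:
        return all(not (len(u) % d == 0 and u == u[:d] * (len(u) // d))
                   for d in range(1, len(u)))

    found = set()
    n = len(s)
    for k, min_rep in min_repeats.items():
        candidates = []
        for i in range(n - k + 1):
            unit = s[i:i + k]
            if "N" in unit or not primitive(unit):
                continue
            if i >= k and s[i - k:i] == unit:
                continue        # not left-maximal
            j = i + k
            while s[j:j + k] == unit:
                j += k
            count = (j - i) // k
            if count >= min_rep:
                candidates.append((i + 1, i + count * k, unit))
        last_end = 0
        for start, end, unit in sorted(candidates):
            if start > last_end:
                found.add((start, end, unit))
                last_end = end
    return found


# --------------------------------------------------------------------------
# Nearest-neighbour melting temperature: manual dH/dS summation with the
# unified parameter table, 50 mM Na+, 50 nM primer, entropy salt correction
# 0.368 (N-1) ln[Na+].
def tm_nn_manual(seq: str, nn_table: dict, Na: float = 0.05,
                 conc: float = 50e-9) -> float:
    dH, dS = nn_table["init"]
    for term in (seq[0], seq[-1]):
        h, s = nn_table["init_A/T" if term in "AT" else "init_G/C"]
        dH += h
        dS += s
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        key = pair + "/" + pair.translate(COMP)
        if key not in nn_table:
            left, right = key.split("/")
            key = right[::-1] + "/" + left[::-1]
        h, s = nn_table[key]
        dH += h
        dS += s
    dS += 0.368 * (len(seq) - 1) * math.log(Na)
    R = 1.987
    return 1000.0 * dH / (dS + R * math.log(conc)) - 273.15


# --------------------------------------------------------------------------
# Primer-site search: full scan of every 3'-end position.  The 3'-terminal
# seed word must match exactly (located here by a vectorised rolling
# comparison over every position); the 5' remainder is aligned by a small
# dynamic programme over (suffix consumed, genome consumed, gap budget).
def primer_sites_fullscan(primer: str, s: str, seed_word: int,
                          max_mm: int, max_gaps: int) -> set[tuple]:
    """Set of (three_prime_end_1based, mismatches, gaps) on the plus
    strand.  Requires max_gaps <= 1."""
    assert max_gaps <= 1
    seed = primer[-seed_word:]
    u = primer[:-seed_word]
    m = len(u)
    arr = np.frombuffer(s.encode(), dtype="S1")
    n = len(s)
    W = seed_word
    if n < W:
        return set()
    match = np.ones(n - W + 1, dtype=bool)
    for k, ch in enumerate(seed):
        match &= arr[k:n - W + 1 + k] == ch.encode()
    out = set()
    INF = math.inf
    for p in np.flatnonzero(match):
        p = int(p)

        @lru_cache(maxsize=None)
        def f(k: int, c: int, gr: int) -> float:
            # min mismatches aligning the last k chars of u to the c
            # genome chars ending at index p, with gr gaps remaining
            if k == 0:
                return 0.0 if c == 0 else INF
            best = INF
            if c > 0 and p - c >= 0:
                g_ch = s[p - c]
                cost = 0 if (g_ch == u[m - k] and g_ch != "N") else 1
                best = min(best, f(k - 1, c - 1, gr) + cost)
                if gr > 0:
                    best = min(best, f(k, c - 1, gr - 1))   # genome unpaired
            if gr > 0:
                best = min(best, f(k - 1, c, gr - 1))       # primer unpaired
            return best

        cands = []
        for c in (m, m + 1, m - 1):
            if c < 0 or p - c < 0:
                continue
            gaps = abs(c - m)
            if gaps > max_gaps:
                continue
            mm = f(m, c, max_gaps)
            if mm <= max_mm:
                cands.append((mm, gaps))
        f.cache_clear()
        if cands:
            mm, gaps = min(cands)
            out.add((p + W, int(mm), int(gaps)))
    return out


# --------------------------------------------------------------------------
# UPGMA: naive agglomeration tracking cophenetic distances directly.
def upgma_cophenetic_bruteforce(dist: np.ndarray, labels) -> dict:
    """frozenset({a,b}) -> cophenetic distance under average linkage."""
    clusters = [[i] for i in range(len(labels))]
    d = dist.astype(float).copy()
    coph = {}
    active = list(range(len(labels)))
    while len(active) > 1:
        bi = bj = -1
        bd = math.inf
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                i, j = active[x], active[y]
                if d[i, j] < bd:
                    bd, bi, bj = d[i, j], i, j
        for a in clusters[bi]:
            for b in clusters[bj]:
                coph[frozenset((labels[a], labels[b]))] = bd
        # average-linkage update, size weighted
        ni, nj = len(clusters[bi]), len(clusters[bj])
        for k in active:
            if k in (bi, bj):
                continue
            d[bi, k] = d[k, bi] = (ni * d[bi, k] + nj * d[bj, k]) / (ni + nj)
        clusters[bi] = clusters[bi] + clusters[bj]
        active.remove(bj)
    return coph


# --------------------------------------------------------------------------
# PIC evaluated symbolically-by-arithmetic, summing over ordered pairs.
def pic_direct(p) -> float:
    p = list(p)
    n = len(p)
    term2 = sum(p[i] ** 2 for i in range(n))
    term3 = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            term3 += (p[i] ** 2) * (p[j] ** 2)
    return 1.0 - term2 - 2.0 * term3
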